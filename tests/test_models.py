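"""Island-effect models: closed-form oracles, mixed-vs-plain agreement,
stability diagnostics, and the comparison batteries."""

import numpy as np
import pandas as pd
import pytest

import shellforage as sf
from shellforage.models import (
    MaturationModel,
    OysterToolModel,
    SnailToolModel,
    tools_to_frame,
)


def ols_oracle(y: np.ndarray, x: np.ndarray):
    """Normal-equations OLS via group-mean algebra, independent of the
    model code path."""
    y0, y1 = y[x == 0], y[x == 1]
    est = y1.mean() - y0.mean()
    n = y.size
    rss = np.sum((y0 - y0.mean()) ** 2) + np.sum((y1 - y1.mean()) ** 2)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 * (1 / y0.size + 1 / y1.size))
    rss0 = np.sum((y - y.mean()) ** 2)
    F = (rss0 - rss) / sigma2
    return est, se, F


def snail_frame(k_weights, n_weights) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "island": ["Koram"] * len(k_weights) + ["NomSao"] * len(n_weights),
            "weight_g": list(k_weights) + list(n_weights),
        }
    )


class TestSnailToolModel:
    def test_exact_log_difference_on_toy_data(self):
        res = SnailToolModel(
            snail_frame([np.e, np.e], [np.e**2, np.e**2])
        ).fit()
        assert res.estimate == pytest.approx(1.0)
        assert res.transform == "log"

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        w = np.exp(rng.normal(3.0, 0.5, 60))
        frame = snail_frame(w[:35], w[35:])
        res = SnailToolModel(frame).fit()
        x = np.array([0] * 35 + [1] * 25, dtype=float)
        est, se, F = ols_oracle(np.log(w), x)
        assert res.estimate == pytest.approx(est, abs=1e-8)
        assert res.se == pytest.approx(se, abs=1e-8)
        assert res.statistic == pytest.approx(F, abs=1e-8)
        assert res.df == (1.0, 58.0)

    def test_nonpositive_weights_rejected_before_transform(self):
        with pytest.raises(ValueError):
            SnailToolModel(snail_frame([1.0, -2.0], [3.0, 4.0]))

    def test_permutation_p_close_to_f_p(self):
        """The relabeling null reproduces the parametric F p-value."""
        rng = np.random.default_rng(8)
        w = np.exp(
            np.concatenate([rng.normal(3.3, 0.6, 45),
                            rng.normal(3.55, 0.6, 22)])
        )
        res = SnailToolModel(snail_frame(w[:45], w[45:])).fit()
        perm = res.permutation_test(n_perm=2000, seed=9)
        mc_sd = np.sqrt(res.p_value * (1 - res.p_value) / 2000)
        assert perm.p_value == pytest.approx(res.p_value, abs=3 * mc_sd + 0.01)


def oyster_frame(rng, n_per=(40, 40), n_ind=(8, 4), effect=1.7,
                 ind_sd=1.0, noise=1.5, mu=8.0):
    rows = []
    for isl_i, island in enumerate(("Koram", "NomSao")):
        intercepts = rng.normal(0, ind_sd, n_ind[isl_i])
        for k in range(n_per[isl_i]):
            u = k % n_ind[isl_i]
            sw = mu + (effect if island == "NomSao" else 0) + intercepts[u]
            sw = sw + rng.normal(0, noise)
            rows.append(
                {"island": island, "weight_g": max(sw, 0.3) ** 2,
                 "user_id": f"{island}-{u}"}
            )
    return pd.DataFrame(rows)


class TestOysterToolModel:
    def test_lmm_with_no_individual_variance_matches_lm(self):
        """Zero between-individual variance: the mixed-model estimate
        collapses to the plain linear-model estimate."""
        rng = np.random.default_rng(5)
        frame = oyster_frame(rng, ind_sd=0.0)
        res = OysterToolModel(frame).fit()
        y = np.sqrt(frame["weight_g"].to_numpy())
        x = (frame["island"] == "NomSao").to_numpy(float)
        est, _, _ = ols_oracle(y, x)
        assert res.estimate == pytest.approx(est, abs=1e-4)

    def test_singular_fit_flagged_as_fallback(self):
        rng = np.random.default_rng(6)
        frame = oyster_frame(rng, ind_sd=0.0)
        res = OysterToolModel(frame).fit()
        # either converged with ~zero variance or explicitly fell back
        if res.fit_result.fallback_lm:
            assert "fallback" in res.summary()

    def test_one_island_rejected(self):
        rng = np.random.default_rng(7)
        frame = oyster_frame(rng)
        with pytest.raises(ValueError):
            OysterToolModel(frame[frame.island == "Koram"])

    def test_recovers_planted_effect(self):
        rng = np.random.default_rng(10)
        frame = oyster_frame(rng, n_per=(93, 93), n_ind=(14, 4), effect=1.7)
        res = OysterToolModel(frame).fit()
        assert res.estimate == pytest.approx(1.7, abs=3 * res.se)
        assert res.p_value < 0.05


class TestLeaveOneOut:
    def test_identical_individuals_all_estimates_equal(self):
        rows = []
        for island, uids in (("Koram", "abc"), ("NomSao", "xyz")):
            for u in uids:
                for _ in range(4):
                    rows.append(
                        {"island": island,
                         "weight_g": 25.0 if island == "Koram" else 64.0,
                         "user_id": u}
                    )
        frame = pd.DataFrame(rows)
        res = OysterToolModel(frame).fit()
        stab = res.leave_one_out()
        assert all(
            est == pytest.approx(res.estimate, abs=1e-6)
            for est in stab.per_unit.values()
        )
        assert stab.influential == ()

    def test_planted_outlier_is_flagged(self):
        rng = np.random.default_rng(12)
        frame = oyster_frame(rng, n_per=(40, 40), n_ind=(8, 4), effect=0.0,
                             ind_sd=0.3, noise=0.8)
        outlier = frame["user_id"] == "NomSao-0"
        frame.loc[outlier, "weight_g"] = 400.0  # one individual far off
        res = OysterToolModel(frame).fit()
        stab = res.leave_one_out()
        assert "NomSao-0" in stab.influential

    def test_balanced_synthetic_default_has_no_influential_units(
        self, default_dataset
    ):
        tools = default_dataset.analysis_tools(sf.Task.OYSTER)
        res = OysterToolModel(tools_to_frame(tools)).fit()
        stab = res.leave_one_out()
        assert stab.influential == ()


class TestMaturationModel:
    @staticmethod
    def frame(island_shift=0.0, n_per_cell=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for sp, base in (("P_sulcatus", 14.0), ("C_bifasciatus", 18.0)):
            for island in ("Koram", "NomSao"):
                for cat in (1, 2, 3, 4):
                    for _ in range(n_per_cell):
                        size = base * (0.5 + 0.25 * cat) + rng.normal(0, 1.0)
                        stage = int(np.clip(cat + rng.integers(-1, 2), 1, 4))
                        rows.append(
                            {
                                "island": island,
                                "species": sp,
                                "size_category": cat
                                + (island_shift if island == "NomSao" else 0.0),
                                "shell_size_mm": size,
                                "stage": stage,
                            }
                        )
        return pd.DataFrame(rows)

    def test_no_island_effect_when_sizes_stage_determined(self):
        res = MaturationModel(self.frame(island_shift=0.0, seed=1)).fit()
        assert abs(res.island_effect.estimate) < 0.2
        assert res.island_effect.p_value > 0.05

    def test_full_model_rejects_with_positive_slope(self):
        res = MaturationModel(self.frame(seed=2)).fit()
        assert res.full_vs_null.p_value < 0.001

    def test_island_shift_detected(self):
        res = MaturationModel(self.frame(island_shift=1.0, seed=3)).fit()
        assert res.island_effect.p_value < 0.01
        assert res.island_effect.estimate == pytest.approx(1.0, abs=0.4)

    def test_m_labio_excluded_and_rank_deficiency_reported(self):
        frame = self.frame(seed=4)
        labio = frame.iloc[:4].copy()
        labio["species"] = "M_labio"
        model = MaturationModel(pd.concat([frame, labio]))
        assert "M_labio" not in set(model.data["species"])
        single_stage = frame[frame.stage == 2]
        with pytest.raises(ValueError):
            MaturationModel(single_stage)

    def test_generated_maturation_data_fits(self, default_dataset):
        full, island = sf.fit_maturation_lm(default_dataset.maturation)
        assert full.p_value < 0.001  # stage strongly structures size
        assert island.p_value > 0.001  # no island effect by construction


class TestComparisonBatteries:
    def test_identical_sizes_give_null_comparison(self):
        records = [
            sf.SizeRecord(isl, sf.Taxon.OYSTER, 20.0 + i, 10.0)
            for isl in sf.Island
            for i in range(10)
        ]
        cmp = sf.compare_prey_sizes(records, sf.Taxon.OYSTER, seed=0)
        assert cmp.test.statistic == pytest.approx(0.0)
        assert cmp.overlap

    def test_rare_taxon_skipped_with_report(self):
        records = [
            sf.SizeRecord(sf.Island.KORAM, sf.Taxon.M_LABIO, 10.0 + i, 8.0)
            for i in range(4)
        ] + [
            sf.SizeRecord(sf.Island.NOMSAO, sf.Taxon.M_LABIO, 12.0 + i % 5, 8.0)
            for i in range(68)
        ]
        cmp = sf.compare_prey_sizes(records, sf.Taxon.M_LABIO, seed=0)
        assert cmp.skipped and cmp.test is None
        assert "Koram" in cmp.skip_reason
        assert cmp.n == {"Koram": 4, "NomSao": 68}

    def test_strong_size_shift_detected(self, default_dataset):
        cmp = sf.compare_prey_sizes(
            default_dataset.prey_sizes, sf.Taxon.OYSTER, seed=1
        )
        assert cmp.test.p_value < 0.001
        assert not cmp.overlap

    def test_availability_contrast_at_observed_scale(self, observed_transects):
        cmp = sf.compare_availability(
            observed_transects, sf.Taxon.P_SULCATUS, seed=2
        )
        assert cmp.test.p_value < 0.05
        assert cmp.ci["NomSao"].point > cmp.ci["Koram"].point

    def test_all_zero_counts_surface_degenerate_error(self):
        plots = [
            sf.SnailTransectPlot(isl, i + 1, {sf.Taxon.M_LABIO: 0})
            for isl in sf.Island
            for i in range(5)
        ]
        with pytest.raises(ValueError):
            sf.compare_availability(plots, sf.Taxon.M_LABIO, seed=0)

    def test_stone_supply_counts_vs_weights_contrast(self):
        def quadrats(island, weight_shift):
            out = []
            for i, n in enumerate((3, 4, 5)):
                stones = tuple(
                    sf.StoneMeasurement(50.0 + 2.0 * k + weight_shift)
                    for k in range(n)
                )
                out.append(
                    sf.StoneQuadrat(island, i + 1, sf.Zone.TIDAL, stones)
                )
            return out

        cmp = sf.compare_stone_supply(
            quadrats(sf.Island.KORAM, 0.0) + quadrats(sf.Island.NOMSAO, 10.0),
            seed=3,
        )
        assert cmp.counts_test.p_value == pytest.approx(1.0)
        assert cmp.weights_test.p_value < 0.05

    def test_synthetic_default_stone_pattern(self, default_dataset):
        """Counts comparable between islands, stones lighter on NomSao."""
        cmp = sf.compare_stone_supply(default_dataset.stone_quadrats, seed=4)
        assert cmp.counts_test.p_value > 0.05
        assert cmp.weights_test.statistic > 0  # Koram heavier
        assert cmp.weights_test.p_value < 0.05
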