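"""Island-effect models for tool weights and snail maturation, plus the
prey/stone comparison batteries.

Three fitted models form the core of the island comparison:

* ``OysterToolModel`` — linear mixed model for sqrt(tool weight) with island
  as fixed effect and a random intercept per tool user, fitted by maximum
  likelihood; the island term is tested by a likelihood-ratio chi-square.
* ``SnailToolModel`` — ordinary linear model for log(tool weight) with island
  as fixed effect, tested by an F-form likelihood-ratio test (no user
  identities are available for snail tools).
* ``MaturationModel`` — linear model relating the field size category of
  sampled snails to species, shell maturation stage and island; the full
  model is compared against the intercept-only null, and the island main
  effect is tested separately.

Each model follows the Model/Results convention: construct from data, call
``fit()``, and read estimates, tests and diagnostics off the Results object.
The reference island is always Koram, so estimates are the effect of NomSao
relative to Koram on the transformed scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .domain import (
    Island,
    SizeRecord,
    SnailTransectPlot,
    StoneQuadrat,
    Taxon,
    ToolUseRecord,
    default_size_method,
    compute_prey_size,
)
from .resampling import (
    BootstrapCI,
    PermutationResult,
    TestResult,
    bootstrap_mean_ci,
    permutation_island_test,
    welch_t_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "StabilityReport",
    "OysterToolModel",
    "SnailToolModel",
    "MaturationModel",
    "IslandEffectResults",
    "MaturationResults",
    "fit_oyster_tool_lmm",
    "fit_snail_tool_lm",
    "fit_maturation_lm",
    "leave_one_out_stability",
    "compare_prey_sizes",
    "compare_availability",
    "compare_stone_supply",
    "GroupComparison",
    "tools_to_frame",
]

REFERENCE = Island.KORAM


@dataclass(frozen=True)
class FitResult:
    """An island-effect estimate with its likelihood-ratio test.

    ``estimate`` is the coefficient of NomSao relative to the Koram
    reference on the transformed response scale; ``statistic`` is a
    chi-square (mixed model) or F (linear model) from comparing the full
    model against the model without the tested term.
    """

    estimate: float
    se: float
    statistic: float
    df: tuple[float, float | None]
    p_value: float
    transform: str
    n: int
    kind: str  # "chi_square" | "F"
    reference_level: Island = REFERENCE
    fallback_lm: bool = False

    def __str__(self) -> str:
        df1, df2 = self.df
        dfs = f"{df1:g}" if df2 is None else f"{df1:g},{df2:g}"
        return (
            f"E={self.estimate:.3f} SE={self.se:.3f} "
            f"{'chi2' if self.kind == 'chi_square' else 'F'}({dfs})="
            f"{self.statistic:.3f} p={self.p_value:.4g} "
            f"[{self.transform}(weight), n={self.n}]"
        )


@dataclass(frozen=True)
class StabilityReport:
    """Leave-one-unit-out estimates around a full-data estimate."""

    full_estimate: float
    per_unit: Mapping[str, float]
    influential: tuple[str, ...]
    failed: tuple[str, ...] = ()

    @property
    def range(self) -> tuple[float, float]:
        vals = list(self.per_unit.values())
        return (min(vals), max(vals))


def tools_to_frame(tools: Sequence[ToolUseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "island": [t.island.value for t in tools],
            "weight_g": [t.weight_g for t in tools],
            "user_id": [t.user_id if t.user_id is not None else f"_anon{i}"
                        for i, t in enumerate(tools)],
            "task": [t.task.value for t in tools],
        }
    )


def _check_two_islands(data: pd.DataFrame) -> None:
    present = set(data["island"])
    if len(present) < 2:
        raise ValueError(
            f"island comparison needs both islands, found only {sorted(present)}"
        )


def _island_indicator(data: pd.DataFrame) -> np.ndarray:
    """0 for the Koram reference, 1 for NomSao."""
    return (data["island"].astype(str) != REFERENCE.value).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# results


class IslandEffectResults:
    """Fit results of a single-term island model (mixed or ordinary).

    Wraps a :class:`FitResult` and offers the resampling companions: a
    cluster-aware permutation test of the island term and leave-one-unit-out
    stability checks.
    """

    def __init__(self, model: "_IslandModelBase", fit_result: FitResult,
                 residuals: np.ndarray, fitted: np.ndarray):
        self.model = model
        self.fit_result = fit_result
        self.residuals = residuals
        self.fitted = fitted

    # convenience pass-throughs
    estimate = property(lambda self: self.fit_result.estimate)
    se = property(lambda self: self.fit_result.se)
    statistic = property(lambda self: self.fit_result.statistic)
    df = property(lambda self: self.fit_result.df)
    p_value = property(lambda self: self.fit_result.p_value)
    n = property(lambda self: self.fit_result.n)
    transform = property(lambda self: self.fit_result.transform)

    def permutation_test(
        self, n_perm: int = 10000, seed: int | None = None
    ) -> PermutationResult:
        """Permutation companion of the likelihood-ratio test.

        Islands are relabelled at the model's sampling-unit level
        (individuals for the mixed model, records for the plain model) and
        the model's test statistic is recomputed for each relabeling.
        """
        m = self.model

        def stat(df: pd.DataFrame) -> float:
            return m._statistic_for(df)

        return permutation_island_test(
            m.data, stat, n_perm=n_perm, unit=m.permutation_unit, seed=seed
        )

    def leave_one_out(self, influence_se: float = 1.0) -> StabilityReport:
        """Refit excluding each sampling unit in turn.

        Units whose exclusion moves the island estimate by more than
        ``influence_se`` standard errors of the full fit are flagged
        influential.
        """
        m = self.model
        units = m.stability_units()
        per_unit: dict[str, float] = {}
        failed: list[str] = []
        for uid, mask in units.items():
            sub = m.data.loc[mask]
            try:
                if len(set(sub["island"])) < 2:
                    raise ValueError("one island left after exclusion")
                per_unit[uid] = m.__class__(sub).fit().estimate
            except Exception:
                failed.append(uid)
        thresh = max(influence_se * self.fit_result.se, 1e-8)
        influential = tuple(
            uid for uid, est in per_unit.items()
            if abs(est - self.fit_result.estimate) > thresh
        )
        return StabilityReport(self.fit_result.estimate, per_unit, influential,
                               tuple(failed))

    def diagnostics(self) -> dict[str, float]:
        """Report-only residual checks (never enforced).

        Shapiro-Wilk p for residual normality and a Breusch-Pagan p for
        homoscedasticity against the fitted values; Cook's-distance style
        leverage is reported as the fraction of points above 4/n.
        """
        resid = np.asarray(self.residuals, dtype=float)
        out: dict[str, float] = {}
        if 3 <= resid.size <= 5000:
            out["shapiro_p"] = float(stats.shapiro(resid).pvalue)
        X = np.column_stack([np.ones_like(self.fitted), self.fitted])
        aux = np.linalg.lstsq(X, resid**2, rcond=None)
        ss_tot = np.sum((resid**2 - np.mean(resid**2)) ** 2)
        ss_res = float(np.sum((resid**2 - X @ aux[0]) ** 2))
        r2 = 0.0 if ss_tot == 0 else 1 - ss_res / ss_tot
        lm_stat = resid.size * r2
        out["breusch_pagan_p"] = float(stats.chi2.sf(lm_stat, 1))
        return out

    def summary(self) -> str:
        fr = self.fit_result
        lines = [
            f"{self.model.__class__.__name__} (ref = {fr.reference_level.value})",
            "-" * 58,
            f"response  : {fr.transform}(weight_g), n = {fr.n}",
            f"island    : {str(fr)}",
        ]
        if fr.fallback_lm:
            lines.append("note      : singular random intercept; plain LM fallback")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# models


class _IslandModelBase:
    """Shared scaffolding: data frame in, ``fit()`` out."""

    transform: str = "none"
    permutation_unit: str = "record"

    def __init__(self, data: pd.DataFrame):
        required = {"island", "weight_g"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing column(s) {sorted(missing)}")
        data = data.reset_index(drop=True)
        if (np.asarray(data["weight_g"], dtype=float) <= 0).any():
            raise ValueError("weights must be positive before transformation")
        _check_two_islands(data)
        self.data = data

    @classmethod
    def from_records(cls, tools: Sequence[ToolUseRecord]):
        return cls(tools_to_frame(tools))

    def _response(self, data: pd.DataFrame) -> np.ndarray:
        y = np.asarray(data["weight_g"], dtype=float)
        if self.transform == "sqrt":
            return np.sqrt(y)
        if self.transform == "log":
            return np.log(y)
        return y

    def fit(self) -> IslandEffectResults:  # pragma: no cover - abstract
        raise NotImplementedError

    def _statistic_for(self, data: pd.DataFrame) -> float:
        raise NotImplementedError

    def stability_units(self) -> dict[str, pd.Series]:
        """Map unit id -> boolean keep-mask excluding that unit."""
        raise NotImplementedError


def _fit_mixedlm_ml(y: np.ndarray, exog: np.ndarray, groups: np.ndarray):
    """ML fit of a random-intercept model, robust to boundary solutions.

    Powell reliably reaches the optimum on these small two-group designs
    (gradient methods occasionally diverge or collapse the random-intercept
    variance to a spurious zero); the gradient optimizers serve as backups,
    with the best finite-likelihood fit kept.
    """
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("powell", "lbfgs", "bfgs"):
            try:
                fit = sm.MixedLM(y, exog, groups=groups).fit(
                    reml=False, method=method, maxiter=2000
                )
            except (np.linalg.LinAlgError, ValueError):
                continue
            values = [fit.llf, *np.ravel(fit.fe_params), *np.ravel(fit.bse_fe)]
            if not np.all(np.isfinite(values)):
                continue  # diverged to a degenerate boundary solution
            if best is None or fit.llf > best.llf + 1e-10:
                best = fit
            if method == "powell" and best is fit:
                break
    if best is None:
        raise RuntimeError("mixed-model likelihood optimisation failed")
    return best


def _ols_island(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float, float]:
    """Closed-form OLS of y on [1, x]: estimate, SE, F, residual SS."""
    n = y.size
    X = np.column_stack([np.ones(n), x])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df2 = n - 2
    if df2 <= 0:
        raise ValueError("degenerate linear model (no residual df)")
    if rss1 <= 0:  # perfect separation on a toy input: SE 0, F infinite
        return float(beta[1]), 0.0, float("inf"), 0.0
    sigma2 = rss1 / df2
    se = float(np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1]))
    F = (rss0 - rss1) / 1.0 / sigma2
    return float(beta[1]), se, float(F), rss1


class SnailToolModel(_IslandModelBase):
    """Linear model for log(snail-tool weight) ~ island.

    Snail tools carry no user identities, so records are the sampling units
    both for the fit and for the permutation companion.
    """

    transform = "log"
    permutation_unit = "record"

    def __init__(self, data: pd.DataFrame):
        super().__init__(data)
        for isl, grp in self.data.groupby("island"):
            if len(grp) < 2:
                raise ValueError(f"need >= 2 records per island, {isl} has {len(grp)}")

    def fit(self) -> IslandEffectResults:
        y = self._response(self.data)
        x = _island_indicator(self.data)
        est, se, F, _ = _ols_island(y, x)
        n = y.size
        p = float(stats.f.sf(F, 1, n - 2))
        fitted = y.mean() + (x - x.mean()) * est  # equivalently X @ beta
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        fitted = X @ beta
        fr = FitResult(est, se, F, (1.0, float(n - 2)), p, self.transform, n, "F")
        return IslandEffectResults(self, fr, y - fitted, fitted)

    def _statistic_for(self, data: pd.DataFrame) -> float:
        y = self._response(data)
        x = _island_indicator(data)
        return _ols_island(y, x)[2]

    def stability_units(self) -> dict[str, pd.Series]:
        return {
            str(i): self.data.index != i for i in self.data.index
        }


class OysterToolModel(_IslandModelBase):
    """Random-intercept mixed model for sqrt(oyster-tool weight) ~ island.

    One intercept per tool user absorbs the repeated tools of the same
    individual; the model is fitted by maximum likelihood so that the island
    term can be tested by a likelihood-ratio chi-square against the
    intercept-only mixed model.  If the individual variance collapses to
    zero the fit falls back to the plain linear model and says so.
    """

    transform = "sqrt"
    permutation_unit = "individual"

    def __init__(self, data: pd.DataFrame):
        super().__init__(data)
        if "user_id" not in self.data.columns:
            raise ValueError("oyster-tool model needs a user_id column")
        per_island_units = self.data.groupby("island")["user_id"].nunique()
        if (per_island_units < 2).any():
            raise ValueError(
                "need >= 2 individuals per island, got "
                + per_island_units.to_string()
            )

    def _fit_lmm(self, data: pd.DataFrame):
        y = self._response(data)
        x = _island_indicator(data)
        groups = data["user_id"].astype(str).to_numpy()
        exog_full = np.column_stack([np.ones(y.size), x])
        full = _fit_mixedlm_ml(y, exog_full, groups)
        null = _fit_mixedlm_ml(y, np.ones((y.size, 1)), groups)
        return full, null, y, exog_full

    def _lm_fallback(self, y: np.ndarray) -> IslandEffectResults:
        n = y.size
        x = _island_indicator(self.data)
        est, se, F, _ = _ols_island(y, x)
        # keep the chi-square LRT form for comparability
        chi2 = n * np.log1p(F / (n - 2))
        p = float(stats.chi2.sf(chi2, 1))
        fitted = np.column_stack([np.ones(n), x]) @ np.array(
            [y[x == 0].mean(), est]
        )
        fr = FitResult(est, se, float(chi2), (1.0, None), p, self.transform,
                       n, "chi_square", fallback_lm=True)
        return IslandEffectResults(self, fr, y - fitted, fitted)

    def fit(self) -> IslandEffectResults:
        try:
            full, null, y, exog = self._fit_lmm(self.data)
        except RuntimeError:
            logger.warning(
                "mixed-model likelihood could not be optimised; "
                "falling back to LM"
            )
            return self._lm_fallback(self._response(self.data))
        n = y.size
        var_re = float(np.asarray(full.cov_re).ravel()[0])
        resid_var = float(full.scale)
        if var_re <= 1e-8 * max(resid_var, 1e-12):
            logger.warning(
                "individual variance is singular (%.3g); falling back to LM",
                var_re,
            )
            return self._lm_fallback(y)
        chi2 = 2.0 * (full.llf - null.llf)
        chi2 = max(float(chi2), 0.0)
        p = float(stats.chi2.sf(chi2, 1))
        fr = FitResult(
            float(full.fe_params[1]),
            float(full.bse_fe[1]),
            chi2,
            (1.0, None),
            p,
            self.transform,
            n,
            "chi_square",
        )
        fitted = np.asarray(full.fittedvalues, dtype=float)
        return IslandEffectResults(self, fr, y - fitted, fitted)

    def _statistic_for(self, data: pd.DataFrame) -> float:
        full, null, _, _ = self._fit_lmm(data)
        return max(float(2.0 * (full.llf - null.llf)), 0.0)

    def stability_units(self) -> dict[str, pd.Series]:
        ids = self.data["user_id"].astype(str)
        return {uid: (ids != uid).to_numpy() for uid in ids.unique()}


class MaturationModel:
    """Linear model for the field size category of staged snails.

    Response: size category (1..4).  Predictors: prey species, gonad
    maturation stage (ordinal, entered as numeric), island, and the
    island x stage interaction.  Two tests are reported:

    * full model against the intercept-only null (does maturation stage,
      together with species, structure shell size at all?), F-form LRT;
    * the island main effect, tested with one df by dropping island from
      the additive model (species + stage + island vs species + stage) —
      under size-selective harvesting alone, snails of a given maturation
      stage should be the same size on both islands, so this term should
      be null.

    M. labio never enters: it was too rare on the heavily foraged island to
    sample across sizes, so it cannot support a cross-island contrast.
    """

    def __init__(self, data: pd.DataFrame):
        required = {"island", "species", "size_category", "stage"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing column(s) {sorted(missing)}")
        data = data.loc[data["species"].astype(str) != Taxon.M_LABIO.value]
        data = data.reset_index(drop=True)
        _check_two_islands(data)
        if data["stage"].nunique() < 2:
            raise ValueError("need >= 2 maturation stages")
        if data["species"].nunique() < 2:
            raise ValueError("need >= 2 species")
        cells = data.groupby(["island"])["stage"].nunique()
        if (cells < 2).any():
            empty = cells[cells < 2].index.tolist()
            raise ValueError(
                f"island(s) {empty} cover < 2 maturation stages; the "
                "island x stage design is rank deficient"
            )
        self.data = data

    @classmethod
    def from_records(cls, samples: Sequence) -> "MaturationModel":
        return cls(
            pd.DataFrame(
                {
                    "island": [s.island.value for s in samples],
                    "species": [s.species.value for s in samples],
                    "size_category": [s.size_category for s in samples],
                    "shell_size_mm": [s.shell_size_mm for s in samples],
                    "stage": [s.stage for s in samples],
                }
            )
        )

    def _design(self, with_island: bool, with_interaction: bool) -> np.ndarray:
        d = self.data
        n = len(d)
        cols = [np.ones(n)]
        species = pd.get_dummies(d["species"].astype(str), drop_first=True)
        for c in species.columns:
            cols.append(species[c].to_numpy(dtype=float))
        stage = d["stage"].to_numpy(dtype=float)
        cols.append(stage)
        if with_island:
            isl = _island_indicator(d)
            cols.append(isl)
            if with_interaction:
                cols.append(isl * stage)
        return np.column_stack(cols)

    @staticmethod
    def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), int(rank)

    def fit(self) -> "MaturationResults":
        y = self.data["size_category"].to_numpy(dtype=float)
        n = y.size

        X_full = self._design(with_island=True, with_interaction=True)
        rss_full, rank_full = self._rss(X_full, y)
        rss_null = float(np.sum((y - y.mean()) ** 2))
        df1 = rank_full - 1
        df2 = n - rank_full
        if df2 <= 0:
            raise ValueError("not enough residual degrees of freedom")
        if rss_full <= 0:
            F_full, p_full = np.inf, 0.0
        else:
            F_full = (rss_null - rss_full) / df1 / (rss_full / df2)
            p_full = float(stats.f.sf(F_full, df1, df2))
        full_vs_null = FitResult(
            float("nan"), float("nan"), float(F_full), (float(df1), float(df2)),
            p_full, "none", n, "F",
        )

        X_add = self._design(with_island=True, with_interaction=False)
        X_red = self._design(with_island=False, with_interaction=False)
        rss_add, rank_add = self._rss(X_add, y)
        rss_red, _ = self._rss(X_red, y)
        df2_add = n - rank_add
        beta_add, _, _, _ = np.linalg.lstsq(X_add, y, rcond=None)
        sigma2 = rss_add / df2_add if df2_add > 0 else np.nan
        cov = sigma2 * np.linalg.pinv(X_add.T @ X_add)
        est = float(beta_add[-1])
        se = float(np.sqrt(cov[-1, -1]))
        if rss_add <= 0:
            F_isl, p_isl = 0.0, 1.0
        else:
            F_isl = (rss_red - rss_add) / 1.0 / (rss_add / df2_add)
            F_isl = max(float(F_isl), 0.0)
            p_isl = float(stats.f.sf(F_isl, 1, df2_add))
        island_effect = FitResult(
            est, se, F_isl, (1.0, float(df2_add)), p_isl, "none", n, "F",
        )
        return MaturationResults(self, full_vs_null, island_effect)


@dataclass
class MaturationResults:
    model: MaturationModel
    full_vs_null: FitResult
    island_effect: FitResult

    def summary(self) -> str:
        return "\n".join(
            [
                "MaturationModel (size category ~ species + stage * island)",
                "-" * 58,
                f"full vs null : F({self.full_vs_null.df[0]:g},"
                f"{self.full_vs_null.df[1]:g}) = {self.full_vs_null.statistic:.3f},"
                f" p = {self.full_vs_null.p_value:.4g}",
                f"island term  : {str(self.island_effect)}",
            ]
        )


# ---------------------------------------------------------------------------
# functional wrappers over the model classes


def fit_oyster_tool_lmm(tools: Sequence[ToolUseRecord] | pd.DataFrame) -> FitResult:
    model = (OysterToolModel.from_records(tools)
             if not isinstance(tools, pd.DataFrame) else OysterToolModel(tools))
    return model.fit().fit_result


def fit_snail_tool_lm(tools: Sequence[ToolUseRecord] | pd.DataFrame) -> FitResult:
    model = (SnailToolModel.from_records(tools)
             if not isinstance(tools, pd.DataFrame) else SnailToolModel(tools))
    return model.fit().fit_result


def fit_maturation_lm(samples) -> tuple[FitResult, FitResult]:
    model = (MaturationModel.from_records(samples)
             if not isinstance(samples, pd.DataFrame) else MaturationModel(samples))
    res = model.fit()
    return res.full_vs_null, res.island_effect


def leave_one_out_stability(
    tools: Sequence[ToolUseRecord] | pd.DataFrame,
    model_cls=OysterToolModel,
    influence_se: float = 1.0,
) -> StabilityReport:
    model = (model_cls.from_records(tools)
             if not isinstance(tools, pd.DataFrame) else model_cls(tools))
    return model.fit().leave_one_out(influence_se=influence_se)


# ---------------------------------------------------------------------------
# comparison batteries (t-test + bootstrap CI pairs)


@dataclass(frozen=True)
class GroupComparison:
    """A two-island comparison: Welch t-test plus per-island bootstrap CIs."""

    what: str
    test: TestResult | None
    ci: Mapping[str, BootstrapCI]
    overlap: bool | None
    skipped: bool = False
    skip_reason: str | None = None
    n: Mapping[str, int] = field(default_factory=dict)


def _split_seed(seed: int | None, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(k)]


def compare_prey_sizes(
    sizes: Sequence[SizeRecord],
    taxon: Taxon,
    method: str | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    min_n: int = 5,
) -> GroupComparison:
    """Island comparison of derived prey sizes for one taxon.

    If either island has fewer than ``min_n`` records the comparison is
    skipped with a report (too-rare taxa cannot support a size contrast,
    as with the tooth-lipped snail on the heavily foraged island).
    """
    method = method or default_size_method(taxon)
    groups: dict[str, list[float]] = {i.value: [] for i in Island}
    found = False
    for r in sizes:
        if r.taxon is taxon:
            found = True
            groups[r.island.value].append(compute_prey_size(r, method))
    if not found:
        raise ValueError(f"no size records for taxon {taxon.value}")
    ns = {k: len(v) for k, v in groups.items()}
    small = [k for k, n in ns.items() if n < min_n]
    if small:
        return GroupComparison(
            what=f"size:{taxon.value}", test=None, ci={}, overlap=None,
            skipped=True,
            skip_reason=f"fewer than {min_n} records on {', '.join(small)} "
                        f"(n = {ns})",
            n=ns,
        )
    s1, s2 = _split_seed(seed, 2)
    ci = {
        Island.KORAM.value: bootstrap_mean_ci(groups[Island.KORAM.value], n_boot, level, s1),
        Island.NOMSAO.value: bootstrap_mean_ci(groups[Island.NOMSAO.value], n_boot, level, s2),
    }
    test = welch_t_test(groups[Island.KORAM.value], groups[Island.NOMSAO.value])
    return GroupComparison(
        f"size:{taxon.value}", test, ci,
        ci[Island.KORAM.value].overlaps(ci[Island.NOMSAO.value]), n=ns,
    )


def compare_availability(
    transects: Sequence[SnailTransectPlot],
    species: Taxon,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> GroupComparison:
    """Island comparison of per-plot counts for one snail species."""
    if species not in (Taxon.P_SULCATUS, Taxon.C_BIFASCIATUS, Taxon.M_LABIO):
        raise ValueError(f"{species} is not a transect-counted species")
    groups: dict[str, list[int]] = {i.value: [] for i in Island}
    for p in transects:
        groups[p.island.value].append(p.count(species))
    for isl, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"need >= 2 transect plots on {isl}")
    s1, s2 = _split_seed(seed, 2)
    ci = {
        Island.KORAM.value: bootstrap_mean_ci(groups[Island.KORAM.value], n_boot, level, s1),
        Island.NOMSAO.value: bootstrap_mean_ci(groups[Island.NOMSAO.value], n_boot, level, s2),
    }
    test = welch_t_test(groups[Island.KORAM.value], groups[Island.NOMSAO.value])
    ns = {k: len(v) for k, v in groups.items()}
    return GroupComparison(
        f"availability:{species.value}", test, ci,
        ci[Island.KORAM.value].overlaps(ci[Island.NOMSAO.value]), n=ns,
    )


@dataclass(frozen=True)
class StoneSupplyComparison:
    counts_test: TestResult
    weights_test: TestResult
    count_ci: Mapping[tuple[str, str], BootstrapCI]
    weight_ci: Mapping[tuple[str, str], BootstrapCI]


def compare_stone_supply(
    quadrats: Sequence[StoneQuadrat],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> StoneSupplyComparison:
    """Island comparison of natural stone supply.

    Counts are compared per quadrat (are candidate stones equally
    available?), weights per stone (are available stones the same size?).
    Bootstrap CIs are reported separately per island x littoral zone.
    """
    counts: dict[str, list[int]] = {i.value: [] for i in Island}
    weights: dict[str, list[float]] = {i.value: [] for i in Island}
    by_zone_counts: dict[tuple[str, str], list[int]] = {}
    by_zone_weights: dict[tuple[str, str], list[float]] = {}
    for q in quadrats:
        counts[q.island.value].append(q.count)
        by_zone_counts.setdefault((q.island.value, q.zone.value), []).append(q.count)
        for s in q.stones:
            weights[q.island.value].append(s.weight_g)
            by_zone_weights.setdefault((q.island.value, q.zone.value), []).append(
                s.weight_g
            )
    for isl, vals in counts.items():
        if len(vals) < 2:
            raise ValueError(f"need >= 2 quadrats on {isl}")
    counts_test = welch_t_test(counts[Island.KORAM.value], counts[Island.NOMSAO.value])
    weights_test = welch_t_test(weights[Island.KORAM.value], weights[Island.NOMSAO.value])
    keys_c = sorted(by_zone_counts)
    keys_w = sorted(by_zone_weights)
    seeds = _split_seed(seed, len(keys_c) + len(keys_w))
    count_ci = {
        k: bootstrap_mean_ci(by_zone_counts[k], n_boot, level, s)
        for k, s in zip(keys_c, seeds[: len(keys_c)])
    }
    weight_ci = {}
    for k, s in zip(keys_w, seeds[len(keys_c):]):
        if by_zone_weights[k]:
            weight_ci[k] = bootstrap_mean_ci(by_zone_weights[k], n_boot, level, s)
        else:  # zone with no stones on one island: CI omitted, logged
            logger.info("no stones in zone %s; weight CI omitted", k)
    return StoneSupplyComparison(counts_test, weights_test, count_ci, weight_ci)
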