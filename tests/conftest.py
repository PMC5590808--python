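import pytest

import shellforage as sf


@pytest.fixture(scope="session")
def default_dataset() -> sf.SurveyDataset:
    """One synthetic survey drawn under the default study conditions."""
    return sf.generate_dataset(sf.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def scenario():
    """Default island profiles and consumption rates."""
    profiles, rates = sf.generate_consumption_scenario()
    return {p.island: p for p in profiles}, rates


def make_transects(island: sf.Island, totals: dict, n_plots: int = 14):
    """Plots whose per-species counts sum to the given island totals."""
    plots = []
    for i in range(n_plots):
        counts = {}
        for sp, total in totals.items():
            base, rem = divmod(int(total), n_plots)
            counts[sp] = base + (1 if i < rem else 0)
        plots.append(sf.SnailTransectPlot(island, i + 1, counts))
    return plots


@pytest.fixture(scope="session")
def observed_transects():
    """Transect plots reproducing the observed per-island species totals."""
    koram = make_transects(
        sf.Island.KORAM,
        {sf.Taxon.P_SULCATUS: 181, sf.Taxon.C_BIFASCIATUS: 50, sf.Taxon.M_LABIO: 4},
    )
    nomsao = make_transects(
        sf.Island.NOMSAO,
        {sf.Taxon.P_SULCATUS: 568, sf.Taxon.C_BIFASCIATUS: 22, sf.Taxon.M_LABIO: 68},
    )
    return koram + nomsao
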