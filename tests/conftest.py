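import numpy as np
import pandas as pd
import pytest

from phenobreak.simulate import (
    ClimateScenario,
    ReactionNorm,
    TrapDesign,
    generate_climate,
    generate_counts,
)


@pytest.fixture(scope="session")
def default_climate():
    """One default 28-year climate realisation, shared across tests."""
    return generate_climate(ClimateScenario(seed=11))


@pytest.fixture(scope="session")
def small_counts():
    """Trap table + truth for one taxon on two plots (default scenario)."""
    climate = generate_climate(ClimateScenario(seed=11))
    counts, truth = generate_counts(
        climate,
        {"taxA": ReactionNorm(baseline_event_day=190.0)},
        TrapDesign(n_plots=2),
        seed=12,
    )
    return counts, truth


def gaussian_trap_table(
    peak: float = 180.0,
    sd: float = 7.0,
    total: float = 1e4,
    start: int = 140,
    end: int = 230,
    step: int = 1,
    seed: int = 0,
    n_traps: int = 1,
) -> pd.DataFrame:
    """Dense Poisson samples of a Gaussian activity pulse (single taxon/plot)."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    edges = np.arange(start, end + step, step, dtype=float)
    s, e = edges[:-1], edges[1:]
    lam = total / n_traps * (stats.norm.cdf(e, peak, sd) - stats.norm.cdf(s, peak, sd))
    rows = []
    for t in range(n_traps):
        rows.append(
            pd.DataFrame(
                {
                    "taxon": "sim",
                    "plot": "p1",
                    "year": 2000,
                    "interval_start_doy": s,
                    "interval_end_doy": e,
                    "trap_id": f"trap{t + 1}",
                    "count": rng.poisson(lam),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
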