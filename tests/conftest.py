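import numpy as np
import pytest

from perioprp import (
    ALL_FDI,
    SITE_CODES,
    PeriodontalChart,
    SiteMeasurement,
    SiteSelector,
    SyntheticConfig,
    ToothRecord,
    generate_population,
)

POPULATION_SEED = 7


@pytest.fixture(scope="session")
def default_population():
    """2,000 charts from the default synthetic configuration, with latent
    class labels. Session-scoped: several tests read it, none mutate it."""
    cfg = SyntheticConfig(n_participants=2000)
    return generate_population(cfg, seed=POPULATION_SEED)


def random_small_chart(rng: np.random.Generator, max_teeth: int = 6,
                       max_mm: int = 8) -> PeriodontalChart:
    """A random chart with few present teeth and occasional missing values,
    for brute-force oracle comparisons."""
    n_present = int(rng.integers(0, max_teeth + 1))
    present = set(rng.choice(ALL_FDI, size=n_present, replace=False).tolist())
    teeth = {}
    for fdi in ALL_FDI:
        if fdi not in present:
            teeth[fdi] = ToothRecord(fdi=fdi, present=False)
            continue
        sites = {}
        for site in SITE_CODES:
            u = rng.random()
            if u < 0.08:
                sites[site] = None
            else:
                cal = int(rng.integers(0, max_mm + 1))
                ppd = int(rng.integers(0, max_mm + 1))
                if u < 0.12:
                    sites[site] = SiteMeasurement(ppd_mm=None, cal_mm=cal)
                elif u < 0.16:
                    sites[site] = SiteMeasurement(ppd_mm=ppd, cal_mm=None)
                else:
                    sites[site] = SiteMeasurement(ppd_mm=ppd, cal_mm=cal)
        teeth[fdi] = ToothRecord(fdi=fdi, present=True, sites=sites)
    return PeriodontalChart(
        participant_id=f"R{rng.integers(1 << 30)}", age_years=50, teeth=teeth
    )


def random_selector(rng: np.random.Generator) -> SiteSelector:
    grid = [(t, s) for t in ALL_FDI for s in SITE_CODES]
    size = int(rng.integers(1, len(grid) + 1))
    idx = rng.choice(len(grid), size=size, replace=False)
    return SiteSelector(frozenset(grid[i] for i in idx))
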