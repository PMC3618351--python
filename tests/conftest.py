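import numpy as np
import pytest

from xomap import (
    GROUP_SIZES,
    MarkerPanel,
    SimConfig,
    apply_missing_scenario,
    call_events,
    reference_panel,
    simulate_offspring,
)
from xomap.model import Marker
from xomap.simulate import default_chrom_map, scale_for_sex_averaged_mean


@pytest.fixture(scope="session")
def ref_panel():
    return reference_panel()


@pytest.fixture(scope="session")
def two_chrom_panel():
    """Tiny panel: markers every 10 Mbp on two short chromosomes."""
    markers = []
    for chrom, size in ((1, 100), (2, 60)):
        for i, pos in enumerate(range(5, size, 10), start=1):
            markers.append(Marker(chrom, pos * 10**6, f"t{chrom}m{i:02d}"))
    return MarkerPanel(markers, {1: 100, 2: 60})


@pytest.fixture(scope="session")
def dense_panel():
    """Single 100-Mbp chromosome with markers every 1 Mbp."""
    markers = [Marker(1, pos * 10**6, f"d{pos:03d}") for pos in range(1, 101)]
    return MarkerPanel(markers, {1: 100})


@pytest.fixture(scope="session")
def sim_cohort(ref_panel):
    """Paper-shaped synthetic cohort: 314 offspring, default maps scaled so
    the true sex-averaged mean is 13.9, light missingness."""
    scale = scale_for_sex_averaged_mean(13.9)
    cfg = SimConfig(
        panel=ref_panel,
        group_sizes=dict(GROUP_SIZES),
        map_cm={s: default_chrom_map(s, scale=scale) for s in ("female", "male")},
        interference_shape=10,
        missing_rate=0.005,
        error_rate=0.0,
        seed=42,
    )
    matrix, truth = simulate_offspring(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def clean_cohort(ref_panel):
    """No missingness, no error: calls are exact up to panel resolution."""
    cfg = SimConfig(panel=ref_panel, group_sizes={"FWT": 60, "MWT": 60},
                    missing_rate=0.0, error_rate=0.0, seed=7)
    matrix, truth = simulate_offspring(cfg)
    return cfg, matrix, truth


# --------------------------------------------------------------------------
# independent oracles (kept deliberately naive)


def brute_force_events(matrix, panel):
    """Independent re-scan: per sample and chromosome, count B<->H transitions
    between consecutive non-missing calls; returns dict sample_id -> total."""
    col = {mid: j for j, mid in enumerate(matrix.marker_ids)}
    totals = {}
    for i, sid in enumerate(matrix.sample_ids):
        n = 0
        for chrom in panel.chromosomes:
            states = [matrix.calls[i, col[m.marker_id]] for m in panel.markers_on(chrom)
                      if m.marker_id in col]
            obs = [s for s in states if s != -1]
            for a, b in zip(obs, obs[1:]):
                if a != b:
                    n += 1
        totals[sid] = n
    return totals


def exact_binom_two_sided(k, n, p=0.5):
    """Two-sided exact binomial p-value by summing all outcomes with
    probability <= that of the observed count."""
    from math import comb

    pmf = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    thresh = pmf[k] * (1 + 1e-9)
    return min(1.0, sum(q for q in pmf if q <= thresh))


def fisher_two_sided(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    pmf = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        pmf[x] = comb(r1, x) * comb(r2, c1 - x) / denom
    obs = pmf[a] * (1 + 1e-9)
    return min(1.0, sum(q for q in pmf.values() if q <= obs))
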