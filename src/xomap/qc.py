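"""Marker/sample quality control and missing-data scenario handling.

Filter order follows the genotyping protocol: marker call-rate filter
(retain strictly above the threshold), then transmission-distortion filter
(two-sided binomial test of 50/50 H/B inheritance among non-missing calls),
then sample call-rate filter computed over the retained markers.

Residual missing calls among retained markers x samples are resolved by one
of two extreme scenarios before event calling:

* ``conservative`` — a missing call never creates an event: each N is
  imputed by carrying the last observed state forward (backfilling at the
  chromosome start), which attains the minimum possible transition count.
* ``liberal`` — each missing call is assigned the state that maximises the
  event count (alternating against the previous state), the "recombination
  in all locations" extreme.

The two scenarios bracket every event total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import CODE_B, CODE_H, CODE_N, GenotypeMatrix, MarkerPanel

logger = logging.getLogger(__name__)

SCENARIOS = ("conservative", "liberal")


@dataclass
class QcConfig:
    snp_call_threshold: float = 0.95
    sample_call_threshold: float = 0.90
    distortion_alpha: float = 0.01
    scenario: str = "conservative"  # conservative | liberal | both
    distortion_exact: bool = True

    def __post_init__(self) -> None:
        for name in ("snp_call_threshold", "sample_call_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if not 0 < self.distortion_alpha < 1:
            raise ValueError(f"distortion_alpha must be in (0,1), got {self.distortion_alpha}")
        if self.scenario not in ("conservative", "liberal", "both"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class QcReport:
    dropped_markers: pd.DataFrame = field(default_factory=pd.DataFrame)
    dropped_samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_markers_in: int = 0
    n_samples_in: int = 0
    n_markers_out: int = 0
    n_samples_out: int = 0
    n_residual_missing: int = 0


def distortion_pvalue(n_h: int, n_called: int, exact: bool = True) -> float:
    """Two-sided p-value for H-count deviating from 50/50 transmission."""
    if n_called == 0:
        return 1.0
    if exact:
        return float(sps.binomtest(n_h, n_called, 0.5).pvalue)
    # normal approximation with continuity correction
    z = (abs(n_h - n_called / 2) - 0.5) / np.sqrt(n_called / 4)
    return float(2 * sps.norm.sf(max(z, 0.0)))


def filter_markers(matrix: GenotypeMatrix, config: QcConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop markers by call rate, then by transmission-ratio distortion.

    Call rates are pooled over the whole cohort.  A marker is retained only
    if its call rate is strictly above the threshold; survivors are then
    tested for distortion with an exact (default) two-sided binomial test at
    ``distortion_alpha``.  Each dropped marker carries one primary reason.
    """
    if matrix.n_samples == 0:
        raise ValueError("cannot run marker QC on an empty cohort")
    rates = matrix.marker_call_rate()
    rows = []
    keep = np.ones(matrix.n_markers, dtype=bool)
    for j in range(matrix.n_markers):
        if rates[j] <= config.snp_call_threshold:
            keep[j] = False
            rows.append({"marker_id": matrix.marker_ids[j], "reason": "low_call",
                         "call_rate": rates[j], "n_h": np.nan, "p_distortion": np.nan})
    for j in np.flatnonzero(keep):
        col = matrix.calls[:, j]
        called = col != CODE_N
        n_h = int((col == CODE_H).sum())
        p = distortion_pvalue(n_h, int(called.sum()), exact=config.distortion_exact)
        if p < config.distortion_alpha:
            keep[j] = False
            rows.append({"marker_id": matrix.marker_ids[j], "reason": "distortion",
                         "call_rate": rates[j], "n_h": n_h, "p_distortion": p})
    dropped = pd.DataFrame(rows, columns=["marker_id", "reason", "call_rate", "n_h", "p_distortion"])
    if len(dropped):
        logger.info("marker QC dropped %d/%d markers (%s)", len(dropped), matrix.n_markers,
                    dropped["reason"].value_counts().to_dict())
    return matrix.take_markers(keep), dropped


def filter_samples(matrix: GenotypeMatrix, config: QcConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop samples whose call rate over retained markers is not strictly
    above the sample threshold."""
    rates = matrix.sample_call_rate()
    keep = rates > config.sample_call_threshold
    dropped = pd.DataFrame(
        {
            "sample_id": [s for s, k in zip(matrix.sample_ids, keep) if not k],
            "group": [g for g, k in zip(matrix.groups, keep) if not k],
            "call_rate": rates[~keep],
        }
    )
    if len(dropped):
        logger.info("sample QC dropped %d/%d samples", len(dropped), matrix.n_samples)
    return matrix.take_samples(keep), dropped


@dataclass
class ScenarioMatrix:
    """A genotype matrix with missing calls resolved under one scenario.

    ``missing_mask`` marks the originally missing cells; cells that could not
    be resolved (a sample with <2 non-missing calls on a chromosome) remain N.
    """

    matrix: GenotypeMatrix
    missing_mask: np.ndarray
    scenario: str


def apply_missing_scenario(matrix: GenotypeMatrix, panel: MarkerPanel, scenario: str) -> ScenarioMatrix:
    """Impute residual missing calls under one of the two extreme scenarios."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    col_of = {mid: j for j, mid in enumerate(matrix.marker_ids)}
    chrom_cols = {}
    for chrom in panel.chromosomes:
        cols = [col_of[m.marker_id] for m in panel.markers_on(chrom) if m.marker_id in col_of]
        if cols:
            chrom_cols[chrom] = np.array(cols)
    calls = matrix.calls.copy()
    missing = matrix.calls == CODE_N
    for cols in chrom_cols.values():
        for i in range(matrix.n_samples):
            states = calls[i, cols]
            if (states != CODE_N).sum() < 2:
                if (states == CODE_N).any():
                    logger.debug("sample %s: <2 calls on a chromosome; contributes no intervals",
                                 matrix.sample_ids[i])
                continue
            calls[i, cols] = _impute_run(states, scenario)
    out = GenotypeMatrix(list(matrix.sample_ids), list(matrix.groups), list(matrix.marker_ids),
                         calls, matrix.filtered_mask.copy())
    return ScenarioMatrix(out, missing, scenario)


def _impute_run(states: np.ndarray, scenario: str) -> np.ndarray:
    """Impute N codes in one sample's per-chromosome call vector."""
    states = states.copy()
    obs = np.flatnonzero(states != CODE_N)
    if scenario == "conservative":
        # carry last observed state forward; backfill before the first call
        first = obs[0]
        states[:first] = states[first]
        for k in range(first + 1, len(states)):
            if states[k] == CODE_N:
                states[k] = states[k - 1]
    else:  # liberal: alternate against the previous assigned state
        first = obs[0]
        # leading run alternates backwards from the first observed call
        for k in range(first - 1, -1, -1):
            states[k] = 1 - states[k + 1]
        for k in range(first + 1, len(states)):
            if states[k] == CODE_N:
                states[k] = 1 - states[k - 1]
    return states


@dataclass
class QcResult:
    matrix: GenotypeMatrix
    panel: MarkerPanel
    report: QcReport


def run_qc(matrix: GenotypeMatrix, panel: MarkerPanel, config: QcConfig) -> QcResult:
    """Full QC pass: marker filters, sample filter, panel re-derivation.

    Chromosomes left with fewer than two retained markers are removed from
    the working panel (they define no interval).
    """
    n_markers_in, n_samples_in = matrix.n_markers, matrix.n_samples
    matrix, dropped_markers = filter_markers(matrix, config)
    matrix, dropped_samples = filter_samples(matrix, config)

    # re-derive the panel over retained markers; drop single-marker chromosomes
    retained = set(matrix.marker_ids)
    per_chrom: dict[int, int] = {}
    for m in panel.markers:
        if m.marker_id in retained:
            per_chrom[m.chrom] = per_chrom.get(m.chrom, 0) + 1
    usable = {m.marker_id for m in panel.markers
              if m.marker_id in retained and per_chrom[m.chrom] >= 2}
    if usable != retained:
        orphan = retained - usable
        logger.info("dropping %d orphan marker(s) on single-marker chromosomes", len(orphan))
        matrix = matrix.take_markers(np.array([mid in usable for mid in matrix.marker_ids]))
    qc_panel = panel.subset(matrix.marker_ids)

    report = QcReport(
        dropped_markers=dropped_markers,
        dropped_samples=dropped_samples,
        n_markers_in=n_markers_in,
        n_samples_in=n_samples_in,
        n_markers_out=matrix.n_markers,
        n_samples_out=matrix.n_samples,
        n_residual_missing=int((matrix.calls == CODE_N).sum()),
    )
    return QcResult(matrix, qc_panel, report)
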