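"""Crossover event calling and genetic-map aggregation.

A recombination event is a change of genotype state (B <-> H) between two
consecutive retained markers on the same chromosome.  Each interval carries
at most one detectable event per meiosis: an even number of true crossovers
inside one interval cancels out and is invisible to the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CODE_N, GenotypeMatrix, Interval, MarkerPanel, round_half_up
from .qc import ScenarioMatrix

GROUP_SEX = {"FWT": "female", "FKO": "female", "MWT": "male", "MKO": "male"}


@dataclass
class CrossoverCallSet:
    """Per-sample, per-interval binary event calls.

    ``assessed`` marks, per sample and interval, whether both flanking calls
    were originally observed (conservative scenario) — unassessed cells still
    carry the scenario-imputed event bit, so per-sample and per-chromosome
    totals are consistent, but interval-level proportions exclude them from
    the denominator.
    """

    sample_ids: list[str]
    groups: list[str]
    intervals: list[Interval]
    events: np.ndarray  # (n_samples, n_intervals) int8, values {0,1}
    assessed: np.ndarray  # (n_samples, n_intervals) bool
    scenario: str = "conservative"

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int8)
        self.assessed = np.asarray(self.assessed, dtype=bool)
        shape = (len(self.sample_ids), len(self.intervals))
        if self.events.shape != shape or self.assessed.shape != shape:
            raise ValueError(f"event/assessed matrices must have shape {shape}")
        if not np.isin(self.events, [0, 1]).all():
            raise ValueError("event cells must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def chromosomes(self) -> list[int]:
        return sorted({iv.chrom for iv in self.intervals})

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups], dtype=bool)

    def interval_cols(self, chrom: int) -> np.ndarray:
        return np.array([j for j, iv in enumerate(self.intervals) if iv.chrom == chrom])

    def per_sample_total(self) -> np.ndarray:
        return self.events.sum(axis=1)

    def per_interval_total(self, group: str | None = None) -> np.ndarray:
        rows = slice(None) if group is None else self.group_mask(group)
        return self.events[rows].sum(axis=0)

    def per_chrom_total(self, group: str | None = None) -> dict[int, int]:
        totals = self.per_interval_total(group)
        return {c: int(totals[self.interval_cols(c)].sum()) for c in self.chromosomes}

    def grand_total(self) -> int:
        return int(self.events.sum())

    def interval_counts(self, group: str) -> pd.DataFrame:
        """Per interval: events ``x`` and assessed denominator ``n`` for a group."""
        rows = self.group_mask(group)
        ev = self.events[rows]
        ok = self.assessed[rows]
        x = (ev * ok).sum(axis=0)
        n = ok.sum(axis=0)
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "interval": [iv.name for iv in self.intervals],
                "x": x.astype(int),
                "n": n.astype(int),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.events, columns=[iv.name for iv in self.intervals])
        df.insert(0, "group", self.groups)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def call_events(scenario_matrix: ScenarioMatrix, panel: MarkerPanel) -> CrossoverCallSet:
    """Scan consecutive retained markers and emit one event per state change.

    Expects a QC'd, scenario-resolved matrix (see
    :func:`xomap.qc.apply_missing_scenario`).  Cells still missing after
    scenario handling (degenerate chromosomes) yield no event and are marked
    unassessed, as are intervals whose flanking calls were imputed.
    """
    matrix = scenario_matrix.matrix
    col_of = {mid: j for j, mid in enumerate(matrix.marker_ids)}
    intervals = [iv for iv in panel.intervals()
                 if iv.left_marker in col_of and iv.right_marker in col_of]
    n_s, n_iv = matrix.n_samples, len(intervals)
    events = np.zeros((n_s, n_iv), dtype=np.int8)
    assessed = np.zeros((n_s, n_iv), dtype=bool)
    for j, iv in enumerate(intervals):
        left = col_of[iv.left_marker]
        right = col_of[iv.right_marker]
        a = matrix.calls[:, left]
        b = matrix.calls[:, right]
        resolvable = (a != CODE_N) & (b != CODE_N)
        events[:, j] = np.where(resolvable & (a != b), 1, 0)
        observed = ~scenario_matrix.missing_mask[:, left] & ~scenario_matrix.missing_mask[:, right]
        assessed[:, j] = resolvable if scenario_matrix.scenario == "liberal" else (resolvable & observed)
    return CrossoverCallSet(list(matrix.sample_ids), list(matrix.groups), intervals,
                            events, assessed, scenario_matrix.scenario)


def chrom_stats(calls: CrossoverCallSet, panel: MarkerPanel,
                group_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-group, per-chromosome event counts, cM and cM/Mbp.

    cM = 100 x count / n; cM/Mbp divides by the first-to-last retained-marker
    physical length.  ``group_sizes`` defaults to the sample counts present
    in the call set.
    """
    groups = sorted(set(calls.groups), key=lambda g: list(GROUP_SEX).index(g) if g in GROUP_SEX else 99)
    if group_sizes is None:
        group_sizes = {g: int(calls.group_mask(g).sum()) for g in groups}
    rows = []
    for g in groups:
        n = group_sizes[g]
        if n <= 0:
            raise ValueError(f"group {g} has no samples")
        totals = calls.per_chrom_total(g)
        for chrom in calls.chromosomes:
            span = panel.span_mbp(chrom)
            cm = 100.0 * totals[chrom] / n
            rows.append({"group": g, "chrom": chrom, "count": totals[chrom], "n": n,
                         "cM": cm, "cM_per_Mbp": cm / span, "span_mbp": span})
    return pd.DataFrame(rows)


def chrom_stats_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Wide per-chromosome table (counts + cM/Mbp rounded to 2 decimals)."""
    out = {}
    for g, sub in stats.groupby("group", sort=False):
        sub = sub.set_index("chrom")
        out[f"{g}_count"] = sub["count"]
        out[f"{g}_cM_per_Mbp"] = sub["cM_per_Mbp"].map(lambda v: round_half_up(v, 2))
    return pd.DataFrame(out)


def group_means(calls: CrossoverCallSet,
                group_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Mean events per meiosis (total/n), SEM and n per group.

    SEM is the sample standard deviation of per-sample totals divided by
    sqrt(n); it is NaN for groups with fewer than two samples.
    """
    totals = calls.per_sample_total()
    rows = []
    for g in sorted(set(calls.groups), key=lambda g: list(GROUP_SEX).index(g) if g in GROUP_SEX else 99):
        mask = calls.group_mask(g)
        n = int(group_sizes[g]) if group_sizes else int(mask.sum())
        t = totals[mask]
        mean = float(t.sum()) / n
        sem = float(t.std(ddof=1) / np.sqrt(n)) if n >= 2 and mask.sum() >= 2 else float("nan")
        rows.append({"group": g, "mean": mean, "sem": sem, "n": n, "total": int(t.sum())})
    return pd.DataFrame(rows).set_index("group")


def sex_averaged(mean_female: float, mean_male: float) -> float:
    """Unweighted mean of the female and male per-meiosis means."""
    return (mean_female + mean_male) / 2.0
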