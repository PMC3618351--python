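"""Group comparisons, interval-level proportions and detection power.

Implements the comparisons used for the backcross analysis: Mann-Whitney
with Bonferroni families, Agresti-Coull 95% intervals and two-sided Fisher
exact tests per consecutive-marker interval, centromeric/telomeric region
averages, the chromosome-size effect, and detection power against simulator
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calling import CrossoverCallSet, GROUP_SEX
from .model import MarkerPanel
from .simulate import TrueMeiosisSet


@dataclass
class ComparisonResult:
    test: str
    groups: tuple[str, str]
    statistic: float
    p_value: float
    family_size: int
    family_alpha: float = 0.05

    @property
    def threshold(self) -> float:
        return self.family_alpha / self.family_size

    @property
    def significant(self) -> bool:
        return self.p_value < self.threshold


def mann_whitney_groups(a: np.ndarray, b: np.ndarray, family_size: int = 4,
                        family_alpha: float = 0.05,
                        labels: tuple[str, str] = ("A", "B")) -> ComparisonResult:
    """Two-sided Mann-Whitney U (normal approximation with tie and continuity
    corrections) with a Bonferroni family threshold.

    If the pooled values are all identical the variance is zero and p = 1 by
    convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return ComparisonResult("mann-whitney", labels, len(a) * len(b) / 2.0, 1.0,
                                family_size, family_alpha)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return ComparisonResult("mann-whitney", labels, float(res.statistic),
                            float(res.pvalue), family_size, family_alpha)


def agresti_coull_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Agresti-Coull binomial confidence interval, clipped to [0, 1].

    With z the standard-normal quantile at (1+conf)/2: n~ = n + z^2,
    p~ = (x + z^2/2)/n~, CI = p~ +/- z sqrt(p~(1-p~)/n~).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    z = sps.norm.ppf((1 + conf) / 2)
    n_t = n + z * z
    p_t = (x + z * z / 2) / n_t
    half = z * np.sqrt(p_t * (1 - p_t) / n_t)
    return max(0.0, p_t - half), min(1.0, p_t + half)


DEFAULT_COMPARISONS = (("FWT", "FKO"), ("MWT", "MKO"))


def fisher_intervals(calls: CrossoverCallSet,
                     comparisons=DEFAULT_COMPARISONS,
                     family_alpha: float = 0.05,
                     conf: float = 0.95,
                     proportion_cutoff: float | None = None) -> pd.DataFrame:
    """Per-interval proportions, Agresti-Coull CIs and Fisher exact tests.

    The Bonferroni family size is the number of testable intervals times the
    number of comparisons, derived from the post-QC interval set.  With
    ``proportion_cutoff`` set, only intervals whose proportions in both
    compared groups fall below the cutoff are tested (low-recombination
    sensitivity re-analysis); the family shrinks accordingly.
    """
    per_group = {}
    for g in set(g for pair in comparisons for g in pair):
        df = calls.interval_counts(g)
        per_group[g] = df
    base = per_group[comparisons[0][0]][["chrom", "interval"]].copy()

    rows = []
    for wt, ko in comparisons:
        w, k = per_group[wt], per_group[ko]
        for j in range(len(base)):
            xw, nw = int(w["x"][j]), int(w["n"][j])
            xk, nk = int(k["x"][j]), int(k["n"][j])
            row = {"chrom": base["chrom"][j], "interval": base["interval"][j],
                   "comparison": f"{wt}-vs-{ko}",
                   "x_wt": xw, "n_wt": nw, "x_ko": xk, "n_ko": nk}
            if nw == 0 or nk == 0:
                row.update({"testable": False, "p": np.nan})
            else:
                pw, pk = xw / nw, xk / nk
                row["p_wt"], row["p_ko"] = pw, pk
                row["ci_wt_lo"], row["ci_wt_hi"] = agresti_coull_ci(xw, nw, conf)
                row["ci_ko_lo"], row["ci_ko_hi"] = agresti_coull_ci(xk, nk, conf)
                testable = True
                if proportion_cutoff is not None and not (pw < proportion_cutoff and pk < proportion_cutoff):
                    testable = False
                row["testable"] = testable
                if testable:
                    _, p = sps.fisher_exact([[xw, nw - xw], [xk, nk - xk]], alternative="two-sided")
                    row["p"] = float(p)
                else:
                    row["p"] = np.nan
            rows.append(row)
    out = pd.DataFrame(rows)
    family_size = int(out["testable"].sum())
    out.attrs["family_size"] = family_size
    out.attrs["family_alpha"] = family_alpha
    out.attrs["threshold"] = family_alpha / family_size if family_size else np.nan
    out["significant"] = out["p"] < out.attrs["threshold"]
    return out


@dataclass
class RegionSpec:
    """A named set of intervals, each given as (chrom, selector) where the
    selector is ``"first"``, ``"last"`` or an explicit interval name."""

    name: str
    members: list[tuple[int, str]] = field(default_factory=list)

    def resolve(self, calls: CrossoverCallSet) -> list[int]:
        cols = []
        for chrom, sel in self.members:
            chrom_cols = calls.interval_cols(chrom)
            if len(chrom_cols) == 0:
                raise ValueError(f"region {self.name!r}: chromosome {chrom} has no intervals after QC")
            if sel == "first":
                cols.append(int(chrom_cols[0]))
            elif sel == "last":
                cols.append(int(chrom_cols[-1]))
            else:
                match = [j for j in chrom_cols if calls.intervals[j].name == sel]
                if not match:
                    raise ValueError(f"region {self.name!r}: interval {sel!r} not found on chromosome {chrom}")
                cols.append(int(match[0]))
        if not cols:
            raise ValueError(f"region {self.name!r} is empty")
        return cols


def centromeric_region() -> RegionSpec:
    return RegionSpec("centromeric", [(c, "first") for c in (1, 7, 8, 11, 18, 19)])


def telomeric_region() -> RegionSpec:
    return RegionSpec("telomeric", [(c, "last") for c in (1, 2, 3, 4, 5, 8, 9, 11, 14, 16, 17, 19)])


def region_compare(calls: CrossoverCallSet, region: RegionSpec,
                   group_a: str = "FWT", group_b: str = "MWT",
                   family_size: int = 4, family_alpha: float = 0.05):
    """Compare mean per-interval event proportions of a region between two
    groups (Mann-Whitney over the region's interval proportions).

    Returns (ComparisonResult, summary DataFrame with mean +/- SEM over the
    region's intervals per group, n = number of intervals).
    """
    cols = region.resolve(calls)
    summaries, props = {}, {}
    for g in (group_a, group_b):
        df = calls.interval_counts(g)
        p = np.array([df["x"][j] / df["n"][j] if df["n"][j] else np.nan for j in cols])
        if np.isnan(p).any():
            raise ValueError(f"region {region.name!r}: interval with empty denominator in group {g}")
        props[g] = p
        summaries[g] = {
            "group": g, "region": region.name, "n_intervals": len(p),
            "mean": float(p.mean()),
            "sem": float(p.std(ddof=1) / np.sqrt(len(p))) if len(p) >= 2 else np.nan,
        }
    result = mann_whitney_groups(props[group_a], props[group_b], family_size,
                                 family_alpha, labels=(group_a, group_b))
    return result, pd.DataFrame([summaries[group_a], summaries[group_b]])


def size_vs_rate(calls: CrossoverCallSet, panel: MarkerPanel,
                 chrom_big: int = 1, chrom_small: int = 19,
                 groups: tuple[str, ...] = ("FWT", "MWT"),
                 group_sizes: dict[str, int] | None = None) -> float:
    """Ratio of pooled per-sample per-Mbp event rates, small vs big chromosome.

    Pools the given groups (wild-type female + male by default); rates use
    the first-to-last retained-marker span of each chromosome.
    """

    def rate(chrom: int) -> float:
        count = sum(calls.per_chrom_total(g)[chrom] for g in groups)
        if group_sizes is None:
            n = sum(int(calls.group_mask(g).sum()) for g in groups)
        else:
            n = sum(group_sizes[g] for g in groups)
        return count / n / panel.span_mbp(chrom)

    r_big = rate(chrom_big)
    if r_big == 0:
        raise ValueError(f"chromosome {chrom_big} has zero event rate")
    return rate(chrom_small) / r_big


@dataclass
class DetectionPower:
    fraction: float
    n_called: int
    n_true: int
    n_true_out_of_span: int
    n_cancelled_in_span: int

    @property
    def residual(self) -> int:
        """True events lost to missing-data/scenario effects (whatever is not
        explained by span coverage or within-interval cancellation)."""
        return self.n_true - self.n_true_out_of_span - self.n_cancelled_in_span - self.n_called


def detection_power(calls: CrossoverCallSet, truth: TrueMeiosisSet,
                    panel: MarkerPanel) -> DetectionPower:
    """Fraction of true crossovers recovered by event calling, with a loss
    decomposition (outside first-to-last-marker span; even-count cancellation
    within an interval; residual missing/scenario effects)."""
    if set(calls.sample_ids) != set(truth.sample_ids):
        raise ValueError("call set and truth set cover different samples")
    n_true = truth.total()
    if n_true == 0:
        raise ValueError("truth set contains zero crossovers; detection power is undefined")
    n_called = calls.grand_total()

    out_of_span = n_true - truth.total_in_span(panel)
    cancelled = 0
    edges = {c: np.array([m.pos_bp for m in panel.markers_on(c)]) for c in panel.chromosomes}
    for (sid, chrom), xs in truth.crossovers.items():
        if chrom not in edges or len(xs) == 0:
            continue
        e = edges[chrom]
        inside = xs[(xs > e[0]) & (xs <= e[-1])]
        if len(inside) == 0:
            continue
        which = np.searchsorted(e, inside, side="left") - 1  # interval index per event
        counts = np.bincount(which, minlength=len(e) - 1)
        cancelled += int(np.sum(counts - counts % 2))
    return DetectionPower(n_called / n_true, n_called, n_true, out_of_span, cancelled)
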