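"""Core data types: marker panels and backcross genotype matrices.

Physical coordinates are stored in base pairs (1-based); every reported
distance is converted to Mbp by dividing by 1e6.  Genotype calls use three
codes: ``B`` (homozygous C57BL/6J), ``H`` (heterozygous, i.e. the gamete
carried the BALB/c allele) and ``N`` (missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

GROUPS = ("FWT", "FKO", "MWT", "MKO")

#: genotype codes -> compact int8 representation used in matrices
CODE_B, CODE_H, CODE_N = 0, 1, -1
_CODE_OF = {"B": CODE_B, "H": CODE_H, "N": CODE_N}
_CHAR_OF = {v: k for k, v in _CODE_OF.items()}


class FormatError(ValueError):
    """Raised when an input table violates the documented file contract."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention used in reported tables."""
    q = Decimal("1") if ndigits == 0 else Decimal("1." + "0" * ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class Marker(NamedTuple):
    chrom: int
    pos_bp: int
    marker_id: str


class Interval(NamedTuple):
    """A pair of consecutive retained markers on one chromosome."""

    chrom: int
    left_marker: str
    right_marker: str
    left_pos: int
    right_pos: int

    @property
    def span_mbp(self) -> float:
        return (self.right_pos - self.left_pos) / 1e6

    @property
    def name(self) -> str:
        return f"{self.left_marker}|{self.right_marker}"


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered physical map of SNP markers across autosomes.

    Parameters
    ----------
    markers
        Markers sorted by (chrom, pos).  Sorting is enforced at construction.
    chrom_sizes
        Autosome id -> chromosome size in Mbp.
    """

    markers: tuple[Marker, ...]
    chrom_sizes: Mapping[int, float]

    def __init__(self, markers: Iterable[Marker], chrom_sizes: Mapping[int, float]):
        markers = tuple(sorted((Marker(*m) for m in markers), key=lambda m: (m.chrom, m.pos_bp)))
        object.__setattr__(self, "markers", markers)
        object.__setattr__(self, "chrom_sizes", dict(chrom_sizes))
        self._validate()

    def _validate(self) -> None:
        seen_pos: set[tuple[int, int]] = set()
        seen_ids: set[str] = set()
        per_chrom: dict[int, int] = {}
        for m in self.markers:
            if not (1 <= m.chrom <= 19):
                raise FormatError(f"marker {m.marker_id!r}: chromosome {m.chrom} is not an autosome id in 1..19")
            if m.chrom not in self.chrom_sizes:
                raise FormatError(f"marker {m.marker_id!r}: no chromosome size for chrom {m.chrom}")
            if m.pos_bp <= 0:
                raise FormatError(f"marker {m.marker_id!r}: non-positive position {m.pos_bp}")
            if m.pos_bp > self.chrom_sizes[m.chrom] * 1e6:
                raise FormatError(
                    f"marker {m.marker_id!r}: position {m.pos_bp} exceeds chrom {m.chrom} "
                    f"size {self.chrom_sizes[m.chrom]} Mbp"
                )
            key = (m.chrom, m.pos_bp)
            if key in seen_pos:
                raise FormatError(f"duplicate position {m.pos_bp} on chromosome {m.chrom}")
            seen_pos.add(key)
            if m.marker_id in seen_ids:
                raise FormatError(f"duplicate marker id {m.marker_id!r}")
            seen_ids.add(m.marker_id)
            per_chrom[m.chrom] = per_chrom.get(m.chrom, 0) + 1
        for chrom, n in per_chrom.items():
            if n < 2:
                raise FormatError(f"chromosome {chrom} has a single marker; at least 2 are required")

    # -- accessors ---------------------------------------------------------
    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def chromosomes(self) -> list[int]:
        return sorted({m.chrom for m in self.markers})

    def markers_on(self, chrom: int) -> list[Marker]:
        return [m for m in self.markers if m.chrom == chrom]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def intervals(self) -> list[Interval]:
        out: list[Interval] = []
        for chrom in self.chromosomes:
            ms = self.markers_on(chrom)
            for a, b in zip(ms, ms[1:]):
                out.append(Interval(chrom, a.marker_id, b.marker_id, a.pos_bp, b.pos_bp))
        return out

    def span_mbp(self, chrom: int) -> float:
        """First-to-last marker physical length in Mbp."""
        ms = self.markers_on(chrom)
        return (ms[-1].pos_bp - ms[0].pos_bp) / 1e6

    def subset(self, keep_ids: Sequence[str]) -> "MarkerPanel":
        keep = set(keep_ids)
        return MarkerPanel([m for m in self.markers if m.marker_id in keep], self.chrom_sizes)


@dataclass
class GenotypeMatrix:
    """Samples x markers call matrix for a backcross cohort.

    ``calls`` holds int8 codes (see :data:`CODE_B` etc.); ``marker_ids``
    fixes the column order and must match the panel the matrix was read
    against.  ``filtered_mask`` distinguishes cells that were never called
    from cells removed by QC (True = removed by a filter).
    """

    sample_ids: list[str]
    groups: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    filtered_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise FormatError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        bad = ~np.isin(self.calls, [CODE_B, CODE_H, CODE_N])
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(f"invalid call code at sample row {i}, marker column {j}")
        for g in self.groups:
            if g not in GROUPS:
                raise FormatError(f"unknown group label {g!r}; expected one of {GROUPS}")
        if self.filtered_mask is None:
            self.filtered_mask = np.zeros_like(self.calls, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def samples_in(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups], dtype=bool)

    def marker_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_markers)
        return (self.calls != CODE_N).sum(axis=0) / self.n_samples

    def sample_call_rate(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.zeros(self.n_samples)
        return (self.calls != CODE_N).sum(axis=1) / self.n_markers

    def take_markers(self, keep: np.ndarray, filtered_out: bool = False) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            list(self.sample_ids),
            list(self.groups),
            [self.marker_ids[j] for j in idx],
            self.calls[:, idx].copy(),
            self.filtered_mask[:, idx].copy(),
        )

    def take_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            [self.groups[i] for i in idx],
            list(self.marker_ids),
            self.calls[idx, :].copy(),
            self.filtered_mask[idx, :].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        chars = np.vectorize(_CHAR_OF.get)(self.calls) if self.calls.size else np.empty(self.calls.shape, dtype=object)
        df = pd.DataFrame(chars, columns=self.marker_ids)
        df.insert(0, "group", self.groups)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class PanelSummary:
    """Per-chromosome and genome-wide marker spacing statistics."""

    per_chrom: pd.DataFrame  # indexed by chrom: n_markers, mean/min/max distance, length
    n_markers: int
    n_chromosomes: int
    total_length_mbp: float
    mean_distance_mbp: float
    mean_max_distance_mbp: float

    @property
    def n_intervals(self) -> int:
        return self.n_markers - self.n_chromosomes

    def to_frame(self, ndigits: int = 2) -> pd.DataFrame:
        df = self.per_chrom.copy()
        for c in ("mean_dist_mbp", "min_dist_mbp", "max_dist_mbp"):
            df[c] = df[c].map(lambda v: round_half_up(v, ndigits))
        df["length_mbp"] = df["length_mbp"].map(lambda v: round_half_up(v, 1))
        return df


# ---------------------------------------------------------------------------
# readers / writers


def read_chrom_sizes(path) -> dict[int, float]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["chrom", "size_mbp"], path)
    return {int(r.chrom): float(r.size_mbp) for r in df.itertuples()}


def read_panel(path, chrom_sizes: Mapping[int, float] | str) -> MarkerPanel:
    """Read a marker panel from TSV (columns chrom, pos_bp, marker_id).

    ``chrom_sizes`` is either a mapping or a path to a companion TSV with
    columns chrom, size_mbp.
    """
    if not isinstance(chrom_sizes, Mapping):
        chrom_sizes = read_chrom_sizes(chrom_sizes)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["chrom", "pos_bp", "marker_id"], path)
    markers = []
    for lineno, row in enumerate(df.itertuples(), start=2):
        try:
            chrom = int(row.chrom)
            pos = int(row.pos_bp)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}, line {lineno}: non-numeric chrom/pos ({row.chrom!r}, {row.pos_bp!r})") from exc
        markers.append(Marker(chrom, pos, str(row.marker_id)))
    return MarkerPanel(markers, chrom_sizes)


def write_panel(panel: MarkerPanel, path, sizes_path=None) -> None:
    pd.DataFrame(panel.markers, columns=["chrom", "pos_bp", "marker_id"]).to_csv(path, sep="\t", index=False)
    if sizes_path is not None:
        rows = sorted(panel.chrom_sizes.items())
        pd.DataFrame(rows, columns=["chrom", "size_mbp"]).to_csv(sizes_path, sep="\t", index=False)


def read_genotypes(path, panel: MarkerPanel, sep: str = "\t") -> GenotypeMatrix:
    """Read a genotype table: sample_id, group, then one call column per marker."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    expected = ["sample_id", "group"] + panel.marker_ids
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: columns do not match panel; expected {len(expected)} columns "
            f"starting {expected[:4]}..., got {len(df.columns)} starting {list(df.columns)[:4]}..."
        )
    call_cols = df.columns[2:]
    calls = np.full((len(df), len(call_cols)), CODE_N, dtype=np.int8)
    for j, col in enumerate(call_cols):
        for i, v in enumerate(df[col]):
            code = _CODE_OF.get(v)
            if code is None:
                raise FormatError(f"{path}: invalid call code {v!r} at sample row {i}, marker column {j} ({col})")
            calls[i, j] = code
    return GenotypeMatrix(list(df["sample_id"]), list(df["group"]), list(call_cols), calls)


def write_genotypes(matrix: GenotypeMatrix, path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# panel summary


def summarize_panel(panel: MarkerPanel) -> PanelSummary:
    """Per-chromosome spacing statistics plus genome totals.

    The genome-wide mean inter-marker distance is total first-to-last
    physical length divided by the number of consecutive-marker intervals
    (markers minus chromosomes); the "resolution power" is the mean of the
    per-chromosome maximal distances.
    """
    rows = []
    for chrom in panel.chromosomes:
        ms = panel.markers_on(chrom)
        gaps = np.diff([m.pos_bp for m in ms]) / 1e6
        rows.append(
            {
                "chrom": chrom,
                "n_markers": len(ms),
                "mean_dist_mbp": gaps.mean(),
                "min_dist_mbp": gaps.min(),
                "max_dist_mbp": gaps.max(),
                "length_mbp": gaps.sum(),
            }
        )
    per_chrom = pd.DataFrame(rows).set_index("chrom")
    n_markers = panel.n_markers
    n_chroms = len(panel.chromosomes)
    total = float(per_chrom["length_mbp"].sum())
    return PanelSummary(
        per_chrom=per_chrom,
        n_markers=n_markers,
        n_chromosomes=n_chroms,
        total_length_mbp=total,
        mean_distance_mbp=total / (n_markers - n_chroms),
        mean_max_distance_mbp=float(per_chrom["max_dist_mbp"].mean()),
    )
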