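"""Synthetic backcross meiosis with crossover interference.

Gametes are simulated per chromosome from a stationary gamma renewal
process on the four-strand bundle (shape ``nu``, mean inter-chiasma
distance 50 cM, i.e. two chiasmata per Morgan), each chiasma being
retained on the transmitted chromatid with probability 1/2, so the
expected crossover count per gamete is map_cM/100 for any ``nu``.
``nu = 1`` degenerates to a Poisson process (no interference); larger
shapes give the underdispersed, evenly spaced crossovers characteristic
of murine meiosis.  Genetic-to-physical mapping is linear within each
chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CODE_B, CODE_H, CODE_N, GenotypeMatrix, MarkerPanel
from .datasets import CHROM_SIZES_MBP, CM_PER_MBP_WT, GROUP_SIZES

_MEAN_CHIASMA_SPACING_CM = 50.0  # bundle scale: 2 chiasmata per Morgan


def sex_of_group(group: str) -> str:
    """Analysis groups encode the sex of the transmitting F1 parent."""
    return "female" if group.startswith("F") else "male"


def default_chrom_map(sex: str, scale: float = 1 / 0.83, basis: str = "size") -> dict[int, float]:
    """Per-chromosome genetic lengths (cM) derived from the detected wild-type
    map densities.

    cM = detected density (cM/Mbp) x chromosome extent (Mbp) x scale.  With
    ``basis="size"`` the extent is the full NCBI chromosome size; with
    ``basis="span"`` it is the first-to-last marker length, which makes the
    scale-1 map equal the detected map exactly.  ``scale`` inflates the truth
    relative to the detected map (default 1/0.83, compensating for the ~17%
    of events a sparse panel misses).
    """
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    if scale <= 0:
        raise ValueError(f"scale must be > 0, got {scale}")
    if basis == "size":
        extent = {c: float(CHROM_SIZES_MBP[c]) for c in CHROM_SIZES_MBP}
    elif basis == "span":
        from .datasets import reference_panel

        panel = reference_panel()
        extent = {c: panel.span_mbp(c) for c in panel.chromosomes}
    else:
        raise ValueError(f"basis must be 'size' or 'span', got {basis!r}")
    dens = CM_PER_MBP_WT[sex]
    return {int(c): float(dens.loc[c]) * extent[int(c)] * scale for c in dens.index}


def scale_for_sex_averaged_mean(target: float, basis: str = "size") -> float:
    """Scale factor making the sex-averaged expected crossover count per
    meiosis (mean of female and male genome map lengths / 100) equal ``target``."""
    f = sum(default_chrom_map("female", scale=1.0, basis=basis).values())
    m = sum(default_chrom_map("male", scale=1.0, basis=basis).values())
    return target / ((f + m) / 200.0)


@dataclass
class SimConfig:
    """Configuration for :func:`simulate_offspring`."""

    panel: MarkerPanel
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(GROUP_SIZES))
    map_cm: dict[str, dict[int, float]] | None = None  # sex -> chrom -> cM
    interference_shape: float = 10.0
    missing_rate: float = 0.005
    error_rate: float = 0.0
    obligate_chiasma: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interference_shape < 1:
            raise ValueError(f"interference shape must be >= 1, got {self.interference_shape}")
        for name in ("missing_rate", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.map_cm is None:
            self.map_cm = {s: default_chrom_map(s) for s in ("female", "male")}
        for sex, cmap in self.map_cm.items():
            for chrom, cm in cmap.items():
                if cm < 0:
                    raise ValueError(f"negative map length {cm} for chrom {chrom} ({sex})")


@dataclass
class TrueMeiosisSet:
    """Ground truth for a simulated cohort: per offspring and chromosome, the
    crossover positions (bp) on the transmitted gamete and the allele carried
    at the chromosome start (0 = C57BL/6J, 1 = BALB/c)."""

    sample_ids: list[str]
    crossovers: dict[tuple[str, int], np.ndarray]
    start_allele: dict[tuple[str, int], int]
    chromosomes: list[int]

    def count(self, sample_id: str, chrom: int) -> int:
        return len(self.crossovers[(sample_id, chrom)])

    def total(self) -> int:
        return sum(len(v) for v in self.crossovers.values())

    def total_in_span(self, panel: MarkerPanel) -> int:
        """Crossovers falling between the first and last panel marker."""
        n = 0
        for (sid, chrom), xs in self.crossovers.items():
            ms = panel.markers_on(chrom)
            if len(ms) < 2:
                continue
            n += int(np.sum((xs > ms[0].pos_bp) & (xs <= ms[-1].pos_bp)))
        return n

    def segments(self, sample_id: str, chrom: int, chrom_size_bp: int) -> list[tuple[int, int, int]]:
        """(start, end, allele) segments of the transmitted haplotype."""
        xs = self.crossovers[(sample_id, chrom)]
        allele = self.start_allele[(sample_id, chrom)]
        bounds = [0, *map(int, xs), chrom_size_bp]
        out = []
        for i in range(len(bounds) - 1):
            out.append((bounds[i], bounds[i + 1], (allele + i) % 2))
        return out

    def allele_at(self, sample_id: str, chrom: int, pos_bp: int) -> int:
        xs = self.crossovers[(sample_id, chrom)]
        return (self.start_allele[(sample_id, chrom)] + int(np.searchsorted(xs, pos_bp))) % 2

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid in self.sample_ids:
            for chrom in self.chromosomes:
                xs = self.crossovers[(sid, chrom)]
                rows.append(
                    {
                        "sample_id": sid,
                        "chrom": chrom,
                        "start_allele": self.start_allele[(sid, chrom)],
                        "crossovers_bp": ",".join(str(int(x)) for x in xs),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TrueMeiosisSet":
        df = pd.read_csv(path, sep="\t", dtype={"crossovers_bp": str}, keep_default_na=False)
        crossovers, start = {}, {}
        sample_ids: list[str] = []
        for r in df.itertuples():
            key = (str(r.sample_id), int(r.chrom))
            xs = [int(x) for x in str(r.crossovers_bp).split(",") if x]
            crossovers[key] = np.array(xs, dtype=np.int64)
            start[key] = int(r.start_allele)
            if str(r.sample_id) not in sample_ids:
                sample_ids.append(str(r.sample_id))
        chroms = sorted(df["chrom"].astype(int).unique())
        return cls(sample_ids, crossovers, start, chroms)


# ---------------------------------------------------------------------------
# gamete simulation


def _stationary_chiasmata(length_cm: float, nu: float, rng: np.random.Generator) -> np.ndarray:
    """Chiasma positions (cM) of a stationary gamma renewal process on
    [0, length_cm] with shape ``nu`` and mean spacing 50 cM.

    For integral ``nu`` this uses the exact construction: a Poisson process of
    rate nu/50 thinned to every nu-th point with a uniformly random phase.
    For non-integral shapes the renewal is started 60 mean spacings upstream,
    which is stationary to numerical precision.
    """
    rate = nu / _MEAN_CHIASMA_SPACING_CM  # sub-event rate per cM
    if float(nu).is_integer():
        nu_i = int(nu)
        # expected sub-events on [0,L] is rate*L; draw with headroom
        n_exp = rate * length_cm
        n_draw = int(n_exp + 6 * np.sqrt(n_exp) + 20)
        gaps = rng.exponential(1.0 / rate, size=n_draw)
        pts = np.cumsum(gaps)
        while pts[-1] < length_cm:  # extremely rare
            extra = rng.exponential(1.0 / rate, size=n_draw)
            pts = np.concatenate([pts, pts[-1] + np.cumsum(extra)])
        pts = pts[pts <= length_cm]
        phase = rng.integers(nu_i)
        return pts[phase::nu_i]
    burnin = 60 * _MEAN_CHIASMA_SPACING_CM
    pos = -burnin
    out = []
    while pos <= length_cm:
        pos += rng.gamma(nu, scale=1.0 / rate)
        if 0 < pos <= length_cm:
            out.append(pos)
    return np.array(out)


def simulate_gamete(chrom_size_bp: int, map_cm: float, nu: float, rng: np.random.Generator,
                    obligate_chiasma: bool = False) -> np.ndarray:
    """Crossover positions (bp, strictly increasing) on one transmitted gamete.

    Chiasmata are placed on the bundle by a stationary gamma renewal process
    and independently retained with probability 1/2; positions are converted
    to bp by linear cM<->bp scaling over the chromosome.
    """
    if map_cm < 0:
        raise ValueError(f"map_cm must be >= 0, got {map_cm}")
    if map_cm == 0:
        return np.array([], dtype=np.int64)
    while True:
        chiasmata = _stationary_chiasmata(map_cm, nu, rng)
        if chiasmata.size or not obligate_chiasma:
            break
    keep = rng.random(len(chiasmata)) < 0.5
    xo_cm = chiasmata[keep]
    pos = np.ceil(xo_cm / map_cm * chrom_size_bp).astype(np.int64)
    pos = np.unique(np.clip(pos, 1, chrom_size_bp))
    return pos


def simulate_offspring(config: SimConfig) -> tuple[GenotypeMatrix, TrueMeiosisSet]:
    """Simulate a backcross cohort on the configured panel.

    Each offspring receives one recombinant F1 gamete per chromosome, drawn
    with the map of the transmitting parent's sex (F* groups use the female
    map, M* groups the male map).  Marker genotype is H where the gamete
    carries the BALB/c allele and B where it carries C57BL/6J; genotyping
    error (B<->H flips) and missing calls are applied after the ground truth
    is recorded.
    """
    panel = config.panel
    rng = np.random.default_rng(config.seed)
    chroms = panel.chromosomes
    chrom_pos = {c: np.array([m.pos_bp for m in panel.markers_on(c)]) for c in chroms}
    chrom_cols = {c: np.array([j for j, m in enumerate(panel.markers) if m.chrom == c]) for c in chroms}

    sample_ids: list[str] = []
    groups: list[str] = []
    for g, n in config.group_sizes.items():
        sample_ids.extend(f"{g}{i:03d}" for i in range(1, n + 1))
        groups.extend([g] * n)

    calls = np.empty((len(sample_ids), panel.n_markers), dtype=np.int8)
    crossovers: dict[tuple[str, int], np.ndarray] = {}
    start_allele: dict[tuple[str, int], int] = {}

    for i, (sid, group) in enumerate(zip(sample_ids, groups)):
        sex = sex_of_group(group)
        for chrom in chroms:
            size_bp = int(panel.chrom_sizes[chrom] * 1e6)
            cm = config.map_cm[sex].get(chrom, 0.0)
            xs = simulate_gamete(size_bp, cm, config.interference_shape, rng, config.obligate_chiasma)
            phase = int(rng.integers(2))
            crossovers[(sid, chrom)] = xs
            start_allele[(sid, chrom)] = phase
            n_before = np.searchsorted(xs, chrom_pos[chrom])
            allele = (phase + n_before) % 2
            calls[i, chrom_cols[chrom]] = np.where(allele == 1, CODE_H, CODE_B)

    truth = TrueMeiosisSet(sample_ids, crossovers, start_allele, list(chroms))

    if config.error_rate > 0:
        flip = rng.random(calls.shape) < config.error_rate
        calls = np.where(flip, 1 - calls, calls).astype(np.int8)
    if config.missing_rate > 0:
        drop = rng.random(calls.shape) < config.missing_rate
        calls = np.where(drop, CODE_N, calls).astype(np.int8)

    matrix = GenotypeMatrix(sample_ids, groups, panel.marker_ids, calls)
    return matrix, truth
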