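"""Bundled reference data for the 130-SNP C57BL/6J x BALB/c backcross design.

The shipped panel reproduces the published per-chromosome spacing summary
(marker counts, mean/min/max inter-marker distance, first-to-last physical
length) of the 130-SNP genotyping panel; the exact SNP coordinates were not
deposited, so positions here are synthetic but summary-faithful to two
decimals.  The per-chromosome crossover-count table for the four analysis
groups (FWT/FKO n=79, MWT/MKO n=78; 314 offspring) is included verbatim so
map statistics can be recomputed from it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CODE_B, GenotypeMatrix, Interval, Marker, MarkerPanel

#: NCBI chromosome sizes in Mbp for the 19 mouse autosomes
CHROM_SIZES_MBP = {
    1: 197, 2: 182, 3: 160, 4: 156, 5: 153, 6: 150, 7: 153, 8: 132, 9: 124,
    10: 130, 11: 122, 12: 121, 13: 120, 14: 125, 15: 103, 16: 98, 17: 95,
    18: 91, 19: 61,
}

# per chromosome: (n_markers, min gap, max gap, first-to-last length), Mbp.
# Lengths are tuned within +/-0.05 of the published 1-decimal cells so that
# length/(n-1) reproduces the published 2-decimal mean gaps exactly.
_GEOMETRY = {
    1: (13, 8.69, 30.36, 187.48),
    2: (7, 9.93, 74.98, 173.60),
    3: (8, 11.37, 46.28, 145.48),
    4: (9, 11.81, 31.86, 144.67),
    5: (9, 8.17, 44.27, 143.10),
    6: (6, 12.45, 61.62, 136.54),
    7: (9, 12.31, 33.07, 132.70),
    8: (9, 9.69, 20.33, 117.71),
    9: (6, 10.73, 30.78, 82.80),
    10: (5, 13.03, 48.46, 104.20),
    11: (7, 6.93, 30.59, 111.70),
    12: (4, 12.64, 31.87, 70.92),
    13: (7, 13.58, 28.97, 103.90),
    14: (8, 8.98, 20.84, 97.40),
    15: (5, 12.74, 16.28, 60.49),
    16: (5, 10.62, 30.33, 70.17),
    17: (5, 7.05, 30.49, 84.20),
    18: (4, 11.89, 16.51, 42.50),
    19: (4, 7.97, 29.87, 51.44),
}

_FIRST_MARKER_BP = 3_000_000

GROUP_SIZES = {"FWT": 79, "FKO": 79, "MWT": 78, "MKO": 78}

#: crossover counts per chromosome detected in each analysis group
CHROM_COUNTS = pd.DataFrame(
    {
        "FWT": [79, 83, 63, 74, 63, 59, 66, 50, 38, 50, 59, 28, 61, 35, 25, 24, 47, 17, 50],
        "FKO": [68, 79, 63, 65, 66, 54, 62, 56, 39, 46, 59, 40, 45, 41, 19, 42, 56, 22, 49],
        "MWT": [70, 76, 48, 50, 59, 51, 47, 42, 34, 36, 57, 25, 32, 37, 25, 34, 39, 10, 57],
        "MKO": [65, 68, 54, 49, 66, 55, 55, 48, 36, 41, 61, 27, 34, 41, 16, 31, 57, 4, 50],
    },
    index=pd.Index(range(1, 20), name="chrom"),
)

#: detected map density (cM/Mbp) per chromosome, wild-type groups
CM_PER_MBP_WT = pd.DataFrame(
    {
        "female": [0.53, 0.61, 0.55, 0.65, 0.56, 0.55, 0.63, 0.54, 0.58, 0.61,
                   0.67, 0.50, 0.74, 0.45, 0.52, 0.43, 0.71, 0.51, 1.23],
        "male": [0.48, 0.56, 0.42, 0.44, 0.53, 0.48, 0.45, 0.46, 0.53, 0.44,
                 0.65, 0.45, 0.39, 0.49, 0.53, 0.62, 0.59, 0.30, 1.42],
    },
    index=pd.Index(range(1, 20), name="chrom"),
)


def reference_panel() -> MarkerPanel:
    """The bundled 130-marker panel (19 autosomes, 111 intervals)."""
    markers: list[Marker] = []
    for chrom, (n, gmin, gmax, length) in _GEOMETRY.items():
        k = n - 3  # gaps other than the extreme two
        filler = (length - gmin - gmax) / k if k > 0 else 0.0
        gaps = [gmin] + [filler] * k + [gmax]
        pos = _FIRST_MARKER_BP
        markers.append(Marker(chrom, pos, f"c{chrom:02d}m01"))
        for i, g in enumerate(gaps, start=2):
            pos += int(round(g * 1e6))
            markers.append(Marker(chrom, pos, f"c{chrom:02d}m{i:02d}"))
    return MarkerPanel(markers, CHROM_SIZES_MBP)


def counts_to_callset(counts: pd.DataFrame | None = None,
                      group_sizes: dict[str, int] | None = None,
                      panel: MarkerPanel | None = None):
    """Encode a per-chromosome count table as a concrete CrossoverCallSet.

    Events are spread deterministically over the first intervals of each
    chromosome (at most one per sample per interval), so per-chromosome and
    per-group totals match the table exactly.  Per-interval placement is
    arbitrary; use it for chromosome-level and group-level statistics only.
    """
    from .calling import CrossoverCallSet

    counts = CHROM_COUNTS if counts is None else counts
    group_sizes = dict(GROUP_SIZES if group_sizes is None else group_sizes)
    panel = reference_panel() if panel is None else panel

    intervals = panel.intervals()
    interval_index = {iv.name: j for j, iv in enumerate(intervals)}
    first_intervals = {chrom: [iv for iv in intervals if iv.chrom == chrom] for chrom in panel.chromosomes}

    sample_ids: list[str] = []
    groups: list[str] = []
    for g, n in group_sizes.items():
        sample_ids.extend(f"{g}{i:03d}" for i in range(1, n + 1))
        groups.extend([g] * n)

    events = np.zeros((len(sample_ids), len(intervals)), dtype=np.int8)
    row0 = 0
    for g, n in group_sizes.items():
        for chrom in counts.index:
            c = int(counts.loc[chrom, g])
            ivs = first_intervals[chrom]
            if c > n * len(ivs):
                raise ValueError(f"count {c} on chrom {chrom} cannot fit {n} samples x {len(ivs)} intervals")
            placed = 0
            for iv in ivs:
                take = min(n, c - placed)
                if take <= 0:
                    break
                j = interval_index[iv.name]
                events[row0:row0 + take, j] = 1
                placed += take
        row0 += n

    assessed = np.ones_like(events, dtype=bool)
    return CrossoverCallSet(sample_ids, groups, intervals, events, assessed, scenario="conservative")


def empty_reference_matrix(group_sizes: dict[str, int] | None = None) -> GenotypeMatrix:
    """All-B genotype matrix on the reference panel (useful as a null fixture)."""
    group_sizes = dict(GROUP_SIZES if group_sizes is None else group_sizes)
    panel = reference_panel()
    sample_ids, groups = [], []
    for g, n in group_sizes.items():
        sample_ids.extend(f"{g}{i:03d}" for i in range(1, n + 1))
        groups.extend([g] * n)
    calls = np.full((len(sample_ids), panel.n_markers), CODE_B, dtype=np.int8)
    return GenotypeMatrix(sample_ids, groups, panel.marker_ids, calls)
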