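"""AT/GC skew statistics: windowed profiles, per-site-class tables,
gene-boundary profiles, and the leading-vs-lagging randomization test.

AT skew is (A-T)/(A+T) over a set of sites read on one strand; GC skew is
(G-C)/(G+C).  Coding sites are read in the gene's sense direction, so a
lagging-strand row aggregates lagging-encoded genes read in their own sense.
Ex-operonic intergenic sequence is read on the leading strand, and its
lagging row is the exact complement mirror.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    BASE_INDEX,
    Genome,
    GeneAnnotation,
    IntergenicRegion,
    SiteClassification,
)


@dataclass(frozen=True)
class BaseCounts:
    n_A: int = 0
    n_C: int = 0
    n_G: int = 0
    n_T: int = 0

    def __post_init__(self):
        if min(self.n_A, self.n_C, self.n_G, self.n_T) < 0:
            raise ValueError("negative base count")

    @classmethod
    def from_array(cls, arr) -> "BaseCounts":
        a, c, g, t = (int(x) for x in arr)
        return cls(a, c, g, t)

    def as_array(self) -> np.ndarray:
        return np.array([self.n_A, self.n_C, self.n_G, self.n_T], dtype=np.int64)

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts.from_array(self.as_array() + other.as_array())

    def complement(self) -> "BaseCounts":
        """Counts of the complementary strand (A<->T, C<->G)."""
        return BaseCounts(n_A=self.n_T, n_C=self.n_G, n_G=self.n_C, n_T=self.n_A)

    @property
    def total(self) -> int:
        return self.n_A + self.n_C + self.n_G + self.n_T


def at_skew(counts: BaseCounts) -> float:
    """(A-T)/(A+T); NaN (never 0) when A+T = 0."""
    denom = counts.n_A + counts.n_T
    if denom == 0:
        return math.nan
    return (counts.n_A - counts.n_T) / denom


def gc_skew(counts: BaseCounts) -> float:
    """(G-C)/(G+C); NaN when G+C = 0."""
    denom = counts.n_G + counts.n_C
    if denom == 0:
        return math.nan
    return (counts.n_G - counts.n_C) / denom


def count_bases(genome: Genome, positions: np.ndarray, sense: np.ndarray | None = None) -> BaseCounts:
    """Base counts at ``positions``; where ``sense`` is -1 the complementary
    base is counted (reading the complement strand)."""
    arr = genome.base_array()[positions]
    if sense is not None:
        s = np.asarray(sense)
        comp = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G in ACGT order
        arr = np.where((s == -1) & (arr >= 0), comp[np.clip(arr, 0, 3)], arr)
    counts = np.bincount(arr[arr >= 0], minlength=4)
    return BaseCounts(n_A=int(counts[0]), n_C=int(counts[1]), n_G=int(counts[2]), n_T=int(counts[3]))


def windowed_skew(
    genome: Genome,
    window: int,
    step: int | None = None,
    mask: np.ndarray | None = None,
    min_bases: int = 0,
) -> pd.DataFrame:
    """Skew in windows tiling the circular genome on the published strand.

    ``step=None`` gives non-overlapping tiling (``ceil(L/window)`` windows);
    otherwise windows of length ``window`` start every ``step`` bases and
    wrap around the origin.  ``mask`` restricts counted positions.  Windows
    with fewer than ``min_bases`` counted bases are flagged invalid
    (``valid=False``) and carry NaN skews.
    """
    L = genome.length
    step = step or window
    if not (1 <= step <= window):
        raise ValueError("require window >= step >= 1")
    if window > L:
        raise ValueError(f"window {window} exceeds genome length {L}")
    arr = genome.base_array()
    onehot = np.zeros((4, L), dtype=np.int64)
    for i in range(4):
        onehot[i] = arr == i
    if mask is not None:
        onehot &= np.asarray(mask, dtype=bool)
    # doubled cumulative sums make circular window sums a single subtraction
    cum = np.concatenate([np.zeros((4, 1), dtype=np.int64), np.cumsum(np.tile(onehot, 2), axis=1)], axis=1)
    starts = np.arange(0, L, step)
    ends = starts + window
    sums = cum[:, ends] - cum[:, starts]  # (4, n_windows)
    n = sums.sum(axis=0)
    at_d = sums[BASE_INDEX["A"]] + sums[BASE_INDEX["T"]]
    gc_d = sums[BASE_INDEX["G"]] + sums[BASE_INDEX["C"]]
    with np.errstate(divide="ignore", invalid="ignore"):
        at = np.where(at_d > 0, (sums[BASE_INDEX["A"]] - sums[BASE_INDEX["T"]]) / np.maximum(at_d, 1), np.nan)
        gc = np.where(gc_d > 0, (sums[BASE_INDEX["G"]] - sums[BASE_INDEX["C"]]) / np.maximum(gc_d, 1), np.nan)
    valid = n >= min_bases
    df = pd.DataFrame(
        {
            "start": starts,
            "center": (starts + window // 2) % L,
            "n_A": sums[0], "n_C": sums[1], "n_G": sums[2], "n_T": sums[3],
            "n_bases": n,
            "at_skew": np.where(valid, at, np.nan),
            "gc_skew": np.where(valid, gc, np.nan),
            "valid": valid,
        }
    )
    return df


def _terminal_codon_mask(annotations: list[GeneAnnotation], length: int) -> np.ndarray:
    """True at positions of each CDS's initiator and stop codon."""
    mask = np.zeros(length, dtype=bool)
    by_id: dict[str, list[GeneAnnotation]] = {}
    for g in annotations:
        if g.kind == "CDS":
            by_id.setdefault(g.gene_id, []).append(g)
    for segs in by_id.values():
        segs = sorted(segs, key=lambda s: s.start)
        pub = np.concatenate([np.arange(s.start, s.end) for s in segs]) % length
        if len(pub) < 6:
            mask[pub] = True
            continue
        pos = pub if segs[0].strand == "+" else pub[::-1]
        mask[pos[:3]] = True
        mask[pos[-3:]] = True
    return mask


SITE_CLASS_ROWS = ("codon1", "codon2", "fourfold", "intergenic_intra", "intergenic_ex")


def site_class_skew_table(
    classification: SiteClassification,
    genome: Genome,
    annotations: list[GeneAnnotation],
    include_terminal_codons: bool = False,
) -> pd.DataFrame:
    """Per-(site class, orientation) sense-direction base counts and skews.

    Coding rows count the sense-strand base of amino-acid-encoding codons
    (each CDS's initiator and stop codon are excluded unless
    ``include_terminal_codons``).  The ex-operonic lagging row is the
    complement mirror of the leading row, matching the convention that all
    ex-operonic sequence is read on the leading strand.
    """
    drop = None
    if not include_terminal_codons:
        drop = _terminal_codon_mask(annotations, classification.length)
    rows = []
    for name in SITE_CLASS_ROWS:
        for orient in ("leading", "lagging"):
            if name == "intergenic_ex":
                m = classification.class_mask(name)
                if drop is not None:
                    m = m & ~drop
                counts = count_bases(genome, np.flatnonzero(m), classification.sense[m])
                if orient == "lagging":
                    counts = counts.complement()
            else:
                m = classification.class_mask(name, orientation=orient)
                if drop is not None:
                    m = m & ~drop
                counts = count_bases(genome, np.flatnonzero(m), classification.sense[m])
            rows.append(
                {
                    "site_class": name,
                    "orientation": orient,
                    "n_A": counts.n_A, "n_C": counts.n_C, "n_G": counts.n_G, "n_T": counts.n_T,
                    "n_bases": counts.total,
                    "at_skew": at_skew(counts),
                    "gc_skew": gc_skew(counts),
                }
            )
    return pd.DataFrame(rows)


def boundary_profile(
    regions: list[IntergenicRegion],
    genome: Genome,
    side: str,
    max_offset: int = 200,
) -> pd.DataFrame:
    """Pooled skew at each offset into intergenic regions from gene boundaries.

    For ``side="5prime"`` offset k is the k-th base upstream of a gene start,
    read in that gene's sense; for ``side="3prime"`` it is the k-th base
    downstream of a gene end.  Regions are used untrimmed (this profile is
    what motivates the trimming rule) and a region contributes once per
    flanking gene whose relevant boundary it abuts; offsets beyond a region's
    length contribute nothing.
    """
    if side not in ("5prime", "3prime"):
        raise ValueError("side must be '5prime' or '3prime'")
    L = genome.length
    arr = genome.base_array()
    counts = np.zeros((max_offset, 4), dtype=np.int64)
    coverage = np.zeros(max_offset, dtype=np.int64)
    comp = np.array([3, 2, 1, 0], dtype=np.int8)
    for region in regions:
        n = min(region.length, max_offset)
        if n <= 0:
            continue
        walks = []
        if side == "5prime":
            # gene starting at region end, + strand: walk leftwards from end
            if region.flank_3_gene.strand == "+":
                walks.append((np.arange(region.end - 1, region.end - 1 - n, -1) % L, False))
            # gene ending at region start, - strand: its 5' flank extends rightwards
            if region.flank_5_gene.strand == "-":
                walks.append((np.arange(region.start, region.start + n) % L, True))
        else:
            if region.flank_5_gene.strand == "+":
                walks.append((np.arange(region.start, region.start + n) % L, False))
            if region.flank_3_gene.strand == "-":
                walks.append((np.arange(region.end - 1, region.end - 1 - n, -1) % L, True))
        for idx, complemented in walks:
            b = arr[idx]
            if complemented:
                b = np.where(b >= 0, comp[np.clip(b, 0, 3)], b)
            ok = b >= 0
            offs = np.flatnonzero(ok)
            np.add.at(counts, (offs, b[ok]), 1)
            coverage[: len(idx)] += 1
    at_d = counts[:, BASE_INDEX["A"]] + counts[:, BASE_INDEX["T"]]
    with np.errstate(divide="ignore", invalid="ignore"):
        at = np.where(at_d > 0, (counts[:, 0] - counts[:, 3]) / np.maximum(at_d, 1), np.nan)
    return pd.DataFrame(
        {
            "offset": np.arange(1, max_offset + 1),
            "n_A": counts[:, 0], "n_C": counts[:, 1], "n_G": counts[:, 2], "n_T": counts[:, 3],
            "n_regions": coverage,
            "at_skew": at,
        }
    )


@dataclass
class PermutationTestResult:
    observed_difference: float
    r: int
    n: int

    @property
    def P(self) -> float:
        return (self.r + 1) / (self.n + 1)


def randomization_pvalue(r: int, n: int) -> float:
    """The randomization-test P-value (r+1)/(n+1)."""
    if n < 1 or r < 0 or r > n:
        raise ValueError("require 0 <= r <= n, n >= 1")
    return (r + 1) / (n + 1)


def _units_for_class(classification, genome, annotations, site_class):
    """Per-gene (coding) or per-region (intergenic) sense base counts and
    orientation labels for the randomization test."""
    drop = _terminal_codon_mask(annotations, classification.length)
    units: list[tuple[np.ndarray, int]] = []
    if site_class in ("codon1", "codon2", "codon3", "fourfold"):
        base_mask = classification.class_mask(site_class) & ~drop
        by_id: dict[str, list[GeneAnnotation]] = {}
        for g in annotations:
            if g.kind == "CDS":
                by_id.setdefault(g.gene_id, []).append(g)
        for segs in by_id.values():
            gm = np.zeros(classification.length, dtype=bool)
            for s in segs:
                gm[np.arange(s.start, s.end) % classification.length] = True
            m = base_mask & gm
            if not m.any():
                continue
            counts = count_bases(genome, np.flatnonzero(m), classification.sense[m])
            units.append((counts.as_array(), int(classification.orientation[m][0])))
        mode = "two_group"
    elif site_class in ("intergenic_intra", "intergenic_ex"):
        m = classification.class_mask(site_class)
        idx = np.flatnonzero(m)
        if len(idx) == 0:
            return [], "two_group"
        breaks = np.flatnonzero(np.diff(idx) > 1)
        runs = np.split(idx, breaks + 1)
        for run in runs:
            counts = count_bases(genome, run, classification.sense[run])
            units.append((counts.as_array(), int(classification.orientation[run[0]])))
        mode = "mirror" if site_class == "intergenic_ex" else "two_group"
    else:
        raise KeyError(site_class)
    return units, mode


def _skew_from_rows(rows: np.ndarray) -> np.ndarray:
    denom = rows[..., 0] + rows[..., 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (rows[..., 0] - rows[..., 3]) / np.maximum(denom, 1), np.nan)


def orientation_permutation_test(
    classification: SiteClassification,
    genome: Genome,
    annotations: list[GeneAnnotation],
    site_class: str,
    n_sims: int = 10_000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Randomization test of the leading-vs-lagging skew difference.

    The observed statistic is leading sense skew minus lagging sense skew for
    the class.  Null draws reassign each unit's (gene's or region's)
    orientation label with probability 1/2 and recompute the statistic; for
    the ex-operonic class — whose two rows are complement mirrors — each
    region's reading strand is instead flipped with probability 1/2 and the
    statistic is the mirrored difference 2*skew(pool).  P = (r+1)/(n+1).
    """
    units, mode = _units_for_class(classification, genome, annotations, site_class)
    if len(units) < 2:
        raise ValueError(f"need at least two units with data for {site_class!r}, got {len(units)}")
    counts = np.stack([u[0] for u in units])  # (n_units, 4) in ACGT order
    labels = np.array([u[1] for u in units])
    rng = np.random.default_rng(seed)
    comp = counts[:, [3, 2, 1, 0]]

    if mode == "mirror":
        pooled = counts.sum(axis=0)
        observed = 2.0 * _skew_from_rows(pooled[None, :])[0]
        flips = rng.random((n_sims, len(units))) < 0.5
        pools = np.where(flips[:, :, None], comp[None, :, :], counts[None, :, :]).sum(axis=1)
        null = 2.0 * _skew_from_rows(pools)
    else:
        lead = counts[labels == 1].sum(axis=0)
        lag = counts[labels == 0].sum(axis=0)
        if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
            raise ValueError("both orientations must be represented")
        observed = _skew_from_rows(lead[None, :])[0] - _skew_from_rows(lag[None, :])[0]
        assign = rng.random((n_sims, len(units))) < 0.5
        lead_null = np.einsum("su,uc->sc", assign, counts)
        lag_null = counts.sum(axis=0)[None, :] - lead_null
        null = _skew_from_rows(lead_null) - _skew_from_rows(lag_null)

    valid = ~np.isnan(null)
    r = int((np.abs(null[valid]) >= abs(observed)).sum())
    return PermutationTestResult(observed_difference=float(observed), r=r, n=int(valid.sum()))
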