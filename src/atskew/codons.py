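"""Stop-codon-aware codon randomization nulls and amino-acid usage selection.

The null model draws codons independently with probability proportional to
the product of (intergenic, strand-specific) base frequencies over all
codons except the three stops — stop codons cannot occur inside a reading
frame, and their avoidance alone imposes AT skew on first codon positions
because all stops begin with T.  Comparing observed codon usage with the
null yields per-amino-acid-block Z-scores, which can be correlated with
amino-acid biosynthetic cost to test for avoidance of expensive (T-rich)
amino acids.

Amino acids with six codons are split into a 4-block and a 2-block (23
blocks partitioning the 61 sense codons), since base frequencies influence
the two blocks differently.
"""

from __future__ import annotations

import importlib.resources
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .genome import BASES, BASE_INDEX

STOP_CODONS = ("TAA", "TAG", "TGA")
ALL_CODONS = tuple("".join(c) for c in itertools.product(BASES, repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

_TABLE = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA = dict(_TABLE.forward_table)

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


@dataclass(frozen=True)
class AminoAcidBlock:
    block_id: str
    amino_acid: str  # one-letter
    codons: tuple[str, ...]


def amino_acid_blocks() -> list[AminoAcidBlock]:
    """The 23 codon blocks: one per amino acid, with six-codon amino acids
    (Leu, Ser, Arg) split into their 4-block and 2-block."""
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(CODON_TO_AA[codon], []).append(codon)
    blocks: list[AminoAcidBlock] = []
    for aa, codons in sorted(by_aa.items()):
        if len(codons) == 6:
            by_prefix: dict[str, list[str]] = {}
            for c in codons:
                by_prefix.setdefault(c[:2], []).append(c)
            four = [cs for cs in by_prefix.values() if len(cs) == 4][0]
            two = sorted(c for c in codons if c not in four)
            blocks.append(AminoAcidBlock(f"{AA3[aa]}4", aa, tuple(sorted(four))))
            blocks.append(AminoAcidBlock(f"{AA3[aa]}2", aa, tuple(two)))
        else:
            blocks.append(AminoAcidBlock(AA3[aa], aa, tuple(sorted(codons))))
    assert sorted(c for b in blocks for c in b.codons) == sorted(SENSE_CODONS)
    return blocks


def _as_freqs(freqs) -> np.ndarray:
    if isinstance(freqs, dict):
        arr = np.array([float(freqs[b]) for b in BASES])
    else:
        arr = np.asarray(freqs, dtype=float)
    if arr.shape != (4,) or (arr < 0).any():
        raise ValueError("frequencies must be 4 nonnegative numbers (A, C, G, T)")
    if abs(arr.sum() - 1.0) > 1e-9:
        arr = arr / arr.sum()
    return arr


def codon_draw_distribution(freqs, exclude: tuple[str, ...] = STOP_CODONS) -> pd.Series:
    """P(xyz) proportional to p_x p_y p_z over codons not in ``exclude``."""
    p = _as_freqs(freqs)
    codons = [c for c in ALL_CODONS if c not in exclude]
    w = np.array([p[BASE_INDEX[c[0]]] * p[BASE_INDEX[c[1]]] * p[BASE_INDEX[c[2]]] for c in codons])
    total = w.sum()
    if total <= 0:
        raise ValueError("draw distribution has zero mass after exclusions")
    return pd.Series(w / total, index=codons, name="probability")


def positional_base_probs(dist: pd.Series, position: int) -> np.ndarray:
    """Marginal base probabilities (A, C, G, T) at codon position 1, 2 or 3."""
    if position not in (1, 2, 3):
        raise ValueError("codon position must be 1, 2 or 3")
    out = np.zeros(4)
    for codon, p in dist.items():
        out[BASE_INDEX[codon[position - 1]]] += p
    return out


def positional_at_skew(dist: pd.Series, position: int) -> float:
    """Analytic (A-T)/(A+T) of the draw distribution at a codon position."""
    m = positional_base_probs(dist, position)
    denom = m[BASE_INDEX["A"]] + m[BASE_INDEX["T"]]
    if denom == 0:
        return math.nan
    return (m[BASE_INDEX["A"]] - m[BASE_INDEX["T"]]) / denom


@dataclass
class CodingNull:
    """Simulated codon usage under the stop-excluded null.

    ``usage``: (n_sims, 61) codon counts; ``skew1``/``skew2``: per-simulation
    sense AT skew at first/second codon positions.
    """

    distribution: pd.Series
    n_codons: int
    usage: np.ndarray = field(repr=False)
    skew1: np.ndarray = field(repr=False)
    skew2: np.ndarray = field(repr=False)

    @property
    def n_sims(self) -> int:
        return self.usage.shape[0]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon_position": [1, 2],
                "mean_at_skew": [self.skew1.mean(), self.skew2.mean()],
                "sd_at_skew": [self.skew1.std(ddof=1), self.skew2.std(ddof=1)],
                "n_sims": self.n_sims,
                "n_codons": self.n_codons,
            }
        )


def simulate_coding(
    n_codons: int,
    freqs,
    n_sims: int = 10_000,
    seed: int | None = None,
    exclude: tuple[str, ...] = STOP_CODONS,
) -> CodingNull:
    """Draw ``n_sims`` random coding sequences of ``n_codons`` codons each.

    Codons are iid from :func:`codon_draw_distribution`; per simulation the
    first- and second-position sense AT skews and the full codon usage are
    recorded.
    """
    if n_codons <= 0:
        raise ValueError("n_codons must be positive")
    dist = codon_draw_distribution(freqs, exclude=exclude)
    rng = np.random.default_rng(seed)
    usage = rng.multinomial(n_codons, dist.to_numpy(), size=n_sims)
    codons = list(dist.index)
    skews = {}
    for position in (1, 2):
        a = np.array([c[position - 1] == "A" for c in codons])
        t = np.array([c[position - 1] == "T" for c in codons])
        nA = usage @ a
        nT = usage @ t
        denom = nA + nT
        with np.errstate(divide="ignore", invalid="ignore"):
            skews[position] = np.where(denom > 0, (nA - nT) / np.maximum(denom, 1), np.nan)
    return CodingNull(distribution=dist, n_codons=n_codons, usage=usage, skew1=skews[1], skew2=skews[2])


def null_test_P(observed: float, sims: np.ndarray) -> float:
    """Two-sided randomization P for an observed value against null draws:
    r = #{|sim - mean| >= |observed - mean|}, P = (r+1)/(n+1)."""
    sims = np.asarray(sims, dtype=float)
    if sims.size == 0:
        raise ValueError("no simulations")
    center = sims.mean()
    r = int((np.abs(sims - center) >= abs(observed - center)).sum())
    return (r + 1) / (sims.size + 1)


def usage_from_counts(counts: dict[str, int]) -> np.ndarray:
    """Codon usage vector (length 61, SENSE_CODONS order) from a mapping."""
    out = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    for codon, n in counts.items():
        c = codon.upper().replace("U", "T")
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c} in observed usage")
        out[_CODON_INDEX[c]] = n
    return out


def z_scores(
    observed_usage: np.ndarray,
    null_usage: np.ndarray,
    blocks: list[AminoAcidBlock] | None = None,
) -> pd.DataFrame:
    """Per-block usage Z-scores against the simulated null.

    Z = (observed block count - mean simulated block count) / SD of simulated
    block counts; dividing by the null SD normalizes for amino acids
    occupying different amounts of codon space.  Blocks with zero null SD
    get NaN and ``defined=False``.
    """
    blocks = blocks or amino_acid_blocks()
    observed_usage = np.asarray(observed_usage)
    null_usage = np.asarray(null_usage)
    if null_usage.ndim != 2 or null_usage.shape[0] < 2:
        raise ValueError("need at least two null simulations")
    rows = []
    for block in blocks:
        idx = [_CODON_INDEX[c] for c in block.codons]
        obs = float(observed_usage[idx].sum())
        sims = null_usage[:, idx].sum(axis=1)
        mean, sd = float(sims.mean()), float(sims.std(ddof=1))
        z = (obs - mean) / sd if sd > 0 else math.nan
        rows.append(
            {
                "block": block.block_id, "amino_acid": block.amino_acid,
                "codons": ",".join(block.codons),
                "observed": obs, "expected": mean, "sd": sd,
                "z": z, "defined": sd > 0,
            }
        )
    return pd.DataFrame(rows)


_DATA_SCHEMAS = {
    "akashi_gojobori": "aa_cost_akashi_gojobori.tsv",
    "molecular_weight": "aa_cost_molecular_weight.tsv",
}


def load_cost_table(schema_or_path: str) -> pd.Series:
    """Amino-acid cost table: a bundled schema name or a path to a TSV with
    columns ``amino_acid`` (one-letter) and ``cost``."""
    if schema_or_path in _DATA_SCHEMAS:
        ref = importlib.resources.files("atskew") / "data" / _DATA_SCHEMAS[schema_or_path]
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", comment="#")
    else:
        df = pd.read_csv(schema_or_path, sep="\t", comment="#")
    series = pd.Series(df["cost"].to_numpy(dtype=float), index=df["amino_acid"], name="cost")
    missing = set(AA3) - set(series.index)
    if missing:
        raise ValueError(f"cost table missing amino acids: {sorted(missing)}")
    return series


@dataclass
class CostCorrelation:
    rho: float
    p_one_sided: float
    n: int
    method: str


def cost_correlation(
    z_table: pd.DataFrame,
    costs: pd.Series,
    alternative: str = "less",
) -> CostCorrelation:
    """Spearman rank correlation between block Z-scores and amino-acid cost.

    Six-codon blocks enter separately, sharing their amino acid's cost.  The
    one-sided P (default: negative association, i.e. costly amino acids
    under-used) uses exact permutation enumeration below 10 points and the
    large-sample t approximation otherwise.
    """
    sub = z_table[z_table["defined"]].copy()
    sub["cost"] = sub["amino_acid"].map(costs)
    sub = sub.dropna(subset=["z", "cost"])
    n = len(sub)
    if n < 3:
        raise ValueError("need at least 3 blocks with defined Z and cost")
    if sub["cost"].nunique() == 1:
        raise ValueError("costs are constant; correlation undefined")
    z = sub["z"].to_numpy()
    cost = sub["cost"].to_numpy()
    rho = float(stats.spearmanr(z, cost).statistic)
    if n < 10:
        zr = stats.rankdata(z)
        cr = stats.rankdata(cost)
        observed = np.corrcoef(zr, cr)[0, 1]
        count = 0
        total = 0
        for perm in itertools.permutations(zr):
            r = np.corrcoef(perm, cr)[0, 1]
            if alternative == "less":
                count += r <= observed + 1e-12
            else:
                count += r >= observed - 1e-12
            total += 1
        p = count / total
        method = "exact_permutation"
    else:
        res = stats.spearmanr(z, cost, alternative=alternative)
        p = float(res.pvalue)
        method = "t_approximation"
    return CostCorrelation(rho=rho, p_one_sided=float(p), n=n, method=method)


def positional_gc_distribution(gc_contents) -> pd.Series:
    """Skew-free stop-excluded codon distribution from per-position GC.

    At codon position k with GC content g_k the null base probabilities are
    p_G = p_C = g_k/2 and p_A = p_T = (1-g_k)/2 (no GC or AT skew); codons
    are products over positions, stops excluded and renormalized.
    """
    gc = np.asarray(gc_contents, dtype=float)
    if gc.shape != (3,) or ((gc <= 0) | (gc >= 1)).any():
        raise ValueError("need three positional GC contents strictly in (0,1)")
    pos_probs = []
    for g in gc:
        pos_probs.append({"A": (1 - g) / 2, "T": (1 - g) / 2, "G": g / 2, "C": g / 2})
    codons = [c for c in ALL_CODONS if c not in STOP_CODONS]
    w = np.array([np.prod([pos_probs[k][c[k]] for k in range(3)]) for c in codons])
    return pd.Series(w / w.sum(), index=codons, name="probability")


def mean_cost(usage: np.ndarray, costs: pd.Series) -> float:
    """Mean amino-acid cost per codon of an observed usage vector."""
    usage = np.asarray(usage, dtype=float)
    c = np.array([costs[CODON_TO_AA[codon]] for codon in SENSE_CODONS])
    return float((usage * c).sum() / usage.sum())


def expected_cost(dist: pd.Series, costs: pd.Series) -> float:
    """Expected amino-acid cost per codon under a codon distribution."""
    return float(sum(p * costs[CODON_TO_AA[codon]] for codon, p in dist.items()))


def cost_ratio(observed_usage: np.ndarray, gc_contents, costs: pd.Series) -> float:
    """Observed over expected mean amino-acid cost.

    The expectation comes from the skew-free positional-GC codon null with
    stop exclusion (computed analytically — the exact mean of the simulated
    null).  A ratio below 1 indicates the genome uses cheaper amino acids
    than its positional base composition alone predicts.
    """
    dist = positional_gc_distribution(gc_contents)
    return mean_cost(observed_usage, costs) / expected_cost(dist, costs)


@dataclass
class OutlierTestResult:
    regions: pd.DataFrame
    pooled_skew: float
    pooled_skew_without_outliers: float
    n_shuffles: int
    level: float


def intergenic_outlier_test(
    region_counts: list,
    n_shuffles: int = 1000,
    level: float = 95.0,
    seed: int | None = None,
) -> OutlierTestResult:
    """Flag intergenic regions whose AT skew exceeds a shuffle null band.

    ``region_counts`` is a list of per-region (leading-strand) BaseCounts.
    The null shuffles the pooled nucleotide content and repartitions it into
    regions with the observed A+T content of each region, which for the AT
    skew statistic amounts to drawing each region's A count from the
    hypergeometric over the pooled A/T content at fixed region A+T.  Regions
    outside the central ``level``% band are outliers; the pooled skew is
    reported with and without them.
    """
    if not region_counts:
        raise ValueError("no regions")
    rng = np.random.default_rng(seed)
    arr = np.stack([c.as_array() for c in region_counts])  # (n, 4) ACGT
    pool_A = int(arr[:, 0].sum())
    pool_T = int(arr[:, 3].sum())
    alpha = (100.0 - level) / 2.0
    rows = []
    for k, counts in enumerate(region_counts):
        n_at = counts.n_A + counts.n_T
        if n_at == 0:
            rows.append({"region": k, "n_AT": 0, "at_skew": math.nan,
                         "band_low": math.nan, "band_high": math.nan, "outlier": False})
            continue
        draw_A = rng.hypergeometric(pool_A, pool_T, n_at, size=n_shuffles)
        null_skew = (2.0 * draw_A - n_at) / n_at
        lo, hi = np.percentile(null_skew, [alpha, 100.0 - alpha])
        obs = (counts.n_A - counts.n_T) / n_at
        rows.append({"region": k, "n_AT": n_at, "at_skew": obs,
                     "band_low": float(lo), "band_high": float(hi),
                     "outlier": bool(obs < lo or obs > hi)})
    df = pd.DataFrame(rows)
    pooled = (pool_A - pool_T) / (pool_A + pool_T)
    keep = ~df["outlier"].to_numpy()
    kept = arr[keep]
    denom = kept[:, 0].sum() + kept[:, 3].sum()
    pooled_wo = (kept[:, 0].sum() - kept[:, 3].sum()) / denom if denom > 0 else math.nan
    return OutlierTestResult(
        regions=df, pooled_skew=float(pooled),
        pooled_skew_without_outliers=float(pooled_wo),
        n_shuffles=n_shuffles, level=level,
    )
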