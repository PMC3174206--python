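"""Strand-resolved mutational profiles from singleton SNPs and the base
composition expected at mutational equilibrium.

Singleton SNPs (variants carried by exactly one isolate) approximate very
recent mutations largely unfiltered by selection.  Counting the 12 ordered
ancestral->derived categories on the leading strand and dividing by the
number of leading-strand sites of each ancestral base gives per-site rates
r_ij.  At compositional equilibrium the loss of each base equals its net
gain,

    f_i * sum_j r_ij = sum_j f_j * r_ji   for every base i,

which is solved (with sum f = 1) as the left null space of the 4x4
generator.  The equilibrium AT skew (f_A - f_T)/(f_A + f_T) is the skew
mutation alone would drive the analyzed site class toward.

Inference utilities: multinomial bootstrap of the SNP spectrum (percentile
CI), leave-k-out robustness against hypothetical miscalled SNPs, and a
randomization test contrasting young (singleton) and older (multi-isolate)
SNP spectra.

Bases are ordered A, C, G, T throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BASES, BASE_INDEX
from .skew import PermutationTestResult

logger = logging.getLogger(__name__)

_COMP_PERM = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT order
_OFFDIAG = [(i, j) for i in range(4) for j in range(4) if i != j]


@dataclass
class SnpRecord:
    """One SNP on the published strand; ``orientation`` says whether the
    published strand is the leading strand at the site."""

    position: int
    ancestral: str
    derived: str
    multiplicity: int = 1
    site_context: str = ""
    orientation: str = "leading"

    def __post_init__(self):
        if self.ancestral == self.derived:
            raise ValueError(f"SNP at {self.position}: ancestral == derived")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    @property
    def is_singleton(self) -> bool:
        return self.multiplicity == 1


@dataclass
class MutationCounts:
    """Counts over the 12 ordered substitution categories (4x4, diagonal unused)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (4, 4):
            raise ValueError("counts must be 4x4")
        if (self.matrix < 0).any():
            raise ValueError("negative counts")
        if np.diag(self.matrix).any():
            raise ValueError("diagonal entries must be zero")

    @classmethod
    def from_pairs(cls, pairs: dict[str, int]) -> "MutationCounts":
        """Build from a mapping like {"AG": 31, ...} where "XY" is X -> Y."""
        m = np.zeros((4, 4), dtype=np.int64)
        for key, value in pairs.items():
            a, b = key[0].upper(), key[1].upper()
            if a == b:
                raise ValueError(f"bad category {key!r}")
            m[BASE_INDEX[a], BASE_INDEX[b]] = value
        return cls(m)

    def to_pairs(self) -> dict[str, int]:
        return {BASES[i] + BASES[j]: int(self.matrix[i, j]) for i, j in _OFFDIAG}

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def complement(self) -> "MutationCounts":
        """Counts re-expressed on the complementary strand (A<->T, C<->G,
        substitution direction preserved)."""
        return MutationCounts(self.matrix[np.ix_(_COMP_PERM, _COMP_PERM)])

    def __add__(self, other: "MutationCounts") -> "MutationCounts":
        return MutationCounts(self.matrix + other.matrix)


def filter_singletons(
    snps: list[SnpRecord],
    context: str | None = "intergenic_ex",
) -> MutationCounts:
    """Singleton SNP spectrum expressed on the leading strand.

    SNPs at sites where the published strand is lagging are complemented so
    all categories refer to the leading strand.  ``context`` filters on
    ``site_context`` (None keeps everything).
    """
    m = np.zeros((4, 4), dtype=np.int64)
    for snp in snps:
        if not snp.is_singleton:
            continue
        if context is not None and snp.site_context != context:
            continue
        a, d = snp.ancestral.upper(), snp.derived.upper()
        if snp.orientation == "lagging":
            a, d = a.translate(str.maketrans("ACGT", "TGCA")), d.translate(str.maketrans("ACGT", "TGCA"))
        m[BASE_INDEX[a], BASE_INDEX[d]] += 1
    return MutationCounts(m)


def load_snp_table(path) -> list[SnpRecord]:
    """Read a SNP TSV with columns position, ancestral, derived, multiplicity
    (optional site_context, orientation)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SnpRecord(
                position=int(row.position),
                ancestral=str(row.ancestral),
                derived=str(row.derived),
                multiplicity=int(getattr(row, "multiplicity", 1)),
                site_context=str(getattr(row, "site_context", "")),
                orientation=str(getattr(row, "orientation", "leading")),
            )
        )
    return records


def annotate_snps(snps: list[SnpRecord], classification) -> list[SnpRecord]:
    """Fill ``site_context`` and ``orientation`` from a SiteClassification."""
    from .genome import CLASS_INTERGENIC, CONTEXT_INTRA, CLASS_NAMES

    for snp in snps:
        pos = snp.position
        if not classification.usable()[pos]:
            snp.site_context = "excluded"
            continue
        cls = classification.site_class[pos]
        if cls == CLASS_INTERGENIC:
            ctx = classification.context[pos]
            snp.site_context = "intergenic_intra" if ctx == CONTEXT_INTRA else "intergenic_ex"
        else:
            snp.site_context = CLASS_NAMES[cls]
        snp.orientation = "leading" if classification.orientation[pos] == 1 else "lagging"
        # for intergenic sites orientation refers to the published strand's
        # replichore role, which is what strand-resolving a SNP needs
        if cls == CLASS_INTERGENIC:
            snp.orientation = "leading" if classification.sense[pos] == 1 else "lagging"
    return snps


def rates_from_counts(counts: MutationCounts, composition) -> np.ndarray:
    """Per-site observed rates r_ij = c_ij / N_i.

    ``composition`` is the number of analyzed sites of each ancestral base on
    the focal strand, ordered A, C, G, T (array or {base: count} mapping).
    """
    N = _as_composition(composition)
    if ((counts.matrix.sum(axis=1) > 0) & (N <= 0)).any():
        raise ValueError("composition has zero sites for a base with observed mutations")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(N[:, None] > 0, counts.matrix / np.maximum(N[:, None], 1e-300), 0.0)
    np.fill_diagonal(r, 0.0)
    return r


def _as_composition(composition) -> np.ndarray:
    if isinstance(composition, dict):
        return np.array([float(composition[b]) for b in BASES])
    arr = np.asarray(composition, dtype=float)
    if arr.shape != (4,):
        raise ValueError("composition must have 4 entries (A, C, G, T)")
    return arr


def infer_composition(counts: MutationCounts, rates: np.ndarray) -> np.ndarray:
    """Invert ``rates_from_counts``: recover site counts N_i = c_ij / r_ij.

    Uses the median over categories with both c > 0 and r > 0 and checks
    cross-category agreement to 1%; useful for reconstructing compositions
    from published count and rate tables.
    """
    rates = np.asarray(rates, dtype=float)
    N = np.zeros(4)
    for i in range(4):
        ests = [
            counts.matrix[i, j] / rates[i, j]
            for j in range(4)
            if j != i and counts.matrix[i, j] > 0 and rates[i, j] > 0
        ]
        if not ests:
            raise ValueError(f"no usable categories to infer N_{BASES[i]}")
        med = float(np.median(ests))
        if max(abs(e - med) / med for e in ests) > 0.01:
            raise ValueError(f"inconsistent estimates for N_{BASES[i]}: {ests}")
        N[i] = round(med)
    return N


def _generator(rates: np.ndarray) -> np.ndarray:
    Q = np.array(rates, dtype=float)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def equilibrium(rates: np.ndarray, warn_absorbing: bool = True) -> np.ndarray:
    """Stationary base frequencies of a 4x4 per-site rate matrix.

    Solves f Q = 0 with sum f = 1 via the null space of the generator
    (singular decomposition), which is robust to zero rate entries.  A base
    with inflow but zero outflow is absorbing: the solver returns all mass on
    it and logs a warning rather than failing.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (4, 4) or (rates < 0).any():
        raise ValueError("rates must be a nonnegative 4x4 matrix")
    off = rates.copy()
    np.fill_diagonal(off, 0.0)
    # bases never touched by any observed mutation are absent from the
    # system: they carry zero stationary mass rather than forming their own
    # trivial closed classes
    active = (off.sum(axis=1) > 0) | (off.sum(axis=0) > 0)
    if not active.any():
        raise ValueError("all rates are zero; stationary distribution undefined")
    sub = off[np.ix_(active, active)]
    Q = sub.copy()
    np.fill_diagonal(Q, -Q.sum(axis=1))
    _, s, vh = np.linalg.svd(Q.T)
    tol = max(1e-12, s[0] * 1e-10)
    if (s < tol).sum() > 1:
        classes = [BASES[i] for i in np.flatnonzero(active) if off[i].sum() == 0]
        raise ValueError(
            "rate matrix is reducible (stationary distribution not unique); "
            f"multiple closed communicating classes (absorbing candidates: {classes or 'cycles'})"
        )
    fs = vh[-1]
    fs = fs / fs.sum()
    if fs.min() < -1e-8:
        raise ValueError("stationary solve produced negative frequencies (reducible matrix?)")
    f = np.zeros(4)
    f[active] = np.clip(fs, 0.0, None)
    f = f / f.sum()
    if warn_absorbing and np.isclose(f.max(), 1.0):
        logger.warning("absorbing base %s carries all stationary mass", BASES[int(f.argmax())])
    return f


def batch_equilibrium(rates: np.ndarray) -> np.ndarray:
    """Vectorized stationary solve for a stack of 4x4 rate matrices.

    Returns an (n, 4) array; rows where the solve is degenerate (non-unique
    null space or negative frequencies) are NaN.
    """
    R = np.asarray(rates, dtype=float)
    Q = R.copy()
    idx = np.arange(4)
    Q[..., idx, idx] = 0.0
    Q[..., idx, idx] = -Q.sum(axis=-1)
    _, s, vh = np.linalg.svd(np.swapaxes(Q, -1, -2))
    f = vh[..., -1, :]
    f = f / f.sum(axis=-1, keepdims=True)
    bad = (f.min(axis=-1) < -1e-8) | (s[..., 2] < np.maximum(1e-12, s[..., 0] * 1e-10))
    f = np.clip(f, 0.0, None)
    f = f / f.sum(axis=-1, keepdims=True)
    f[bad] = np.nan
    return f


def equilibrium_at_skew(f) -> float:
    """(f_A - f_T)/(f_A + f_T); NaN when f_A + f_T = 0."""
    f = np.asarray(f, dtype=float)
    denom = f[..., 0] + f[..., 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (f[..., 0] - f[..., 3]) / np.where(denom > 0, denom, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class EquilibriumResult:
    f: np.ndarray
    at_skew: float
    ci_low: float
    ci_high: float
    B: int
    level: float
    bootstrap_skews: np.ndarray = field(repr=False)
    n_failures: int = 0


def _resample_skews(counts, composition, B, rng, max_redraw=100):
    """B equilibrium skews from multinomial resamples of the SNP events."""
    N = _as_composition(composition)
    p = counts.matrix.flatten() / counts.total
    skews = np.full(B, np.nan)
    pending = np.arange(B)
    failures = 0
    for _ in range(max_redraw):
        draws = rng.multinomial(counts.total, p, size=len(pending)).reshape(-1, 4, 4)
        rates = draws / N[None, :, None]
        f = batch_equilibrium(rates)
        sk = equilibrium_at_skew(f)
        for k in np.flatnonzero(np.isnan(sk)):
            # the batch solve flags matrices with untouched bases; the scalar
            # solver handles those by dropping them from the system
            try:
                sk[k] = equilibrium_at_skew(equilibrium(rates[k], warn_absorbing=False))
            except ValueError:
                pass
        ok = ~np.isnan(sk)
        skews[pending[ok]] = sk[ok]
        failures += int((~ok).sum())
        pending = pending[~ok]
        if len(pending) == 0:
            break
    else:
        raise RuntimeError("bootstrap replicates repeatedly failed to solve")
    return skews, failures


def bootstrap_ci(
    counts: MutationCounts,
    composition,
    B: int = 1000,
    level: float = 95.0,
    seed: int | None = None,
) -> EquilibriumResult:
    """Percentile bootstrap interval for the equilibrium AT skew.

    The resampling unit is the SNP event: each replicate redraws the observed
    total from the multinomial over the 12 categories with the site
    composition held fixed, then recomputes rates, the stationary solve and
    the skew.  Replicates whose solve is degenerate are redrawn (count
    logged).
    """
    if counts.total == 0:
        raise ValueError("no SNPs to resample")
    rng = np.random.default_rng(seed)
    rates = rates_from_counts(counts, composition)
    f = equilibrium(rates)
    point = equilibrium_at_skew(f)
    skews, failures = _resample_skews(counts, composition, B, rng)
    if failures:
        logger.warning("%d bootstrap replicates redrawn after degenerate solves", failures)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(skews, [alpha, 100.0 - alpha])
    return EquilibriumResult(
        f=f, at_skew=point, ci_low=float(lo), ci_high=float(hi),
        B=B, level=level, bootstrap_skews=skews, n_failures=failures,
    )


def leave_k_out(
    counts: MutationCounts,
    composition,
    k: int = 3,
    sims: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Equilibrium skews after removing k SNPs at random, ``sims`` times.

    Each simulation removes k SNP events uniformly without replacement
    (multivariate hypergeometric over the 12 categories) and recomputes the
    equilibrium skew — a robustness check against a handful of hypothetical
    false-positive SNP calls.
    """
    if k >= counts.total:
        raise ValueError(f"k={k} must be smaller than the SNP total {counts.total}")
    rng = np.random.default_rng(seed)
    N = _as_composition(composition)
    flat = counts.matrix.flatten()
    if k == 0:
        removed = np.zeros((sims, 16), dtype=np.int64)
    else:
        removed = rng.multivariate_hypergeometric(flat, k, size=sims)
    kept = (flat[None, :] - removed).reshape(-1, 4, 4)
    rates = kept / N[None, :, None]
    f = batch_equilibrium(rates)
    return equilibrium_at_skew(f)


def age_class_randomization(
    counts_young: MutationCounts,
    counts_old: MutationCounts,
    composition,
    n_sims: int = 2000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Randomization test contrasting young and older SNP spectra.

    Observed statistic: |skew_eq(young) - skew_eq(old)|.  Null draws pool the
    two groups, resample with replacement, and randomly allocate events to
    groups of the original sizes (equivalently: both groups are independent
    multinomials from the pooled spectrum).  P = (r+1)/(n+1); degenerate
    replicates are redrawn and logged.
    """
    n1, n2 = counts_young.total, counts_old.total
    if n1 == 0 or n2 == 0:
        raise ValueError("both SNP groups must be non-empty")
    N = _as_composition(composition)
    sk_young = equilibrium_at_skew(equilibrium(rates_from_counts(counts_young, composition)))
    sk_old = equilibrium_at_skew(equilibrium(rates_from_counts(counts_old, composition)))
    observed = abs(sk_young - sk_old)

    pooled = (counts_young.matrix + counts_old.matrix).flatten()
    p = pooled / pooled.sum()
    rng = np.random.default_rng(seed)
    diffs = np.full(n_sims, np.nan)
    pending = np.arange(n_sims)
    failures = 0
    for _ in range(100):
        d1 = rng.multinomial(n1, p, size=len(pending)).reshape(-1, 4, 4)
        d2 = rng.multinomial(n2, p, size=len(pending)).reshape(-1, 4, 4)
        s1 = equilibrium_at_skew(batch_equilibrium(d1 / N[None, :, None]))
        s2 = equilibrium_at_skew(batch_equilibrium(d2 / N[None, :, None]))
        vals = np.abs(s1 - s2)
        ok = ~np.isnan(vals)
        diffs[pending[ok]] = vals[ok]
        failures += int((~ok).sum())
        pending = pending[~ok]
        if len(pending) == 0:
            break
    else:
        raise RuntimeError("randomization replicates repeatedly failed to solve")
    if failures:
        logger.warning("%d age-class replicates redrawn after degenerate solves", failures)
    r = int((diffs >= observed).sum())
    return PermutationTestResult(observed_difference=observed, r=r, n=n_sims)


def expected_false_positive_snps(
    n_target_bases: int,
    n_genome_bases: int,
    n_genomes: int,
    fp_per_genome: float = 1.0,
) -> float:
    """Expected miscalled SNPs landing in the analyzed site class.

    With a benchmarked false-positive rate of ``fp_per_genome`` miscalls per
    genome, the expectation is (target fraction of the genome) * rate *
    (number of genomes)."""
    return (n_target_bases / n_genome_bases) * fp_per_genome * n_genomes
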