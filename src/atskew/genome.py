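"""Genome ingestion, replichore geometry, and per-position site classification.

A circular bacterial chromosome is split by the origin (ori) and terminus
(ter) of replication into two replichores.  Within the ori->ter replichore
(increasing published-strand coordinates) the published strand is the
replicatory leading strand; within the other replichore the complement is
leading.  A gene is "leading-encoded" when its sense strand is the leading
strand of the replichore it sits in.

Every genomic position is classified into one of the site classes used for
skew accounting: codon position 1/2/3 (in the gene's reading frame, with
fourfold-degenerate third positions flagged), or intergenic (intra-operonic
when both flanking genes belong to the same operon on the same strand,
ex-operonic otherwise).  Positions that cannot be used are excluded with an
explicit reason (overlapping CDS, non-core, boundary trim, over-long
intergenic region, ambiguous base, ...).

Coordinates are 0-based half-open internally; GFF3 input is 1-based
inclusive and converted on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# site class codes
CLASS_INTERGENIC = 0
CLASS_CODON1 = 1
CLASS_CODON2 = 2
CLASS_CODON3 = 3
CLASS_NAMES = {
    CLASS_INTERGENIC: "intergenic",
    CLASS_CODON1: "codon1",
    CLASS_CODON2: "codon2",
    CLASS_CODON3: "codon3",
}

# operonic context codes
CONTEXT_NA = 0
CONTEXT_INTRA = 1
CONTEXT_EX = 2
CONTEXT_NAMES = {CONTEXT_NA: "not_applicable", CONTEXT_INTRA: "intra_operonic", CONTEXT_EX: "ex_operonic"}

# exclusion reason codes (0 = not excluded)
REASON_NONE = 0
REASON_NON_CORE = 1
REASON_PSEUDOGENE = 2
REASON_OVERLAP = 3
REASON_BOUNDARY_TRIM = 4
REASON_LENGTH_CAP = 5
REASON_AMBIGUOUS = 6
REASON_RNA_GENE = 7
REASON_BAD_FRAME = 8
REASON_NAMES = {
    REASON_NONE: "",
    REASON_NON_CORE: "non_core",
    REASON_PSEUDOGENE: "pseudogene",
    REASON_OVERLAP: "overlap",
    REASON_BOUNDARY_TRIM: "boundary_trim",
    REASON_LENGTH_CAP: "length_cap",
    REASON_AMBIGUOUS: "ambiguous_base",
    REASON_RNA_GENE: "rna_gene",
    REASON_BAD_FRAME: "bad_frame",
}


def _fourfold_prefixes() -> frozenset[str]:
    """Two-base codon prefixes whose amino acid is invariant to the third base
    (standard genetic code; identical to translation table 11 for sense codons)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    prefixes = set()
    for a in BASES:
        for b in BASES:
            aas = set()
            for c in BASES:
                codon = a + b + c
                aas.add(table.forward_table.get(codon, "*"))
            if len(aas) == 1 and "*" not in aas:
                prefixes.add(a + b)
    return frozenset(prefixes)


FOURFOLD_PREFIXES = _fourfold_prefixes()


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A single circular chromosome with replication origin and terminus."""

    id: str
    sequence: str
    ori: int = 0
    ter: int | None = None
    circular: bool = True

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
        if self.ter is None:
            # default: terminus at the antipode of the origin
            self.ter = (self.ori + len(self.sequence) // 2) % len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_array(self) -> np.ndarray:
        """Sequence as an int8 array with A,C,G,T -> 0..3 and N -> -1."""
        arr = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
        out = np.full(arr.shape, -1, dtype=np.int8)
        for b, i in BASE_INDEX.items():
            out[arr == ord(b)] = i
        return out


@dataclass
class GeneAnnotation:
    """One gene segment on the published strand, 0-based half-open.

    Wrap-around genes are represented as two segments sharing ``gene_id``;
    ``classify_sites`` joins them in transcription order for frame purposes.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    is_core: bool = True
    operon_id: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReplichoreMap:
    """Partition of the circle into the two replichores defined by ori and ter.

    Replichore 1 is the arc [ori, ter) in increasing published-strand
    coordinates; its leading strand is the published strand.  Replichore 2 is
    the remainder; its leading strand is the complement.
    """

    length: int
    ori: int
    ter: int

    def __post_init__(self):
        if self.ori == self.ter:
            raise ValueError("ori and ter must differ")
        for name, pos in (("ori", self.ori), ("ter", self.ter)):
            if not (0 <= pos < self.length):
                raise ValueError(f"{name}={pos} outside [0,{self.length})")

    def replichore_of(self, position):
        """1 for positions on the ori->ter arc, else 2 (vectorized)."""
        pos = np.asarray(position)
        if self.ori < self.ter:
            in1 = (pos >= self.ori) & (pos < self.ter)
        else:
            in1 = (pos >= self.ori) | (pos < self.ter)
        return np.where(in1, 1, 2)

    def published_is_leading(self, position):
        """True where the published strand is the leading strand."""
        return np.asarray(self.replichore_of(position)) == 1

    def leading_strand_of(self, replichore: int) -> str:
        return "published" if replichore == 1 else "complement"

    def gene_is_leading(self, gene: GeneAnnotation) -> bool:
        """Leading/lagging call for a gene; majority replichore wins for genes
        spanning the ori/ter boundary (with a logged warning)."""
        pos = np.arange(gene.start, gene.end)
        in1 = self.published_is_leading(pos)
        n1 = int(in1.sum())
        if 0 < n1 < len(pos):
            logger.warning(
                "gene %s spans a replichore boundary (%d/%d bases in replichore 1); "
                "assigned by majority", gene.gene_id, n1, len(pos),
            )
        majority_repl1 = n1 * 2 >= len(pos)
        return majority_repl1 == (gene.strand == "+")


def load_genome(path: str | Path, ori: int = 0, ter: int | None = None) -> Genome:
    """Read a single-record FASTA into a :class:`Genome` (uppercased)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected 1 record, found {len(records)}")
    rec = records[0]
    return Genome(id=rec.id, sequence=str(rec.seq), ori=ori, ter=ter)


_RNA_TYPES = {"rRNA", "tRNA", "ncRNA", "tmRNA", "RNA", "misc_RNA", "snRNA", "SRP_RNA", "RNase_P_RNA"}


def _is_pseudo(feature) -> bool:
    attrs = feature.attributes
    if feature.featuretype == "pseudogene":
        return True
    if "pseudo" in attrs or "pseudogene" in attrs:
        return True
    for key in ("product", "Note", "note", "description"):
        for val in attrs.get(key, []):
            low = val.lower()
            if "pseudogene" in low or "gene remnant" in low or "remnant" in low:
                return True
    return False


def load_annotation(
    path: str | Path,
    core_mask: list[tuple[int, int]] | None = None,
    genome_length: int | None = None,
    operons: dict[str, str] | None = None,
) -> list[GeneAnnotation]:
    """Load CDS and RNA gene features from GFF3 (1-based inclusive on disk).

    Features typed ``pseudogene`` or flagged as pseudogenes/gene remnants are
    dropped (collect them with :func:`pseudogene_intervals` if their footprint
    should be masked).  ``is_core`` is set from ``core_mask`` (0-based
    half-open intervals): a gene is core iff fully contained in the merged
    mask.  ``operons`` maps gene_id -> operon_id.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    merged_mask = merge_intervals(core_mask) if core_mask is not None else None
    out: list[GeneAnnotation] = []
    for feat in db.all_features():
        if feat.featuretype == "CDS":
            kind = "CDS"
        elif feat.featuretype in _RNA_TYPES:
            kind = "RNA"
        else:
            continue
        if _is_pseudo(feat):
            continue
        if feat.strand not in "+-":
            raise ValueError(f"feature {feat.id}: strand field must be + or -, got {feat.strand!r}")
        start, end = feat.start - 1, feat.end  # to 0-based half-open
        if genome_length is not None and end > genome_length:
            raise ValueError(f"feature {feat.id}: end {end} beyond genome length {genome_length}")
        gene_id = (
            feat.attributes.get("locus_tag", [None])[0]
            or feat.attributes.get("ID", [None])[0]
            or feat.id
        )
        is_core = True
        if merged_mask is not None:
            is_core = any(s <= start and end <= e for s, e in merged_mask)
        out.append(
            GeneAnnotation(
                gene_id=gene_id, start=start, end=end, strand=feat.strand, kind=kind,
                is_core=is_core, operon_id=(operons or {}).get(gene_id),
            )
        )
    return out


def pseudogene_intervals(path: str | Path) -> list[tuple[int, int]]:
    """0-based half-open footprints of pseudogene/remnant features in a GFF3."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    return [(f.start - 1, f.end) for f in db.all_features() if _is_pseudo(f)]


def load_core_mask(path: str | Path) -> list[tuple[int, int]]:
    """Read a BED file (0-based half-open) of core-genome intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[1, 2], names=["start", "end"])
    return [(int(s), int(e)) for s, e in zip(df["start"], df["end"])]


def load_operon_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (gene_id, operon_id) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if "gene_id" not in cols or "operon_id" not in cols:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "operon_id"], dtype=str)
    return dict(zip(df["gene_id"], df["operon_id"]))


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def build_replichore_map(genome: Genome, ori: int | None = None, ter: int | None = None) -> ReplichoreMap:
    return ReplichoreMap(
        length=genome.length,
        ori=genome.ori if ori is None else ori,
        ter=genome.ter if ter is None else ter,
    )


def detect_ter_by_cumulative_skew(genome: Genome, base_pair: str = "GC") -> int:
    """Locate the terminus as the extremum of the cumulative GC (or AT) skew.

    Provided as an optional diagnostic; it is never applied silently — the
    default terminus is the antipode of the origin.
    """
    arr = genome.base_array()
    if base_pair == "GC":
        signal = (arr == BASE_INDEX["G"]).astype(np.int64) - (arr == BASE_INDEX["C"])
    else:
        signal = (arr == BASE_INDEX["A"]).astype(np.int64) - (arr == BASE_INDEX["T"])
    cum = np.cumsum(np.roll(signal, -genome.ori))
    return int((np.argmax(cum) + genome.ori + 1) % genome.length)


@dataclass
class IntergenicRegion:
    """A spacer between two consecutive genes on the circle.

    ``start``/``end`` are published-strand coordinates with ``end`` possibly
    exceeding the genome length for the single region that wraps the origin
    of coordinates (positions are taken modulo the length).
    """

    start: int
    end: int
    genome_length: int
    flank_5_gene: GeneAnnotation  # gene ending at `start` (published coords)
    flank_3_gene: GeneAnnotation  # gene starting at `end` (published coords)
    operonic: str = "ex"  # "intra" | "ex"
    trimmed: tuple[int, int] | None = None  # half-open, None if dropped
    excluded_reason: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def transcription_context_strand(self) -> str:
        a, b = self.flank_5_gene.strand, self.flank_3_gene.strand
        return a if a == b else "mixed"

    def positions(self, trimmed: bool = False) -> np.ndarray:
        if trimmed:
            if self.trimmed is None:
                return np.empty(0, dtype=np.int64)
            s, e = self.trimmed
        else:
            s, e = self.start, self.end
        return np.arange(s, e) % self.genome_length


def _genic_intervals(annotations, extra=()):
    ivs = [(g.start, g.end) for g in annotations]
    ivs.extend(extra)
    return merge_intervals(ivs)


def extract_intergenic(
    annotations: list[GeneAnnotation],
    genome: Genome,
    max_len: int = 500,
    trim: int = 60,
    extra_genic: list[tuple[int, int]] = (),
) -> list[IntergenicRegion]:
    """Circular gaps between genes, with the eligibility and trimming rules.

    Regions with raw length > ``max_len`` are excluded entirely (reason
    ``length_cap``); surviving regions lose ``trim`` bases at each end, and
    regions of raw length <= 2*trim end up empty (reason ``boundary_trim``).
    ``extra_genic`` intervals (e.g. pseudogene footprints) bound regions but
    produce no flanking-gene metadata of their own.
    """
    if trim < 0 or max_len <= 0:
        raise ValueError("require trim >= 0 and max_len > 0")
    L = genome.length
    merged = _genic_intervals(annotations, extra_genic)
    if not merged:
        return []

    def gene_ending_at(pos):
        cands = [g for g in annotations if g.end % L == pos % L]
        return max(cands, key=lambda g: g.length) if cands else None

    def gene_starting_at(pos):
        cands = [g for g in annotations if g.start % L == pos % L]
        return max(cands, key=lambda g: g.length) if cands else None

    regions = []
    for i, (s, e) in enumerate(merged):
        nxt = merged[(i + 1) % len(merged)]
        gap_start = e
        gap_end = nxt[0] if nxt[0] > e else nxt[0] + L  # wrap region unrolled
        if gap_end == gap_start:
            continue
        g5 = gene_ending_at(gap_start)
        g3 = gene_starting_at(gap_end % L)
        if g5 is None or g3 is None:
            # flanked by a masked (non-gene) footprint; still a region but
            # context is indeterminate -> treat as ex-operonic with the
            # nearest flanks available
            g5 = g5 or g3
            g3 = g3 or g5
            if g5 is None:
                continue
        operonic = (
            "intra"
            if (g5.operon_id is not None and g5.operon_id == g3.operon_id and g5.strand == g3.strand)
            else "ex"
        )
        region = IntergenicRegion(
            start=gap_start, end=gap_end, genome_length=L,
            flank_5_gene=g5, flank_3_gene=g3, operonic=operonic,
        )
        raw = region.length
        if raw > max_len:
            region.excluded_reason = "length_cap"
        elif raw <= 2 * trim:
            region.excluded_reason = "boundary_trim"
        else:
            region.trimmed = (gap_start + trim, gap_end - trim)
        regions.append(region)
    return regions


@dataclass
class SiteClassification:
    """Per-position site labels for a genome, stored as parallel arrays.

    ``site_class``: 0 intergenic, 1/2/3 codon positions.
    ``fourfold``: True only at fourfold-degenerate codon3 positions.
    ``context``: operonic context for intergenic sites.
    ``orientation``: 1 where the site's reading strand is the leading strand
    (for coding sites: the gene is leading-encoded; for intra-operonic
    spacers: the operon's transcription strand is leading; ex-operonic
    spacers are read on the leading strand, hence always 1).
    ``sense``: reading strand in published terms, +1 published / -1
    complement / 0 undefined.
    ``excluded``: nonzero reason code where the position is unusable.
    """

    site_class: np.ndarray
    fourfold: np.ndarray
    context: np.ndarray
    orientation: np.ndarray
    sense: np.ndarray
    excluded: np.ndarray

    @property
    def length(self) -> int:
        return len(self.site_class)

    def usable(self) -> np.ndarray:
        return self.excluded == REASON_NONE

    def class_mask(self, name: str, orientation: str | None = None) -> np.ndarray:
        """Boolean mask of usable positions of a named class.

        Names: codon1, codon2, codon3, fourfold, intergenic,
        intergenic_intra, intergenic_ex.
        """
        ok = self.usable()
        if name == "fourfold":
            m = ok & self.fourfold
        elif name == "intergenic":
            m = ok & (self.site_class == CLASS_INTERGENIC)
        elif name == "intergenic_intra":
            m = ok & (self.site_class == CLASS_INTERGENIC) & (self.context == CONTEXT_INTRA)
        elif name == "intergenic_ex":
            m = ok & (self.site_class == CLASS_INTERGENIC) & (self.context == CONTEXT_EX)
        elif name in ("codon1", "codon2", "codon3"):
            m = ok & (self.site_class == int(name[-1]))
        else:
            raise KeyError(name)
        if orientation is not None:
            want = 1 if orientation == "leading" else 0
            m = m & (self.orientation == want)
        return m

    def summary(self) -> dict[str, int]:
        counts = {}
        ok = self.usable()
        for code, nm in CLASS_NAMES.items():
            counts[nm] = int((ok & (self.site_class == code)).sum())
        counts["fourfold"] = int((ok & self.fourfold).sum())
        counts["intra_operonic"] = int(self.class_mask("intergenic_intra").sum())
        counts["ex_operonic"] = int(self.class_mask("intergenic_ex").sum())
        for code, nm in REASON_NAMES.items():
            if code:
                counts[f"excluded_{nm}"] = int((self.excluded == code).sum())
        counts["excluded_total"] = int((~ok).sum())
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(self.length),
                "class": [CLASS_NAMES[c] for c in self.site_class],
                "fourfold": self.fourfold.astype(int),
                "operonic_context": [CONTEXT_NAMES[c] for c in self.context],
                "orientation": np.where(self.orientation == 1, "leading", "lagging"),
                "excluded_reason": [REASON_NAMES[c] for c in self.excluded],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def classify_sites(
    genome: Genome,
    annotations: list[GeneAnnotation],
    replichore_map: ReplichoreMap | None = None,
    max_intergenic: int = 500,
    trim: int = 60,
    core_mask: list[tuple[int, int]] | None = None,
    pseudogene_footprints: list[tuple[int, int]] = (),
) -> SiteClassification:
    """Label every genomic position with its site class and reading strand.

    CDS positions get codon positions 1/2/3 in the gene's reading frame
    (wrap/split genes are joined by shared gene_id in transcription order);
    fourfold-degenerate third positions are flagged.  Positions covered by
    two or more CDS are excluded (``overlap``); RNA-gene interiors, N bases,
    non-core positions and pseudogene footprints are excluded with their own
    reasons.  Intergenic positions follow the eligibility (``max_intergenic``)
    and end-trimming (``trim``) rules of :func:`extract_intergenic`.
    """
    L = genome.length
    rmap = replichore_map or build_replichore_map(genome)
    site_class = np.zeros(L, dtype=np.int8)
    fourfold = np.zeros(L, dtype=bool)
    context = np.zeros(L, dtype=np.int8)
    orientation = np.zeros(L, dtype=np.int8)
    sense = np.zeros(L, dtype=np.int8)
    excluded = np.zeros(L, dtype=np.int8)

    pub_leading = rmap.published_is_leading(np.arange(L))

    cds = [g for g in annotations if g.kind == "CDS"]
    rnas = [g for g in annotations if g.kind != "CDS"]

    # coverage over CDS only: frame ambiguity is a CDS-on-CDS problem
    coverage = np.zeros(L, dtype=np.int16)
    for g in cds:
        coverage[np.arange(g.start, g.end) % L] += 1

    # group CDS segments by gene id (wrap-around genes are split segments)
    by_id: dict[str, list[GeneAnnotation]] = {}
    for g in cds:
        by_id.setdefault(g.gene_id, []).append(g)

    for gene_id, segs in by_id.items():
        segs = sorted(segs, key=lambda s: s.start)
        strand = segs[0].strand
        pub_positions = np.concatenate([np.arange(s.start, s.end) for s in segs])
        # transcription order: published order for +, reversed for -
        pos = pub_positions if strand == "+" else pub_positions[::-1]
        if len(pos) % 3 != 0:
            logger.warning("CDS %s length %d not divisible by 3; excluded", gene_id, len(pos))
            excluded[pub_positions % L] = REASON_BAD_FRAME
            continue
        leading = rmap.gene_is_leading(segs[0]) if len(segs) == 1 else rmap.gene_is_leading(
            GeneAnnotation(gene_id, segs[0].start, segs[-1].end, strand)
        )
        idx = pos % L
        codon_pos = (np.arange(len(pos)) % 3) + 1
        site_class[idx] = codon_pos.astype(np.int8)
        orientation[idx] = 1 if leading else 0
        sense[idx] = 1 if strand == "+" else -1
        # fourfold flags on third positions, read in the gene's sense
        seq = "".join(genome.sequence[p] for p in idx)
        if strand == "-":
            seq = seq.translate(COMPLEMENT)
        for k in range(0, len(seq) - 2, 3):
            if seq[k : k + 2] in FOURFOLD_PREFIXES:
                fourfold[idx[k + 2]] = True

    # RNA genes: genic but not codon-classified
    for g in rnas:
        idx = np.arange(g.start, g.end) % L
        excluded[idx] = REASON_RNA_GENE

    # intergenic gaps with eligibility and trimming
    extra = list(pseudogene_footprints) + [(g.start, g.end) for g in rnas]
    regions = extract_intergenic(annotations, genome, max_len=max_intergenic, trim=trim, extra_genic=extra)
    for region in regions:
        all_pos = region.positions(trimmed=False)
        if region.excluded_reason == "length_cap":
            excluded[all_pos] = REASON_LENGTH_CAP
            continue
        kept = region.positions(trimmed=True)
        trimmed_away = np.setdiff1d(all_pos, kept, assume_unique=True)
        excluded[trimmed_away] = REASON_BOUNDARY_TRIM
        if len(kept) == 0:
            continue
        site_class[kept] = CLASS_INTERGENIC
        if region.operonic == "intra":
            context[kept] = CONTEXT_INTRA
            strand = region.flank_5_gene.strand
            sense[kept] = 1 if strand == "+" else -1
            # leading where the transcription strand is the leading strand
            orientation[kept] = ((strand == "+") == pub_leading[kept]).astype(np.int8)
        else:
            context[kept] = CONTEXT_EX
            # ex-operonic sequence is read on the leading strand per replichore
            sense[kept] = np.where(pub_leading[kept], 1, -1).astype(np.int8)
            orientation[kept] = 1

    # overlapping CDS positions: frame is ambiguous
    excluded[coverage >= 2] = REASON_OVERLAP

    # pseudogene footprints
    for s, e in pseudogene_footprints:
        excluded[np.arange(s, e) % L] = REASON_PSEUDOGENE

    # core mask: positions outside the merged mask are non-core
    if core_mask is not None:
        in_core = np.zeros(L, dtype=bool)
        for s, e in merge_intervals(core_mask):
            in_core[np.arange(s, e) % L] = True
        excluded[~in_core] = REASON_NON_CORE

    # ambiguous bases override everything
    excluded[genome.base_array() < 0] = REASON_AMBIGUOUS

    # excluded positions carry no class/orientation semantics
    bad = excluded != REASON_NONE
    fourfold[bad] = False
    sense[bad] = 0

    return SiteClassification(site_class, fourfold, context, orientation, sense, excluded)


def leading_coding_fraction(
    annotations: list[GeneAnnotation], replichore_map: ReplichoreMap, core_only: bool = True
) -> float:
    """Fraction of (core) coding bases encoded on the leading strand."""
    genes = [g for g in annotations if g.kind == "CDS" and (g.is_core or not core_only)]
    total = sum(g.length for g in genes)
    if total == 0:
        raise ValueError("no coding bases")
    leading = sum(g.length for g in genes if replichore_map.gene_is_leading(g))
    return leading / total
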