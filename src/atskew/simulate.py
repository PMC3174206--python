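"""Synthetic genomes with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes: a
circular chromosome with an ori/ter replichore split, genes placed in
operons and co-oriented with the replication fork with a configurable
probability, stop-free codon content drawn from a per-strand codon model,
intergenic spacers filled iid from strand-specific base frequencies, and
SNPs sprinkled onto eligible ex-operonic sites from a fixed 12-rate
mutation matrix.  Everything emitted is paired with a truth bundle (exact
per-position site classes, per-gene orientation, the rate matrix's
stationary distribution, per-SNP categories) so classification, skew and
equilibrium estimates can be checked against known answers.

Default parameters mirror the Staphylococcus aureus TW20 study system:
~2.8 Mb, ~2,500 genes, 78% leading-strand gene orientation, 140 singleton
and 54 older SNPs, and the TW20 leading-strand singleton rate matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import STOP_CODONS, codon_draw_distribution
from .genome import (
    BASES,
    CLASS_INTERGENIC,
    CONTEXT_EX,
    CONTEXT_INTRA,
    FOURFOLD_PREFIXES,
    REASON_BOUNDARY_TRIM,
    REASON_LENGTH_CAP,
    Genome,
    GeneAnnotation,
    ReplichoreMap,
    SiteClassification,
    revcomp,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _default_leading_freqs() -> np.ndarray:
    from .datasets import tw20_leading_intergenic_freqs

    return tw20_leading_intergenic_freqs()


def _default_rates() -> np.ndarray:
    from .datasets import tw20_leading_rates

    return tw20_leading_rates()


@dataclass
class SynthConfig:
    """Parameters of the synthetic study system (defaults at TW20 scale)."""

    genome_length: int = 2_800_000
    ori: int = 0
    ter: int | None = None  # default: antipode
    n_genes: int = 2500
    gene_length_codons: tuple[float, float] = (300.0, 80.0)  # mean, sd of aa codons
    leading_orientation_prob: float = 0.78
    operon_mean_genes: float = 3.0
    intra_spacer_mean: float = 80.0  # exponential; some spacers survive 60 bp trimming
    ex_spacer_range: tuple[int, int] = (150, 460)  # within the 500 bp eligibility cap
    intergenic_freqs_leading: np.ndarray | None = None  # ACGT, read on leading strand
    intergenic_freqs_lagging: np.ndarray | None = None  # default: complement of leading
    codon_model_leading: pd.Series | None = None  # default: stop-free draw from freqs
    codon_model_lagging: pd.Series | None = None
    mutation_rates: np.ndarray | None = None  # 4x4 leading-strand per-site rates
    n_singletons: int = 140
    n_older_snps: int = 54
    older_multiplicity_range: tuple[int, int] = (2, 4)
    max_intergenic: int = 500
    trim: int = 60
    seed: int = 0

    def resolved(self) -> "SynthConfig":
        cfg = replace(self)
        if cfg.ter is None:
            cfg.ter = cfg.genome_length // 2
        if cfg.intergenic_freqs_leading is None:
            cfg.intergenic_freqs_leading = _default_leading_freqs()
        cfg.intergenic_freqs_leading = np.asarray(cfg.intergenic_freqs_leading, dtype=float)
        if cfg.intergenic_freqs_lagging is None:
            cfg.intergenic_freqs_lagging = cfg.intergenic_freqs_leading[[3, 2, 1, 0]]
        cfg.intergenic_freqs_lagging = np.asarray(cfg.intergenic_freqs_lagging, dtype=float)
        if cfg.codon_model_leading is None:
            cfg.codon_model_leading = codon_draw_distribution(cfg.intergenic_freqs_leading)
        if cfg.codon_model_lagging is None:
            cfg.codon_model_lagging = codon_draw_distribution(cfg.intergenic_freqs_lagging)
        if cfg.mutation_rates is None:
            cfg.mutation_rates = _default_rates()
        cfg.mutation_rates = np.asarray(cfg.mutation_rates, dtype=float)
        if not (0 <= cfg.ori < cfg.ter < cfg.genome_length):
            raise ValueError("generator requires 0 <= ori < ter < genome_length")
        return cfg


@dataclass
class TruthBundle:
    classification: SiteClassification
    gene_is_leading: dict[str, bool]
    stationary: np.ndarray  # of mutation_rates, ACGT
    stationary_at_skew: float
    config: SynthConfig


@dataclass
class SyntheticGenome:
    genome: Genome
    annotations: list[GeneAnnotation]
    operons: dict[str, str]
    truth: TruthBundle

    def replichore_map(self) -> ReplichoreMap:
        return ReplichoreMap(self.genome.length, self.genome.ori, self.genome.ter)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit FASTA, GFF3, operon TSV, all-core BED, and a truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        fasta = outdir / "genome.fasta"
        with open(fasta, "w") as fh:
            fh.write(f">{self.genome.id}\n")
            seq = self.genome.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
        paths["fasta"] = fasta
        gff = outdir / "genes.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.genome.id} 1 {self.genome.length}\n")
            for g in self.annotations:
                attrs = f"ID={g.gene_id};locus_tag={g.gene_id}"
                fh.write(
                    f"{self.genome.id}\tatskew_synth\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
                )
        paths["gff3"] = gff
        operons = outdir / "operons.tsv"
        pd.DataFrame(
            {"gene_id": list(self.operons), "operon_id": list(self.operons.values())}
        ).to_csv(operons, sep="\t", index=False)
        paths["operons"] = operons
        bed = outdir / "core.bed"
        with open(bed, "w") as fh:
            fh.write(f"{self.genome.id}\t0\t{self.genome.length}\n")
        paths["core_bed"] = bed
        truth = outdir / "truth.json"
        with open(truth, "w") as fh:
            json.dump(
                {
                    "stationary": dict(zip(BASES, self.truth.stationary.tolist())),
                    "stationary_at_skew": self.truth.stationary_at_skew,
                    "gene_is_leading": self.truth.gene_is_leading,
                    "n_genes": len(self.truth.gene_is_leading),
                    "class_counts": self.truth.classification.summary(),
                },
                fh,
                indent=1,
            )
        paths["truth"] = truth
        return paths


def _draw_gene_codons(rng, cfg) -> int:
    mean, sd = cfg.gene_length_codons
    return max(50, int(round(rng.normal(mean, sd))))


def generate_genome(config: SynthConfig | None = None) -> SyntheticGenome:
    """Build a synthetic chromosome plus its ground truth.

    Genes are packed into operons along the circle starting at the origin:
    each operon's orientation is leading with the configured probability
    (relative to the replichore it starts in), genes are a start codon plus
    iid stop-free codons plus a stop codon, operon members are separated by
    short intra-operonic spacers, and operons by ex-operonic spacers.
    Operons never cross the terminus or the origin; the gap is padded with
    intergenic sequence instead.  Raises on infeasible packing.
    """
    from .equilibrium import equilibrium, equilibrium_at_skew

    cfg = (config or SynthConfig()).resolved()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length
    rmap = ReplichoreMap(L, cfg.ori, cfg.ter)

    seq = np.full(L, "N", dtype="U1")
    site_class = np.zeros(L, dtype=np.int8)
    fourfold = np.zeros(L, dtype=bool)
    context = np.zeros(L, dtype=np.int8)
    orientation = np.zeros(L, dtype=np.int8)
    sense = np.zeros(L, dtype=np.int8)
    excluded = np.zeros(L, dtype=np.int8)

    codon_choices = {
        True: (np.array(cfg.codon_model_leading.index), cfg.codon_model_leading.to_numpy()),
        False: (np.array(cfg.codon_model_lagging.index), cfg.codon_model_lagging.to_numpy()),
    }
    stops = np.array(STOP_CODONS)

    annotations: list[GeneAnnotation] = []
    operons: dict[str, str] = {}
    gene_is_leading: dict[str, bool] = {}
    gene_intervals: list[tuple[int, int]] = []

    cursor = cfg.ori + int(rng.integers(*cfg.ex_spacer_range))
    placed = 0
    operon_idx = 0
    boundaries = [cfg.ter, L]  # operons may not cross these
    while placed < cfg.n_genes:
        k = min(1 + rng.poisson(max(cfg.operon_mean_genes - 1.0, 0.0)), cfg.n_genes - placed)
        codons_per_gene = [_draw_gene_codons(rng, cfg) for _ in range(k)]
        intra_lens = [max(1, int(round(rng.exponential(cfg.intra_spacer_mean)))) for _ in range(k - 1)]
        operon_len = sum(3 * (c + 2) for c in codons_per_gene) + sum(intra_lens)
        boundary = next((b for b in boundaries if cursor < b), None)
        if boundary is None:
            raise ValueError(
                f"infeasible packing: {cfg.n_genes - placed} genes left beyond the genome end"
            )
        if cursor + operon_len > boundary:
            if boundary == L:
                raise ValueError(
                    f"infeasible packing: {cfg.n_genes - placed} genes left with "
                    f"{L - cursor} bases of genome remaining"
                )
            cursor = boundary  # pad to ter with intergenic; region may exceed the cap
            continue
        leading = bool(rng.random() < cfg.leading_orientation_prob)
        repl = int(rmap.replichore_of(cursor))
        strand = "+" if (repl == 1) == leading else "-"
        operon_idx += 1
        operon_id = f"op{operon_idx:05d}"
        members = []
        for gi, n_codons in enumerate(codons_per_gene):
            gene_id = f"gene{placed + 1:05d}"
            choices, probs = codon_choices[leading]
            body = "".join(rng.choice(choices, size=n_codons, p=probs))
            sense_seq = "ATG" + body + str(rng.choice(stops))
            pub_seq = sense_seq if strand == "+" else revcomp(sense_seq)
            start, end = cursor, cursor + len(sense_seq)
            seq[start:end] = list(pub_seq)
            pub_positions = np.arange(start, end)
            pos = pub_positions if strand == "+" else pub_positions[::-1]
            site_class[pos] = ((np.arange(len(pos)) % 3) + 1).astype(np.int8)
            orientation[pub_positions] = 1 if leading else 0
            sense[pub_positions] = 1 if strand == "+" else -1
            for ci in range(0, len(sense_seq) - 2, 3):
                if sense_seq[ci : ci + 2] in FOURFOLD_PREFIXES:
                    fourfold[pos[ci + 2]] = True
            annotations.append(
                GeneAnnotation(gene_id=gene_id, start=start, end=end, strand=strand,
                               kind="CDS", is_core=True, operon_id=operon_id)
            )
            operons[gene_id] = operon_id
            gene_is_leading[gene_id] = leading
            gene_intervals.append((start, end))
            members.append(gene_id)
            placed += 1
            cursor = end
            if gi < k - 1:
                cursor += intra_lens[gi]
        cursor += int(rng.integers(*cfg.ex_spacer_range))
        # transcription order within a '-' operon runs right-to-left on the
        # published strand; member order is irrelevant to the site statistics

    # ---- intergenic truth: circular gaps between genes -------------------
    gaps = []
    ivs = sorted(gene_intervals)
    for i, (s, e) in enumerate(ivs):
        nxt_start = ivs[(i + 1) % len(ivs)][0]
        gap_end = nxt_start if nxt_start > e else nxt_start + L
        if gap_end > e:
            gaps.append((e, gap_end))
    by_start = {g.start: g for g in annotations}
    by_end = {g.end: g for g in annotations}
    pub_leading_all = rmap.published_is_leading(np.arange(L))
    freq_lead = cfg.intergenic_freqs_leading
    for gap_start, gap_end in gaps:
        positions = np.arange(gap_start, gap_end) % L
        # fill sequence: draw on the leading strand, complement where the
        # published strand is lagging
        lead_bases = rng.choice(list(BASES), size=len(positions), p=freq_lead)
        pub = np.where(
            pub_leading_all[positions], lead_bases, [_COMP[b] for b in lead_bases]
        )
        seq[positions] = pub
        g5 = by_end[gap_start % L]
        g3 = by_start[gap_end % L]
        raw = gap_end - gap_start
        if raw > cfg.max_intergenic:
            excluded[positions] = REASON_LENGTH_CAP
            continue
        if raw <= 2 * cfg.trim:
            excluded[positions] = REASON_BOUNDARY_TRIM
            continue
        kept = np.arange(gap_start + cfg.trim, gap_end - cfg.trim) % L
        trimmed_away = np.concatenate(
            [np.arange(gap_start, gap_start + cfg.trim), np.arange(gap_end - cfg.trim, gap_end)]
        ) % L
        excluded[trimmed_away] = REASON_BOUNDARY_TRIM
        site_class[kept] = CLASS_INTERGENIC
        intra = (
            g5 is not None
            and g5.operon_id == g3.operon_id
            and g5.strand == g3.strand
        )
        if intra:
            context[kept] = CONTEXT_INTRA
            sense[kept] = 1 if g5.strand == "+" else -1
            orientation[kept] = ((g5.strand == "+") == pub_leading_all[kept]).astype(np.int8)
        else:
            context[kept] = CONTEXT_EX
            sense[kept] = np.where(pub_leading_all[kept], 1, -1).astype(np.int8)
            orientation[kept] = 1

    assert not (seq == "N").any()
    genome = Genome(id=f"synth_{cfg.seed}", sequence="".join(seq), ori=cfg.ori, ter=cfg.ter)
    classification = SiteClassification(site_class, fourfold, context, orientation, sense, excluded)
    stationary = equilibrium(cfg.mutation_rates)
    truth = TruthBundle(
        classification=classification,
        gene_is_leading=gene_is_leading,
        stationary=stationary,
        stationary_at_skew=equilibrium_at_skew(stationary),
        config=cfg,
    )
    return SyntheticGenome(genome=genome, annotations=annotations, operons=operons, truth=truth)


def sprinkle_snps(
    synth: SyntheticGenome,
    n_singletons: int | None = None,
    n_older: int | None = None,
    rates: np.ndarray | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Drop SNPs onto eligible ex-operonic intergenic sites.

    Sites come from the truth classification (ex-operonic, trimmed, i.e. at
    least ``trim`` bases from any gene and inside the length cap).  Expected
    category counts follow N_i * r_ij over the 12 leading-strand categories;
    per drawn category a site with leading-strand ancestral base i is picked
    uniformly without replacement and the derived base is j.  The emitted
    table is on the published strand (the reference keeps ancestral bases,
    so ancestral truth is the reference base); ``true_category`` records the
    leading-strand i->j label.
    """
    cfg = synth.truth.config
    n_singletons = cfg.n_singletons if n_singletons is None else n_singletons
    n_older = cfg.n_older_snps if n_older is None else n_older
    R = np.asarray(cfg.mutation_rates if rates is None else rates, dtype=float)
    rng = np.random.default_rng(cfg.seed + 7919 if seed is None else seed)
    cls = synth.truth.classification
    eligible = np.flatnonzero(cls.class_mask("intergenic_ex"))
    if len(eligible) == 0:
        raise ValueError("no eligible ex-operonic sites")
    arr = synth.genome.base_array()[eligible]
    lead_is_pub = cls.sense[eligible] == 1
    comp = np.array([3, 2, 1, 0])
    lead_base = np.where(lead_is_pub, arr, comp[arr])

    sites_by_base = {i: eligible[lead_base == i] for i in range(4)}
    N = np.array([len(sites_by_base[i]) for i in range(4)], dtype=float)
    weights = (N[:, None] * R).flatten()
    weights[:: 5] = 0.0  # diagonal
    p = weights / weights.sum()

    used: set[int] = set()
    rows = []
    total = n_singletons + n_older
    cats = rng.multinomial(total, p).reshape(4, 4)
    snp_index = 0
    multiplicities = np.concatenate(
        [
            np.ones(n_singletons, dtype=int),
            rng.integers(cfg.older_multiplicity_range[0], cfg.older_multiplicity_range[1] + 1, size=n_older),
        ]
    )
    rng.shuffle(multiplicities)
    for i in range(4):
        for j in range(4):
            if i == j or cats[i, j] == 0:
                continue
            pool = [s for s in sites_by_base[i] if s not in used]
            if len(pool) < cats[i, j]:
                raise ValueError("not enough eligible sites for the requested SNP count")
            chosen = rng.choice(pool, size=cats[i, j], replace=False)
            for pos in chosen:
                used.add(int(pos))
                pub_is_lead = bool(cls.sense[pos] == 1)
                anc_lead, der_lead = BASES[i], BASES[j]
                anc_pub = anc_lead if pub_is_lead else _COMP[anc_lead]
                der_pub = der_lead if pub_is_lead else _COMP[der_lead]
                rows.append(
                    {
                        "position": int(pos),
                        "ancestral": anc_pub,
                        "derived": der_pub,
                        "multiplicity": int(multiplicities[snp_index]),
                        "site_context": "intergenic_ex",
                        "orientation": "leading" if pub_is_lead else "lagging",
                        "true_category": anc_lead + der_lead,
                    }
                )
                snp_index += 1
    df = pd.DataFrame(rows).sort_values("position").reset_index(drop=True)
    return df


def snps_to_records(df: pd.DataFrame):
    """Convert a sprinkled SNP table to SnpRecord objects."""
    from .equilibrium import SnpRecord

    return [
        SnpRecord(
            position=int(r.position), ancestral=str(r.ancestral), derived=str(r.derived),
            multiplicity=int(r.multiplicity), site_context=str(r.site_context),
            orientation=str(r.orientation),
        )
        for r in df.itertuples(index=False)
    ]


def write_snp_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
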