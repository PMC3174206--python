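"""Genome loading, replichore geometry, and site classification."""

import numpy as np
import pytest
from Bio.Seq import Seq

from atskew import (
    GeneAnnotation,
    Genome,
    ReplichoreMap,
    build_replichore_map,
    classify_sites,
    extract_intergenic,
    leading_coding_fraction,
    load_annotation,
    load_genome,
    revcomp,
)
from atskew.genome import CLASS_CODON2, CLASS_CODON3, REASON_NONE


def write_fasta(tmp_path, records):
    path = tmp_path / "genome.fasta"
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


GFF_HEADER = "##gff-version 3\n"


def write_gff(tmp_path, lines):
    path = tmp_path / "genes.gff3"
    path.write_text(GFF_HEADER + "".join(lines))
    return path


class TestLoadGenome:
    def test_single_record_identity(self, tmp_path):
        path = write_fasta(tmp_path, [("chr", "ATGAAATAGGGC")])
        g = load_genome(path)
        assert g.length == 12
        assert g.sequence == "ATGAAATAGGGC"

    def test_lowercase_normalized(self, tmp_path):
        up = load_genome(write_fasta(tmp_path, [("chr", "ATGAAATAGGGC")]))
        low = load_genome(write_fasta(tmp_path, [("chr", "atgaaataGGGC")]))
        assert up.sequence == low.sequence

    def test_multiple_records_rejected(self, tmp_path):
        path = write_fasta(tmp_path, [("a", "ACGT"), ("b", "ACGT")])
        with pytest.raises(ValueError, match="expected 1 record, found 2"):
            load_genome(path)

    def test_default_ter_is_antipode(self):
        g = Genome(id="x", sequence="A" * 100, ori=10)
        assert g.ter == 60


class TestLoadAnnotation:
    def test_coordinates_converted_to_half_open(self, tmp_path):
        gff = write_gff(tmp_path, ["chr\tsrc\tCDS\t1\t9\t.\t+\t0\tID=g1\n"])
        genes = load_annotation(gff)
        assert (genes[0].start, genes[0].end) == (0, 9)

    def test_pseudogenes_dropped(self, tmp_path):
        gff = write_gff(
            tmp_path,
            [
                "chr\tsrc\tCDS\t1\t9\t.\t+\t0\tID=g1\n",
                "chr\tsrc\tpseudogene\t20\t40\t.\t+\t.\tID=p1\n",
                "chr\tsrc\tCDS\t50\t70\t.\t-\t0\tID=g2;note=gene remnant\n",
            ],
        )
        genes = load_annotation(gff)
        assert [g.gene_id for g in genes] == ["g1"]

    def test_core_mask_sets_flag(self, tmp_path):
        gff = write_gff(
            tmp_path,
            [
                "chr\tsrc\tCDS\t1\t9\t.\t+\t0\tID=g1\n",
                "chr\tsrc\tCDS\t101\t130\t.\t+\t0\tID=g2\n",
            ],
        )
        genes = load_annotation(gff, core_mask=[(0, 50)])
        flags = {g.gene_id: g.is_core for g in genes}
        assert flags == {"g1": True, "g2": False}

    def test_feature_beyond_genome_rejected(self, tmp_path):
        gff = write_gff(tmp_path, ["chr\tsrc\tCDS\t1\t99\t.\t+\t0\tID=g1\n"])
        with pytest.raises(ValueError, match="beyond genome length"):
            load_annotation(gff, genome_length=50)


class TestReplichoreMap:
    @pytest.fixture
    def rmap(self):
        return ReplichoreMap(length=100, ori=0, ter=50)

    def test_first_replichore_is_published_leading(self, rmap):
        assert rmap.replichore_of(10) == 1
        assert rmap.published_is_leading(10)
        assert rmap.leading_strand_of(1) == "published"

    def test_second_replichore_complement_leading(self, rmap):
        assert rmap.replichore_of(60) == 2
        assert not rmap.published_is_leading(60)
        assert rmap.leading_strand_of(2) == "complement"

    def test_published_gene_in_second_replichore_is_lagging(self, rmap):
        gene = GeneAnnotation("g", 60, 70, "+")
        assert not rmap.gene_is_leading(gene)

    def test_ori_equals_ter_rejected(self):
        with pytest.raises(ValueError):
            ReplichoreMap(length=100, ori=5, ter=5)

    def test_wrapping_replichore(self):
        rmap = ReplichoreMap(length=100, ori=80, ter=30)
        assert rmap.replichore_of(90) == 1
        assert rmap.replichore_of(10) == 1
        assert rmap.replichore_of(50) == 2


class TestClassification:
    def test_round_trip_matches_generator_truth(self, small_synth):
        """Classification recovered from FASTA-level data must equal the
        generator's ground truth at every position, exactly."""
        cls = classify_sites(
            small_synth.genome, small_synth.annotations, small_synth.replichore_map()
        )
        truth = small_synth.truth.classification
        for name in ("site_class", "fourfold", "context", "orientation", "sense", "excluded"):
            assert (getattr(cls, name) == getattr(truth, name)).all(), name

    def test_partition_covers_genome(self, small_synth):
        s = small_synth.truth.classification.summary()
        total = s["intergenic"] + s["codon1"] + s["codon2"] + s["codon3"] + s["excluded_total"]
        assert total == small_synth.genome.length

    def test_complement_symmetry(self, small_synth):
        """Reverse-complementing the genome and mirroring ori/ter and the
        annotation leaves every leading/lagging and class call invariant."""
        g = small_synth.genome
        L = g.length
        mirrored = Genome(
            id="mirror", sequence=revcomp(g.sequence),
            ori=(L - g.ori) % L, ter=(L - g.ter) % L,
        )
        flipped = [
            GeneAnnotation(
                gene_id=a.gene_id, start=L - a.end, end=L - a.start,
                strand="-" if a.strand == "+" else "+",
                kind=a.kind, is_core=a.is_core, operon_id=a.operon_id,
            )
            for a in small_synth.annotations
        ]
        rmap_m = build_replichore_map(mirrored)
        for a, b in zip(small_synth.annotations, flipped):
            assert small_synth.replichore_map().gene_is_leading(a) == rmap_m.gene_is_leading(b)
        cls = classify_sites(mirrored, flipped, rmap_m)
        truth = small_synth.truth.classification
        rev = slice(None, None, -1)
        assert (cls.site_class[rev] == truth.site_class).all()
        assert (cls.fourfold[rev] == truth.fourfold).all()
        assert (cls.orientation[rev] == truth.orientation).all()
        assert (cls.excluded[rev] == truth.excluded).all()

    def test_fourfold_agrees_with_translation_oracle(self, small_synth):
        """Brute-force oracle: a third position is fourfold iff translating
        all four third-base variants gives one amino acid."""
        cls = small_synth.truth.classification
        genome = small_synth.genome
        rng = np.random.default_rng(0)
        third = np.flatnonzero((cls.site_class == CLASS_CODON3) & (cls.excluded == REASON_NONE))
        for pos in rng.choice(third, size=300, replace=False):
            sense = cls.sense[pos]
            if sense == 1:
                codon = genome.sequence[pos - 2 : pos + 1]
            else:
                codon = revcomp(genome.sequence[pos : pos + 3])
            aas = {str(Seq(codon[:2] + b).translate(table=11)) for b in "ACGT"}
            assert (len(aas) == 1 and "*" not in aas) == bool(cls.fourfold[pos]), (pos, codon)

    def test_codon_positions_in_frame(self):
        genome = Genome(id="t", sequence="ATGGCTTAA" + "A" * 91, ori=0, ter=50)
        gene = GeneAnnotation("g1", 0, 9, "+")
        cls = classify_sites(genome, [gene], max_intergenic=1000, trim=0)
        # the C of GCT is the 5th base -> codon position 2
        assert cls.site_class[4] == CLASS_CODON2
        # third position of GCT (Ala, fourfold); stop codon third base is not
        assert cls.fourfold[5]
        assert not cls.fourfold[8]

    def test_frame_broken_cds_excluded_not_fatal(self, caplog):
        genome = Genome(id="t", sequence="ATGGCTTA" + "A" * 92, ori=0, ter=50)
        gene = GeneAnnotation("g1", 0, 8, "+")  # length 8, not divisible by 3
        with caplog.at_level("WARNING"):
            cls = classify_sites(genome, [gene])
        assert (cls.excluded[:8] != REASON_NONE).all()
        assert "not divisible by 3" in caplog.text

    def test_overlapping_cds_excluded(self):
        genome = Genome(id="t", sequence="ATG" * 40, ori=0, ter=60)
        genes = [GeneAnnotation("g1", 0, 30, "+"), GeneAnnotation("g2", 24, 60, "+")]
        cls = classify_sites(genome, genes)
        from atskew.genome import REASON_OVERLAP

        assert (cls.excluded[24:30] == REASON_OVERLAP).all()
        assert (cls.excluded[0:24] != REASON_OVERLAP).all()


class TestIntergenic:
    def make(self, gap):
        # two + strand genes separated by `gap` bases on a linear-ish circle
        L = 600 + gap + 1200  # generous tail so the wrap region is capped out
        left = "ATG" + "GCT" * 98 + "TAA"
        right = "ATG" + "GCT" * 98 + "TAA"
        middle = "ACGT" * (gap // 4) + "ACGT"[: gap % 4]
        tail = "A" * (L - 2 * len(left) - gap)
        genome = Genome(id="t", sequence=left + middle + right + tail, ori=0, ter=L // 2)
        genes = [
            GeneAnnotation("g1", 0, len(left), "+"),
            GeneAnnotation("g2", len(left) + gap, len(left) + gap + len(right), "+"),
        ]
        return genome, genes

    @pytest.mark.parametrize(
        "gap,expected_trimmed", [(200, 80), (501, None), (120, None), (121, 1)]
    )
    def test_trim_and_cap_rules(self, gap, expected_trimmed):
        genome, genes = self.make(gap)
        regions = extract_intergenic(genes, genome, max_len=500, trim=60)
        region = next(r for r in regions if r.start == genes[0].end)
        if gap == 501:
            assert region.excluded_reason == "length_cap"
            assert region.trimmed is None
        elif expected_trimmed is None:
            assert region.excluded_reason == "boundary_trim"
            assert region.trimmed is None
        else:
            s, e = region.trimmed
            assert e - s == expected_trimmed

    def test_operonic_context_requires_shared_operon_and_strand(self):
        genome, genes = self.make(200)
        for a, b, expected in [
            ("op1", "op1", "intra"),
            ("op1", "op2", "ex"),
            (None, None, "ex"),
        ]:
            genes[0].operon_id, genes[1].operon_id = a, b
            region = next(
                r
                for r in extract_intergenic(genes, genome)
                if r.start == genes[0].end
            )
            assert region.operonic == expected


class TestLeadingFraction:
    def test_extremes(self):
        rmap = ReplichoreMap(length=1000, ori=0, ter=500)
        leading = [GeneAnnotation(f"g{i}", i * 50, i * 50 + 30, "+") for i in range(5)]
        assert leading_coding_fraction(leading, rmap) == 1.0
        mixed = leading + [GeneAnnotation(f"h{i}", i * 50, i * 50 + 30, "-") for i in range(5, 10)]
        assert leading_coding_fraction(mixed, rmap) == 0.5

    def test_no_genes_rejected(self):
        rmap = ReplichoreMap(length=1000, ori=0, ter=500)
        with pytest.raises(ValueError):
            leading_coding_fraction([], rmap)

    def test_recovers_generator_truth(self, small_synth):
        rmap = small_synth.replichore_map()
        frac = leading_coding_fraction(small_synth.annotations, rmap)
        truth = small_synth.truth.gene_is_leading
        lengths = {a.gene_id: a.length for a in small_synth.annotations}
        expected = sum(lengths[g] for g, lead in truth.items() if lead) / sum(lengths.values())
        assert frac == pytest.approx(expected)
        # and the generator draws orientation at the configured probability
        p = small_synth.truth.config.leading_orientation_prob
        n = len(truth)
        se = (p * (1 - p) / n) ** 0.5
        assert abs(sum(truth.values()) / n - p) < 4 * se
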