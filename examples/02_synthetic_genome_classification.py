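"""Generate a synthetic chromosome and classify every position.

The generator plants known structure (78% leading-strand gene orientation,
stop-free codon content, operons, trimmed intergenic spacers); the
classifier recovers it from the FASTA/GFF level and the per-class skew
table shows how skew concentrates in sense-direction codon sites.
"""

from atskew import (
    SynthConfig,
    classify_sites,
    generate_genome,
    leading_coding_fraction,
    site_class_skew_table,
)

cfg = SynthConfig(genome_length=200_000, n_genes=130, gene_length_codons=(180.0, 40.0), seed=42)
synth = generate_genome(cfg)
rmap = synth.replichore_map()

cls = classify_sites(synth.genome, synth.annotations, rmap)
truth = synth.truth.classification
exact = all(
    (getattr(cls, a) == getattr(truth, a)).all()
    for a in ("site_class", "fourfold", "context", "orientation", "sense", "excluded")
)
print(f"classification matches generator truth exactly: {exact}")
print("class counts:", {k: v for k, v in cls.summary().items() if v and not k.startswith("excluded")})

frac = leading_coding_fraction(synth.annotations, rmap)
print(f"leading-strand coding fraction: {frac:.3f} (generator drew at 0.78)")

table = site_class_skew_table(cls, synth.genome, synth.annotations)
print(table[["site_class", "orientation", "n_bases", "at_skew"]].to_string(index=False))
# First-position sense skew is strongly positive on both strands (stop
# avoidance in the codon model); ex-operonic rows mirror each other exactly.
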