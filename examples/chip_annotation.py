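"""Genomic-context classification of TF ChIP peaks.

Places 200 synthetic ChIP peaks at an exact 35/34/26/5 promoter /
gene-body / upstream / intergenic mix, then recovers that composition
with the midpoint-to-nearest-TSS classifier after 300 bp resizing.
"""

from gonadomics import (
    SimDesign,
    classify_context,
    context_composition,
    resize_peaks,
    simulate_chip_peaks,
    simulate_multiome,
)

sim = simulate_multiome(SimDesign(seed=3))
design = SimDesign(seed=3, n_chip_peaks=200, chip_overlap_frac={})
chip, truth = simulate_chip_peaks(design, sim.genes, sim.truth["da_peaks"],
                                  sim.peaks)

chip300 = resize_peaks(chip, 300)
annotated = classify_context(chip300, sim.genes)
comp = context_composition(annotated)
print("recovered context composition (%):")
print(comp.to_string())
print("\nplanted composition (%): promoter 35, gene_body 34, upstream 26, "
      "intergenic 5")
print("Classification keys on the peak midpoint: promoter is within 1 kb "
      "upstream of the nearest TSS, upstream reaches to -10 kb, and the "
      "recovered split equals the planted one exactly because placement "
      "is unambiguous by construction.")
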