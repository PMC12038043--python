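"""DA-peak x ChIP overlap and peak-gene linkage.

Builds the full synthetic study (ChIP coverage 43.7% / 3.8% of the two
DA sides, links planted for ~48% of DA peaks), detects DA peaks, and
reports the overlap and linked fractions with the truncation rule used
for the printed percentages.
"""

from gonadomics import da_test, link_peaks, linked_fraction, overlap_fraction
from gonadomics.dataset import build_bundle

bundle = build_bundle(seed=7)
sim = bundle.sim
labels = sim.cells["cluster_label"].to_numpy()
cov = sim.cells["n_frag_in_peaks"].to_numpy(float)

da = da_test(sim.atac, labels, "c0", "c3", cov)
links = link_peaks(sim.atac, sim.rna, sim.peaks, sim.genes, cov)

for side, direction in (("c0 (progenitor)", "up_in_a"),
                        ("c3 (Leydig-like)", "up_in_b")):
    names = da.loc[da["significant"] & (da["direction"] == direction),
                   "feature_id"]
    rep = overlap_fraction(sim.peaks.subset(names), bundle.chip, side)
    lrep = linked_fraction(names, links, side)
    print(f"{side}: {rep['n_overlapping']}/{rep['n_da_peaks']} "
          f"({rep['percent']}%) DA peaks contain a ChIP peak; "
          f"{lrep['n_overlapping']}/{lrep['n_da_peaks']} "
          f"({lrep['percent']}%) are linked to a gene")

print("\nPercentages are truncated (never rounded up) to one decimal, "
      "the convention that reproduces the printed pairs such as "
      "169/386 -> 43.7%. The progenitor side is ChIP-rich and the "
      "Leydig side ChIP-poor, matching the designed asymmetry.")
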