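"""Validate transfers: annotation overlap between aligned proteins, and
disorder calls from AlphaFold plDDT confidence.

When two rows of an alignment are independently annotated, the overlap of
their annotations (as a percent of the reference region's columns) measures
how well homology transfer would have predicted the second annotation.  The
plDDT classifier calls residues disordered below 0.7 confidence.
"""

from idptransfer.io import AnnotatedRegion, Msa
from idptransfer.validation import (
    annotation_overlap,
    classify_disorder_plddt,
    overlap_distribution,
)

msa = Msa(["human", "mouse"],
          ["MDAQTRRESLSSGFHDELNGSH", "MDAQSRR-SLSSGFHDELNGSH"], "human")

ref_region = AnnotatedRegion("DPr001", "human", 3, 14, "IDPO:00076", "disorder")
mouse_regions = [
    AnnotatedRegion("DPr101", "mouse", 5, 12, "IDPO:00076", "disorder"),
    AnnotatedRegion("DPr102", "mouse", 16, 20, "GO:0005515", "protein binding"),
]
result = annotation_overlap(msa, ref_region, "mouse", mouse_regions)
print(f"overlap of {ref_region.region_id} with mouse annotations: "
      f"{result.overlap_percent:.1f}% (best match {result.other_region_id}, "
      f"decile bin {result.bin})")
# Only same-namespace terms compete (the GO region is ignored here); the
# percent is normalized by the reference region's 12 columns.

hist = overlap_distribution([result])
print("decile histogram:", {k: v for k, v in hist.items() if v})

plddt = [0.92, 0.88, 0.75, 0.55, 0.41, 0.38, 0.62, 0.81]
calls = classify_disorder_plddt(plddt, cutoff=0.7)
print("plDDT calls: ", ", ".join(f"{v:.2f}={c[:3]}" for v, c in zip(plddt, calls)))
print(f"{calls.count('disordered')}/{len(calls)} residues called disordered "
      "(plDDT < 0.7)")
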