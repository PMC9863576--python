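"""Consolidate the published hotspot table: widths, grouping, merging.

Recomputes the physical confidence interval of each selected hotspot from
its flanking-marker positions, groups hotspots by genome, and fuses the
two pairs whose physical intervals overlap.
"""

from medscan.datasets import load_reference_hotspots
from medscan.hotspots import (genome_counts, hotspots_from_frame, merge_overlapping,
                              mta_sigma, physical_interval, select_hotspots)

hs = [physical_interval(h) for h in hotspots_from_frame(load_reference_hotspots())]

ref = load_reference_hotspots()
exact = sum(h.ci_mb == printed for h, printed in zip(hs, ref["ci_mb"]))
print(f"{exact}/{len(hs)} physical CIs recomputed exactly from flanking "
      "marker positions")

kept = select_hotspots(hs, max_ci_mb=20.0)
print(f"{len(kept)} hotspots within 20 Mb; per genome {genome_counts(kept)}")

merged = merge_overlapping(kept)
fused = [h for h in merged if "-" in h.name]
for h in fused:
    print(f"merged {h.name}: {h.bp_interval[0]:.0f}-{h.bp_interval[1]:.0f} bp "
          f"({h.ci_mb} Mb), classes {sorted(h.trait_classes)}")
print(f"{len(merged)} regions remain after merging")

# An association's position density: a chromosome with 10 cM LD decay
# spreads each MTA as a Gaussian of sd CI/3.92
print(f"sigma for a 10 cM LD extent: {mta_sigma(10.0):.3f} cM")
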