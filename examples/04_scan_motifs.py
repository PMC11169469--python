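"""hnRNPL binding-motif annotation of a skipped-exon event.

Scans the skipped exon, the adjacent introns and the adjacent exons (in
transcribed orientation) for the canonical consensus ACACACA/ACACAAA and
for bounded-gap CA repeats (3 or 4 CA units, ≤2 bases between units).
"""

from orthosplice import GenomeSource, MotifSpec
from orthosplice.diff_events import EventKey
from orthosplice.motif_scan import build_scan_region, scan_region

contig = ("T" * 100 + "GCGC"                 # 5'-adjacent exon
          + "T" * 20 + "CATTCATCA" + "T" * 21   # upstream intron, CA-rich
          + "ACACACAGGGTTT"                  # skipped exon with consensus
          + "T" * 50 + "GGCC" + "T" * 30)
genome = GenomeSource("toy", {"c": contig})
event = EventKey("mouse", "GeneX", "c", "+",
                 target=(154, 167), left_flank=(100, 104),
                 right_flank=(217, 221))

region = build_scan_region(event, genome)
for name, seq in region.segments.items():
    print(f"{name:18s} {len(seq):3d} nt")

annotation = scan_region(region, MotifSpec())
print(f"\nhas_canonical={annotation.has_canonical} "
      f"has_ca_rich={annotation.has_ca_rich}")
for hit in annotation.hits:
    print(f"  {hit.segment:18s} {hit.motif_id:9s} offset {hit.offset:3d} "
          f"{hit.matched}")
print("\ncanonical = exact ACACACA/ACACAAA; ca3/ca4 = CA repeats within "
      "10/14 nt.")
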