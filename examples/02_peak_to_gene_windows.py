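"""Assign peaks to genes through promoter / gene-body / distal windows.

Two genes on opposite strands; four peaks probing each window category.
The promoter window is TSS +-5 kb (strand-aware anchor), the gene body is
the rest of the transcript, and anything within 25 kb of a transcript
edge is distal.
"""

from cotarget import AssignmentConfig, GenomicInterval, TranscriptModel, assign_peaks

iv = GenomicInterval

genes = [
    TranscriptModel("GENE_PLUS", "tx_plus", iv("chr1", 100_000, 140_000), "+"),
    TranscriptModel("GENE_MINUS", "tx_minus", iv("chr1", 300_000, 340_000), "-"),
]
peaks = [
    iv("chr1", 97_000, 97_400),    # 3 kb upstream of the + TSS: promoter
    iv("chr1", 120_000, 120_300),  # mid-transcript, past +5 kb: gene body
    iv("chr1", 150_000, 150_300),  # 10 kb past the + gene end: distal
    iv("chr1", 342_000, 342_300),  # 2 kb beyond the - gene's right edge = its TSS side: promoter
    iv("chr1", 500_000, 500_300),  # > 25 kb from everything: unassigned
]

assignments, bound = assign_peaks(peaks, genes, AssignmentConfig())
for a in assignments:
    print(f"{a.peak} -> {a.gene_id:10s} {a.category:9s} distance={a.distance}")
print(f"\nbound genes: {sorted(bound)}")
print("the fifth peak is beyond the distal limit of both genes, so it binds nothing")
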