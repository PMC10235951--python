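"""Euplotid translation and stop-free ORF scanning.

Under the euplotid nuclear code (NCBI table 10) UGA encodes cysteine, so
only UAA/UAG interrupt a reading frame — and in *Euplotes* even those mark
+1/+2 frameshift points rather than termination.  This example translates a
short sequence under both codes and lists the maximal stop-free ORF runs
the detector stitches together.
"""

from euplofs import EUPLOTID, STANDARD, find_orfs, translate

seq = "ATGAAATGAGCTAAA" + "T" + "AGGATTGCTGA"  # AAA_TAG +1 junction after codon 5

print("standard :", translate(seq, STANDARD))
print("euplotid :", translate(seq, EUPLOTID))
print()
print("maximal stop-free ORF runs (start, end, frame, codons):")
for orf in find_orfs(seq):
    print(f"  {orf.start:3d} {orf.end:3d}  frame {orf.frame}  {orf.n_codons} codons")
print()
print(
    "The two translations differ only where the sequence contains TGA\n"
    "(a stop under the standard code, cysteine 'C' under the euplotid one);\n"
    "the frame-0 run ends where the TAG frameshift stop begins, and a\n"
    "frame-1 run resumes one nucleotide into that stop — the +1 join the\n"
    "detector looks for."
)
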