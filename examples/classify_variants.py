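"""Classify SNVs against a toy gene model.

Builds a two-exon gene (CDS ``ATGAAACCCTAG``) and classifies a handful of
substitutions: a missense change, a stop gain, a silent change and a splice
donor hit.
"""

from snvsieve import VariantKey
from snvsieve.consequence import GeneModel, Transcript, classify

import numpy as np

rng = np.random.default_rng(0)
background = "".join(rng.choice(list("ACGT"), size=120))
# exon 1: positions 21-31 (UTR 21-24, CDS 25-31), intron 32-61,
# exon 2: 62-71 (CDS 62-66, UTR 67-71); CDS = ATGAAAC | CCTAG
cds = "ATGAAACCCTAG"
seq = background[:20] + "NNNN" + cds[:7] + background[31:61] + cds[7:] \
    + "NNNNN" + background[76:]
seq = seq.replace("N", "T")
model = GeneModel(sequences={"1": seq})
model.add_transcript(Transcript(
    transcript_id="TX1", gene_id="DEMO", chrom="1", strand="+",
    exons=[(21, 31), (62, 71)], cds=[(25, 31), (62, 66)],
))

examples = [
    ("missense (AAA->CAA, K->Q)", VariantKey("1", 28, "A", "C")),
    ("stop gain (AAA->TAA)", VariantKey("1", 28, "A", "T")),
    ("silent (CCC->CCA, P->P)", VariantKey("1", 63, "C", "A")),
    ("splice donor +2", VariantKey("1", 33, seq[32],
                                   "A" if seq[32] != "A" else "G")),
    ("deep intronic", VariantKey("1", 45, seq[44],
                                 "A" if seq[44] != "A" else "G")),
]
for label, key in examples:
    (ann,) = classify(key, model)
    print(f"{label:28s} {key}  ->  {ann.consequence}"
          + (f" (exon {ann.exon_index})" if ann.exon_index else ""))
print("\nEach substitution gets exactly one class per transcript, by the "
      "precedence splice > nonsense > missense > silent > UTR > intronic.")
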