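"""De novo gene hits in a parent-child trio.

A child carries three variants: one also seen in the father, one in the
mother, and one in neither parent.  Only the last is de novo — present in
the child, absent from both parents.
"""

import snvsieve as sv

cohort = sv.Cohort([
    sv.SampleMeta("child", group="case", father_id="father",
                  mother_id="mother"),
    sv.SampleMeta("father", group="parent"),
    sv.SampleMeta("mother", group="parent"),
])
inherited_p = sv.VariantKey("2", 1000, "G", "A")
inherited_m = sv.VariantKey("3", 2000, "C", "T")
fresh = sv.VariantKey("7", 3000, "A", "G")
for key, carriers in [(inherited_p, ["child", "father"]),
                      (inherited_m, ["child", "mother"]),
                      (fresh, ["child"])]:
    for sid in carriers:
        cohort.add_observation(sv.VariantObservation(key, sid, 40, 19))
for key, gene in [(inherited_p, "GENE_A"), (inherited_m, "GENE_B"),
                  (fresh, "GENE_C")]:
    cohort.add_annotation(sv.VariantAnnotation(
        key=key, gene_id=gene, transcript_id=f"{gene}.t1",
        consequence="nonsynonymous", exon_index=1,
    ))

hits = sv.call_denovo(cohort, "child")
print("de novo hits:", {u: [str(k) for k in ks]
                        for (u, s), ks in hits.hits.items()})
print("\nGENE_C is the only de novo hit: its variant has no stored call in "
      "either parent.  Variants observed in a parent are inherited, not de "
      "novo.  Absence of a call conflates reference-equal with no-call; see "
      "the min_parent_coverage gate for requiring coverage evidence.")
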