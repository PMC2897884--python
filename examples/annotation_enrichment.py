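"""Cumulative-binomial enrichment of annotations in a selected gene set.

For each annotation, x carriers among n selected genes are compared with
the background carrier fraction p; the p-value is 1 - B(x; n, p), the
probability of seeing MORE than x carriers by chance.  Annotations need
p < 0.001 and at least 10 carriers to be reported.
"""

from rnamend.enrichment import AnnotationTally, annotation_enrichment, cumulative_binomial

print("B(2; 5, 0.5) =", cumulative_binomial(2, 5, 0.5), "(16 of 32 outcomes)\n")

tallies = [
    # annotation, carriers in set, set size, background fraction
    AnnotationTally("carbohydrate metabolism", x=42, n=300, p=0.05),
    AnnotationTally("membrane", x=60, n=300, p=0.15),
    AnnotationTally("ribosome", x=25, n=300, p=0.02),
    AnnotationTally("rare but tiny set", x=6, n=300, p=0.001),   # < 10 carriers
    AnnotationTally("not enriched", x=16, n=300, p=0.05),
]
print(f"{'annotation':<26} {'x':>4} {'p_bg':>6} {'p_value':>10}")
for r in annotation_enrichment(tallies, p_cut=0.001, min_models=10):
    print(f"{r.annotation:<26} {r.x:>4} {r.p:>6.3f} {r.p_value:>10.3g}")
# "rare but tiny set" is absent despite a small p-value (fewer than 10
# carriers); "not enriched" is absent because 16/300 is what p=0.05 predicts.
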