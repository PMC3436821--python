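"""Test one gene measured in three before/after pairs.

The counts (57, 95), (27, 50), (55, 135) are consistently lower before
treatment; every sample shares the total 13,331,120.  The inverted
beta-binomial test combines the three 2x2 tables into one common
fold-change estimate with a likelihood-ratio p-value, here under three
technical-variation models (standard Poisson, and exponentiated Poisson
with v = 5 and v = 0.2).
"""

from ibbpair import FeaturePairSet, PairedCountTable, ibb_test, per_pair_estimates

TOTAL = 13_331_120
pairs = FeaturePairSet(
    "gene1",
    tuple(
        PairedCountTable(a, b, TOTAL, TOTAL, f"subject{i + 1}")
        for i, (a, b) in enumerate([(57, 95), (27, 50), (55, 135)])
    ),
)

for v in (1.0, 5.0, 0.2):
    res = ibb_test(pairs, v=v)
    print(
        f"v={v:>3}: fold change = {res.fold_change:.3f} "
        f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f}), "
        f"S = {res.statistic:.3f}, p = {res.p_value:.4f}"
    )

print()
print("forest records (log fold change, v = 1):")
for rec in per_pair_estimates(pairs):
    print(
        f"  {rec.label:>9}: {rec.log_fold:+.3f} "
        f"[{rec.ci_low:+.3f}, {rec.ci_high:+.3f}]  weight {rec.weight:.2f}"
    )
print()
print("A fold change of ~0.5 means the gene is about half as abundant before")
print("treatment; p < 0.05 for v = 1 indicates a significant common effect.")
print("The over-dispersed platform (v = 0.2) widens the intervals and raises p.")
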