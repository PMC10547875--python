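"""JZS Bayes factors for model-vs-data correlations.

For a Pearson correlation r over n subjects, the default two-sided JZS Bayes
factor quantifies the evidence for a nonzero population correlation against
the null.  BF10 > 3 is conventionally "moderate" evidence for a correlation,
BF10 < 1/3 evidence for its absence.
"""

from chronobayes import jzs_corr_bf10

n = 30
print(f"{'r':>7} {'BF10':>10}")
for r in (0.1, 0.304, 0.316, 0.378, 0.471, 0.492, 0.527, 0.560, 0.640, 0.817):
    print(f"{r:7.3f} {jzs_corr_bf10(r, n):10.1f}")
print(f"\n(n = {n}; the BF grows without bound as |r| -> 1)")
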