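"""JZS Bayes factors for t statistics, with interpretive labels.

The default Bayes factor compares H1 (effect size ~ Cauchy(0, 0.707))
against the point null, turning a t statistic and sample size into a
graded evidence ratio.  BF_null = 1/BF10 states the evidence *for* the
null — the natural summary when two conditions are meant to be matched.
"""

from metaconf import bf_category, jzs_bf_ttest

print(f"{'t':>6}{'n':>5}{'BF10':>9}{'BF_null':>9}   category")
for t, n in [(0.5, 20), (2.23, 20), (2.98, 20), (3.89, 20), (4.23, 20), (6.0, 20)]:
    res = jzs_bf_ttest(t, n)
    print(f"{t:>6.2f}{n:>5}{res.bf10:>9.2f}{res.bf_null:>9.2f}   {res.category}")

print("\nBands: <3 not worth more than a bare mention, 3-20 positive,")
print("20-150 strong, >150 very strong. A t of 0.5 at n=20 yields")
print(f"BF_null = {jzs_bf_ttest(0.5, 20).bf_null:.2f}: moderate evidence that "
      "the conditions truly do not differ.")
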