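"""One-way ANOVA rebuilt from published group summaries (mean +/- SE, n).

Culture experiments usually print per-group means with standard errors
rather than raw replicate values; `anova_from_summary` reconstructs the
full sums-of-squares table from exactly that, here for life expectancy at
hatching across three culture media.
"""

from rotipop import GroupSummary, anova_from_summary, anova_oneway, posthoc_letters

summaries = [
    GroupSummary("SE", 85.60, 2.85, 3),
    GroupSummary("SEB", 97.87, 3.60, 3),
    GroupSummary("NW", 104.80, 3.92, 3),
]
res = anova_from_summary(summaries, se_mode=True)
for key, value in res.to_dict().items():
    print(f"{key:>12s}  {value:.3f}")

# ss_between ~ 567.2 is driven only by the three means and n; ss_within is
# rebuilt from the SEs as sum (n-1) * n * SE^2 and carries their rounding.

# with raw replicate values the same table comes from anova_oneway, and a
# post-hoc letter display marks which media differ:
raw = [[84.1, 83.9, 88.8], [95.2, 103.1, 95.3], [101.0, 112.3, 101.1]]
letters = posthoc_letters(raw, method="snk", labels=["SE", "SEB", "NW"])
print("letters:", letters, "| F =", round(anova_oneway(raw).F, 2))
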