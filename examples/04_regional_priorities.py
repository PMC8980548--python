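"""Decide each region's 1-2 priority molecules.

Per region, molecule shares are computed among patients sensitized to at
least one panel molecule. If the top share beats the runner-up by more
than 5 points the top molecule wins outright; otherwise a one-sample
Student's t step decides whether the runner-up's claim to being a maximum
is as strong as the leader's, in which case both are reported. Small
groups are excluded with an explicit reason rather than dropped.
"""

from hdmprof import binarize, classify_all_regions, generate, preset_ukraine_like, with_seed

cohort = generate(with_seed(preset_ukraine_like(n_patients=5000), seed=42))
matrix = binarize(cohort)

print(f"{'region':<16} {'priority':<22} {'rule':<17} excluded")
for d in classify_all_regions(cohort, matrix, by="all"):
    label = " + ".join(d.priority) if d.priority else "-"
    rule = d.trace.rule_path or "-"
    print(f"{d.region:<16} {label:<22} {rule:<17} {d.excluded_reason}")
print()
print("'margin_single' means the top molecule led by >5 share points;")
print("'ttest_pair' means the t step kept both near-tied maxima;")
print("Zakarpattia and Khmelnytskyi show the preset's built-in Der p 23 dominance.")
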