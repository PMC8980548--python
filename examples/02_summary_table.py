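"""Per-molecule prevalence summary: counts, shares and mean sIgE.

For each panel molecule: how many sensitized patients carry it, what
percentage of all HDM-sensitized patients that is, and the mean +/- sigma
sIgE level among those positive for it.
"""

from hdmprof import binarize, generate, preset_ukraine_like, summarize, with_seed

cohort = generate(with_seed(preset_ukraine_like(n_patients=5000), seed=42))
matrix = binarize(cohort)

print(f"{'molecule':<10} {'n':>5} {'share %':>8} {'mean sIgE':>10} {'sigma':>7}")
for row in summarize(cohort, matrix, group="all"):
    print(
        f"{row.molecule:<10} {row.n_sensitized:>5} {row.share_pct:>8.2f} "
        f"{row.mean_sige:>10.2f} {row.sd_sige:>7.2f}"
    )
print()
print("Shares are percentages of patients sensitized to >=1 panel molecule;")
print("means are over positives only, hence always >= the 0.35 kU/L cut-off.")
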