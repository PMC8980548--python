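# hdmprof

Molecular sensitization profiling of multiplex house-dust-mite (HDM)
specific-IgE panels.

## The problem

Component-resolved allergy diagnostics measures serum IgE against individual
allergenic proteins rather than whole extracts. For house dust mites
(*Dermatophagoides pteronyssinus* and *D. farinae*) the clinically relevant
panel is eleven molecules — Der f 1, Der f 2, Der p 1, Der p 2, Der p 5,
Der p 7, Der p 10, Der p 11, Der p 20, Der p 21, Der p 23 — and the pattern
of which molecules a patient is sensitized to (their *profile*) predicts both
disease course and the likely benefit of allergen immunotherapy. Population
studies therefore need, from a table of per-patient sIgE levels:

* **binarization** — a patient is sensitized to a molecule iff
  sIgE ≥ 0.35 kU/L (inclusive);
* **prevalence summaries** — per molecule, the count *nₘ* of sensitized
  patients, its share 100·nₘ/N among the N patients sensitized to ≥1 panel
  molecule, and mean ± σ sIgE over positives, overall and by age group
  (child < 18 y / adult);
* **profile enumeration** — each sensitized patient's exact positive set;
  profiles are counted, ranked and classed mono- vs poly-sensitization;
* **regional priority molecules** — per region (and region × age group),
  molecule shares sₘ = nₘ/N are ranked; if the top share beats the runner-up
  by more than a 5-point margin the top molecule alone is the region's
  priority. Otherwise a one-sample Student's *t* step decides: for each
  molecule with sₘ > 0, the upper-tail test of the full share series against
  popmean sₘ gives a p-value (t = (x̄ − sₘ)/(s/√k), k = series length), and
  the runner-up is kept as a second priority iff its p-value lies within 5%
  (relative) of the absolute maximum's. Region-groups with no sensitized
  patients, or fewer than 3, are excluded with an explicit reason.

Because cohort-scale patient data are rarely shareable, the package includes
a synthetic cohort generator: a Gaussian-copula latent-threshold model with
configurable marginal prevalences per region × age group, a latent
correlation matrix for co-sensitization structure, and log-normal sIgE
levels among positives. A documented preset emulates a national testing
population (16 regions, ~58% children, strongly correlated group-1/group-2
major allergens, two Western regions biased toward Der p 23 dominance).

## Worked example

```python
from hdmprof import (binarize, classify_all_regions, enumerate_profiles,
                     generate, preset_ukraine_like, with_seed)

cohort = generate(with_seed(preset_ukraine_like(n_patients=5000), seed=42))
matrix = binarize(cohort)                     # 0/1 at 0.35 kU/L

table = enumerate_profiles(cohort, matrix)
for p in table.profiles[:3]:
    print(f"{p.share_pct:6.2f}%  {p.label}")

for d in classify_all_regions(cohort, matrix, by="all")[:3]:
    print(d.region, "->", " + ".join(d.priority), f"({d.trace.rule_path})")
```

prints

```
 10.07%  Der f 2+Der p 2
  7.83%  Der p 23
  7.61%  Der f 2
Cherkasy -> Der p 2 (margin_single)
Chernivtsi -> Der f 2 (margin_single)
Dnipropetrovsk -> Der p 2 + Der f 2 (ttest_pair)
```

The modal profile is exclusive co-sensitization to the two group-2 major
allergens (10.07% of the 1,787 sensitized patients); 7.83% are
monosensitized to the peritrophin-like Der p 23. Per region, `margin_single`
means one molecule led by more than 5 share points, `ttest_pair` means the
*t* step retained two near-tied maxima. The scripts in `examples/` walk
through each capability (simulation, summary table, profile ranking,
regional priorities) and explain the printed numbers.

A thin CLI wraps the same functions:

```bash
hdmprof simulate --n 5000 --seed 42 --out cohort.tsv
hdmprof run --in cohort.tsv --outdir results/
```

`run` emits `summary.tsv`, `profiles.tsv`, `regions.tsv`,
`regions_trace.tsv` (the per-molecule p-value map behind each decision) and
a `manifest.json` with the resolved configuration and input checksum; reruns
on identical input are byte-identical.

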