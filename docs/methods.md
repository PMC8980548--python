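# Methods

## Binarization and strata

Specific IgE to a molecule is dichotomized at 0.35 kU/L, the conventional
multiplex-assay positivity cut-off, with an **inclusive** comparison
(level ≥ 0.35 → 1) and no epsilon slack. The threshold is a config value
(`BinarizationConfig`), not a constant; nothing downstream re-reads raw
levels except the mean ± σ summaries.

Age strata use the strict paediatric convention: *child* ⇔ age < 18 years,
so age exactly 18 is adult. Fractional ages are accepted. The boundary is a
single documented convention rather than a tunable, because mixing
conventions across stages would silently change denominators.

All prevalence-style shares within the analysis use the
**sensitized-to-any denominator**: the number of patients in the group
positive for at least one panel molecule. The cohort-wide rate (denominator
= everyone tested) is a separate, explicitly named function
(`cohort_prevalence_pct`); conflating the two is the easiest way to corrupt
this kind of analysis. Mean ± σ sIgE is computed over positives only —
including sub-threshold values would drag every mean below biologically
reported magnitudes — and σ is the population standard deviation (÷n),
matching the M ± σ reporting convention; the n−1 estimator is available via
`sample_sd=True`.

Reported percentages are rounded half-up to two decimals using exact
decimal arithmetic (`compute_share`), so arithmetic on printed count tables
reproduces printed percentages deterministically rather than depending on
binary-float round-half-even behaviour.

## Profiles

A profile is a patient's exact positive set. Exact-set assignment (not
subset closure) is the only convention under which "number of distinct
profiles among N sensitized patients" is coherent and profile counts
conserve: Σ counts = N, and per-molecule sums over profiles equal the
summary-table counts — both are asserted exactly in the tests. Ranking is
by count descending; ties break by fewer members, then by canonical panel
order of the member tuple. Ties are not scientifically meaningful but a
deterministic order is required for reproducible output. Profile labels are
"+"-joined molecule names in canonical panel order.

## Regional priority decision

For a region-group with share series s₁…s₁₁ (molecules with zero count keep
share 0; the series is at most 11 long):

1. *Exclusions first*: no sensitized patients → `no_sensitized`; fewer than
   `min_group_n` (default 3) → `below_min_n`. The default of 3 is the
   smallest group for which a two-molecule comparison is not determined by
   a single patient.
2. *Maxima*: first and second maxima by share, ties by canonical panel
   order.
3. *Margin rule*: if s(m₁) − s(m₂) > margin (default 0.05), m₁ alone is the
   priority (`margin_single`). The 5% margin is read as **5 percentage
   points of share**, since the compared quantities are shares;
   `margin_relative=True` switches to a relative reading. A gap exactly
   equal to the margin goes to the t-step (the margin rule requires a
   strict excess).
4. *t-step*: for every molecule with positive share, a one-sample upper-tail
   Student's *t* test of the **full share series** against that molecule's
   own share asks whether the series holds another maximum above it. The
   runner-up is retained iff |p(m₂) − p(m₁)| / p(m₁) ≤ `p_similarity`
   (default 0.05, a **relative** closeness criterion — p-values are compared
   with each other, not with shares). Retention with exactly equal shares is
   reported as `margin_equal_pair`, otherwise `ttest_pair`; rejection gives
   `ttest_single`. If the runner-up's share is zero (possible only when the
   top share ≤ margin) no p-value exists for it and the decision is the
   single maximum.

The p-value for the absolute maximum is always the largest in the map
(upper-tail monotonicity in the popmean), so the similarity rule effectively
asks whether the runner-up's "cannot be ignored" evidence is as weak as the
leader's. `alpha` (default 0.002) annotates which per-molecule nulls count
as unconfirmed in the trace; it is a reporting annotation, not a gate,
because the pair decision rests on the similarity rule. An alternative
reading — gate the pair on the *smallest* p-value rather than similarity to
the maximum's — exists; since p(m₁) is the maximum, the similarity reading
is the one implemented, and the full p-value map is recorded in the trace so
either reading can be audited post hoc.

The t statistic is computed from the closed form
t = (x̄ − μ₀)/(s/√k) with the n−1 sample standard deviation and the
Student-t upper-tail probability with k−1 degrees of freedom; a constant
series (s = 0) has no defined t and returns p = 1 when x̄ ≤ μ₀, else p = 0,
flagged `degenerate`. Tests cross-check the implementation against both
`scipy.stats.ttest_1samp(alternative="greater")` and an independent
quadrature of the explicit t density (agreement ≤ 1e-8), and the whole
decision rule against a literal brute-force transcription on all 9,261
length-3 share series over the grid {0, 0.05, …, 1}³.

## Synthetic cohort generator

The generator exists so every pipeline stage can be exercised with known
ground truth. Its model:

* **Regions** are drawn i.i.d. from configured weights; **age group** is
  Bernoulli(child_fraction); **ages** are normals truncated to the stratum
  (children mean 7.29, sd 4.29 years on [0, 18); adults mean 36.41, sd 11.9
  on [18, 95)), matching the emulated population's reported stratum moments.
* **Sensitization indicators** come from a latent-threshold (Gaussian
  copula) model: one draw z ~ N(0, R) per patient, molecule j positive iff
  z_j < Φ⁻¹(p_j) with p_j the configured marginal prevalence for that
  patient's region × age group. Marginals are therefore exact Bernoulli(p_j)
  while R induces co-sensitization dependence. Independent Bernoullis would
  make the profile stage untestable against realistic structure, which is
  the point of the analysis. R must be symmetric, unit-diagonal and PSD
  (eigenvalue tolerance −1e-9); validation precedes any sampling.
* **Levels**: positives draw log-normal per-molecule (parameters derivable
  from a target mean/sd via `lognormal_params_from_moments`; the preset uses
  published-magnitude means of ~1.7–27 kU/L with similar-magnitude sd,
  i.e. right-skewed), clamped up to the threshold; negatives draw uniform on
  [0, 0.30) to exercise the binarization boundary rather than sitting at
  zero. Thresholding a generated cohort therefore recovers the indicator
  matrix exactly.
* **tIgE** is an independent log-normal nuisance column (median ≈ 100 kU/L,
  log-sd 1.1); no joint modelling with sIgE is attempted.
* **Determinism**: one `numpy.random.default_rng(seed)` consumed in a fixed
  draw order (regions → age group → ages → latent matrix → per-molecule
  levels → tIgE); a fixed seed reproduces the cohort bit-for-bit.

### The study-like preset

`preset_ukraine_like()` encodes the emulated study conditions: 16 regions
(the four largest testing centres weighted 19.62 / 14.48 / 7.7 / 7.55%, the
rest uniform), child fraction 0.5786, marginal prevalences equal to the
published within-sensitized shares × 0.27 (the overall sensitized fraction),
child/adult multipliers 1.20/0.73 chosen so the expected child:adult
sensitized ratio is ≈ 2.26 at that child fraction, and a correlation matrix
with strong within-group-pair blocks (Der f 1–Der p 1 and Der f 2–Der p 2
at 0.9), a deliberately weaker cross-group block (0.5) so exclusive group-2
co-sensitization stays the modal exact-set profile, Der p 23 riding with the
majors at 0.7, minor molecules (Der p 10/11/20) at 0.45 and 0.78 elsewhere.
The correlations were chosen to reproduce the **rank order** of the top
profiles (modal pair {Der f 2, Der p 2}, Der p 23 monosensitization
second-tier), not their exact percentages — no joint-distribution data exist
to fit. Two Western regions (Zakarpattia, Khmelnytskyi) override Der p 23 to
0.30 and the four majors to 0.10, building in a > 10-point share gap so the
regional classifier must find them.

What the preset does **not** reproduce: the real data's within-sensitized
shares are higher (e.g. Der f 2 ≈ 73% vs ≈ 52% here) because real
sensitization sets are more strongly nested than a single Gaussian copula
at these marginals can express while keeping the sensitized union near
27–36%; regional prevalence heterogeneity beyond the two biased regions;
age-dependent level distributions; assay noise near the cut-off. Passing
tests on preset data therefore validate the *pipeline's arithmetic and
decision logic* under realistic dependence, not epidemiological fidelity of
any particular percentage.

## Pipeline and numerical choices

* Problem sizes in the tests and acceptance checks — 9,261 grid cases,
  1,000 t-test series, 100 cohorts of 80 for conservation, n = 5,000 for
  marginal recovery, n = 10,000 for preset structure — were chosen as the
  smallest sizes at which each property is sharp (conservation is exact at
  any n; recovery uses the 3-binomial-SE bound; the preset's modal-pair gap
  is ~3 share points, far beyond sampling noise at n = 10,000).
* Floats in emitted tables are serialized at 4 decimals (configurable), the
  precision at which round-trips are exact; manifests are sorted-key JSON.
  These two choices are what make rerun byte-identity hold.
* Ingest rejects missing or negative sIgE cells and duplicate patient ids
  rather than imputing or deduplicating — silent repair would change every
  denominator. Decimal-comma input ("26,57") is rejected unless explicitly
  enabled, and only with the tab dialect.
* Region labels are opaque strings; a macro-zone lookup
  (West/Centre/East/South) exists for reporting only.

## Known limitations

* The t-step treats the 11 molecule shares as an i.i.d. sample for the
  purpose of the one-sample test; the shares are in fact dependent
  (computed on the same patients). The procedure is a published decision
  heuristic, implemented faithfully and traced fully, not a calibrated
  inference.
* With more than two tied maxima the priority list still caps at two
  (first two in canonical order), since the decision contract is 1–2
  molecules.
* tIgE summaries are computed but have no external reference to validate
  against; tIgE is carried as optional metadata only.
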