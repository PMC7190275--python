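# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic cohorts do and do not establish.

## Calibrated inflammatory score

Three per-axis categories are scored against a control-strain calibration.
For categories where disease raises the measurement (infiltration count,
muscle thickness) the score-0 band is the control mean ± 2·SD (sample SD,
n−1 denominator); the interval from the band's upper edge to the diseased
cohort's maximum is split into three equal-width bins scoring 1, 2, 3. For
the villus-length/crypt-depth ratio, where disease lowers the value, the
band is mean ± 0.5 (the ratio is a unitless quantity of magnitude ~3, so a
fixed half-unit band plays the role 2 SD plays for the counts) and the
graded range runs from the diseased minimum up to the band's lower edge.

Conventions the rule itself does not fix, resolved here:

- Bins are half-open, closed on the side away from the band — `(lo, hi]`
  ascending for upper categories, `[lo, hi)` descending for the ratio — so
  boundary values resolve deterministically.
- New values beyond the calibration's diseased extremum clamp to 3
  (worse-than-worst must not score lower).
- If no diseased value lies beyond the band (degenerate calibration), any
  out-of-band value in the disease direction scores 3; this preserves
  monotonicity and avoids zero-width bins.
- Out-of-band values in the *healthy* direction score 0; only the disease
  direction is graded.
- A control cohort with zero SD cannot define a band and raises.

Per-mouse scores are the arithmetic mean of axis scores per category, plus
0.5 × the section-wide crypt-abscess count; "scored to 0" is read as a total
of exactly 0 (the stricter reading; rounding-to-0 would only raise
coverage). Per-axis morphological criteria for abscesses are upstream of
this package — only the count × 0.5 aggregation is implemented.

## Trypsin-differential cryptdin quantification

The standard curve is linear through the origin, fitted by least squares on
intensity → ng (with the single 200 ng synthetic oxCrp1 standard this is
exact proportionality — the minimal model consistent with reporting ng).
Oxidized amount = trypsin-treated lane; total = untreated lane; reduced =
difference. Negative per-sample reduced estimates are *retained* and
flagged rather than clamped: clamping would bias group means upward exactly
where the interesting comparisons live (means near zero). Tryptic digestion
is assumed complete; no partial-digestion correction is applied. On the
acid-urea gel, the oxidized marker's mobility line belongs to the oxidized
zone (boundary bands call oxidized).

## Microbiome metrics

All metrics are computed directly from branch lengths and counts
(scikit-bio supplies only Newick parsing and the tree container; its own
metric implementations serve as independent cross-checks in the test
suite).

- Faith's PD includes the path to the root ("whole tree" convention).
- Unweighted UniFrac = (branch length leading exclusively to leaves present
  in one sample) / (branch length leading to leaves present in either); a
  branch is "present" for a sample if any descendant leaf is.
- α-diversity is computed on a single seeded rarefaction to the minimum
  retained library size (configurable depth, or off); β-diversity uses the
  same rarefied table. Samples below the depth are dropped with a warning.
- Taxonomy collapse sums counts at a rank and renormalizes per sample; OTUs
  lacking a name at the rank aggregate under `<nearest named ancestor>;Other`
  (so an unresolved Lachnospiraceae genus appears as
  `Lachnospiraceae;Other`).
- PCoA is classical scaling: eigendecomposition of the double-centred
  −½D²; axes with eigenvalues ≤ 10⁻⁹·max are dropped, negative eigenvalues
  are reported but not corrected (no Cailliez correction — UniFrac's
  non-Euclidean part is small on these data), and each axis's
  largest-magnitude coordinate is made positive for sign stability.
- PERMANOVA uses the direct distance-matrix form of the pseudo-F
  (SS_total from all pairs /n, SS_within from within-group pairs /n_g) with
  free label permutation, p = (1 + #{F* ≥ F}) / (1 + n_perm), seeded.

## Association statistics

Pearson r with t = r√((n−2)/(1−r²)) on n−2 df, two-sided. Mann–Whitney U
uses midranks; with combined n ≤ 12 and no ties the two-sided p is computed
by full enumeration of label arrangements (the study's group sizes of 3–8
sit exactly where the normal approximation is poorest); otherwise a
tie-corrected normal approximation with continuity correction. One-way
ANOVA reports the F test and Tukey HSD pairwise p-values from the
studentized-range distribution (scipy's numerical-quadrature
implementation) with the Tukey–Kramer standard error for unequal n.
Two-way ANOVA uses type-II sums of squares (identical to the classical
decomposition on balanced data; unbalanced layouts warn), with the
repeated-measures label of the source design retained as documentation
only — no within-subject covariance structure is modelled. Post hoc
pairwise t-tests use the full-model residual variance with p multiplied by
the number of comparisons and clamped at 1. All tests are two-sided.

## Synthetic cohort generator

The generator is the package's study stand-in: every downstream module is
exercised on cohorts whose *structure* matches the study design, with the
study's reference group summaries as default parameters.

**Latent severity.** Each disease-model mouse carries a continuous severity
s ≥ 0 drawn as N(µ_age, 0.15²) clipped at 0, with µ = 0, 0.5, 1 at 4, 10,
20 weeks; controls have s = 0 identically. The study only implies ordered
worsening by age; a continuous scalar was chosen because it gives clean,
configurable correlation targets.

**Histology.** One standard-normal mouse effect b carries 90% of each
category's variance (ICC 0.9) and enters every category *in its disease
direction* — a sick-looking mouse looks sick in all categories. This
alignment is what makes ≥ 90% of in-sample-calibrated control mice score
exactly 0 attainable: axis-level exceedances concentrate in a few mice
rather than spreading across many. The study gives no variance-components
information for histology axes; ICC 0.9 is a modelling choice exposed in
the configuration. Control means/SDs (infiltration 10 ± 2 cells, muscle
30 ± 4 µm, ratio 3.0 ± 0.22) are order-of-magnitude realistic values;
severity-1 effects default to 4 control SD in each category. Abscesses are
Poisson with rate 2·s (controls: 0). Abnormal (eosinophilic
granule-positive) cell counts are Poisson per axis with disease-strain mean
3.54 → 8.30 cells/axis across s = 0 → 1 and a small control mean (0.2).

**Gel densitometry.** Implied amounts follow the reference group means
(ox 6.50 → 11.76, r 0.23 → 9.82 ng/500 µg from s = 0 → 1, linear in s) with
two noise layers: mean-1 multiplicative lognormal amount noise, whose scale
is *derived* from a target severity–amount Pearson correlation
(`coupling_r` = 0.8, `coupling_ox` = 0.05, plus an assay-CV floor of 0.2),
and additive per-lane densitometry noise (SD 0.5 ng, truncated at zero
intensity). The additive layer is what produces occasional negative
per-sample reduced estimates at low severity — the reference 4-week reduced
dispersion (SEM 0.49 at mean 0.23) is impossible under purely
multiplicative noise and implies exactly such negatives. The near-zero
oxidized coupling encodes the study's reported *absence* of oxidized-Crp
associations with inflammation and diversity; because the oxidized means
still double with age, full decoupling forces a heavy-tailed oxidized
marginal (CV ≈ 5, larger than the reference SEMs imply). This trade — honest
null associations at the study's sample sizes versus a realistic oxidized
marginal — is deliberate and means simulated per-group oxidized means are
individually very noisy (they remain unbiased; the 50-seed consistency
check in the acceptance suite verifies this). Lane intensities are
constructed so that quantification round-trips the drawn amounts exactly;
with all noise terms zero the configured means are recovered to machine
precision.

**Microbiota.** Five families (the four focal ones plus a Muribaculaceae-
like remainder) have base proportions from the reference 4-week composition
and severity-1 targets from the 20-week composition; per-sample family
proportions interpolate on the log scale (renormalized) and are jittered by
a Dirichlet draw with concentration 2000. Within each family, OTU weights
follow a geometric series whose ratio falls with severity
(q: 0.8850 → 0.8427), so evenness and hence observed richness decline;
these two ratios were calibrated once, via the expected-richness formula
Σ(1−(1−p_j)^N) at N = 12,000, to the reference observed-OTU means
(194.9 → 158.7). Counts are one multinomial draw at a lognormal library
size (median 20,000, geometric SD 1.3 — typical MiSeq depth; unstated in
the source design). The phylogeny is a random binary coalescent-style
topology with exponential branch lengths (mean 0.036, set once so mean
Faith's PD at severity 0 lands near the reference value 15.61; tree-to-tree spread
is ±1), generated once per cohort — the study's real phylogeny is
irrelevant to testing the metrics. The Dirichlet concentration is tighter
than typical real microbiome cohorts; it is chosen so the family-level
association structure is reliably detectable at the design's n = 8 per
age, which is what the qualitative-pattern checks require. Consequently the
generator demonstrates *pipeline correctness and statistical structure*,
not realistic between-mouse compositional variance; power estimates on
these cohorts do not transfer to real data.

**Determinism.** All randomness flows from one root seed through named
SeedSequence substreams (severity, histology, gel, microbiota, tree);
identical configuration + seed reproduces byte-identical tables, and the
pipeline manifest records a configuration hash plus per-file SHA-256.

## Problem sizes

Default cohorts are 4 control + 8 disease-model mice per age × 3 ages
(matching the design's group sizes); the calibration-coverage experiment
uses 50 cohorts of 20 + 20 mice; the association-pattern experiment uses 20
cohorts; PERMANOVA calibration uses 500 null simulations × 199
permutations. The full test suite runs in well under a minute.

## Known limitations

- The generator's compositional and gel noise models are calibrated for
  structural fidelity at reference group means, not for marginal realism (see
  above); oxidized-Crp marginals are heavy-tailed by design.
- Unbalanced two-way layouts get type-II sums of squares with a warning;
  true repeated-measures covariance modelling is out of scope.
- PCoA offers no negative-eigenvalue correction; eigenvalues are reported
  so users can judge the non-Euclidean part.
- Exact Mann–Whitney enumeration is O(C(n, n_a)) and switches to the
  corrected normal approximation above combined n = 12.
- The paper-level quantities that derive from real animals (absolute
  inflammatory scores, diversity values, family percentages) are generator
  *defaults*, not reproducible results; only their structural relations are
  testable here.
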