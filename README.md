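# ileodef

Analysis pipeline for a Crohn's-disease mouse-model study design linking
Paneth-cell α-defensin misfolding to intestinal dysbiosis. In such studies a
disease-model strain (spontaneous ileitis worsening from 4 to 20 weeks) is
compared with a control strain along three measurement tracks, and this
package implements the full downstream computation for each track plus the
correlation layer that ties them together:

- **Histology** — a control-calibrated ordinal inflammatory score. Each
  well-orientated crypt-villus axis is graded 0–3 for (a) inflammatory
  infiltration, (b) villus distortion (villus length / crypt depth) and
  (c) muscle-layer thickening. The score-0 band is the control-strain
  mean ± 2 SD (mean ± 0.5 for the ratio); the interval from the band edge to
  the most extreme diseased value is split into three equal-width bins
  scoring 1, 2, 3. Per-mouse category scores are axis means; crypt
  abscesses add 0.5 each; the total is the sum of the four components.
- **Fecal cryptdin conformers** — trypsin-differential densitometry.
  Oxidized cryptdins (three disulfide bonds) resist trypsin; reduced
  (disulfide-null, misfolded) conformers are digested. With lane
  intensities converted to ng by a through-origin standard curve,
  ox = Trp⁺, total = Trp⁻, r = Trp⁻ − Trp⁺ (kept unclamped and flagged when
  negative). AU-PAGE mobility calls conformers relative to the oxCrp1
  marker.
- **16S microbiome summaries**, implemented from first principles on an OTU
  table + Newick phylogeny: observed OTUs, Faith's PD
  (Σ branch lengths of the subtree spanning observed taxa and the root),
  unweighted UniFrac
  (unique branch length / union branch length over presence sets),
  rarefaction, taxonomy collapse with the `Family;Other` convention,
  classical PCoA (double-centred −½D², eigendecomposition), and PERMANOVA
  (pseudo-F on the distance matrix, label-permutation p-value).
- **Association statistics** — Pearson correlation with the t-test on n−2
  df, Mann–Whitney U (exact by full enumeration for combined n ≤ 12),
  one-way ANOVA with Tukey–Kramer post hoc (studentized-range p-values),
  two-way ANOVA with Bonferroni post hoc.

Because the original animal data are not required, a first-class
**synthetic cohort generator** emulates the study's statistical structure: a
latent per-mouse severity rises with age in the disease strain only and
drives (i) histology through a shared per-mouse random effect (intra-mouse
correlation ≈ 0.9 across axes), (ii) gel densitometry whose implied reduced
amount correlates with severity at a configurable level (default r = 0.8),
and (iii) a Dirichlet-multinomial microbiota with family-level shifts
(Lachnospiraceae ↓, Ruminococcaceae ↓, Bacteroidaceae ↑, Rikenellaceae ↑)
and severity-dependent evenness loss, so richness and phylogenetic
diversity fall with severity. Defaults are the study design's group
summaries; see `docs/methods.md`.

## Worked example

The numbered drivers under `analysis/` run the study end to end on a
simulated cohort (12 control + 24 disease-model mice, seed 42) and write
their tables under `results/`:

```
python analysis/01_simulate_cohort.py
python analysis/02_score_histology.py
python analysis/03_quantify_cryptdins.py
python analysis/04_microbiome_diversity.py
python analysis/05_associations.py
```

`02` calibrates the score on the control strain and reports, e.g.

```
infiltration: score-0 band [7.58, 13.55], case extremum 20.00
mean total score by strain and age:
case     4  0.34    10  3.62    20  5.99
control  4  0.02    10  0.00    20  0.08
```

— disease-model scores climb with age while controls stay at ~0, the
behaviour the calibration is designed to produce. `04` shows the dysbiosis
track (disease strain only): observed OTUs fall 193 → 160 and Faith's PD
14.5 → 13.0 from 4 to 20 weeks, Lachnospiraceae drops 33.8% → 25.7% while
Bacteroidaceae rises 29.8% → 35.1%, and PERMANOVA on unweighted UniFrac
separates the strains at 20 wk (pseudo-F = 6.62, p = 0.002) but not at 4 wk
(p = 0.856). `05` prints the correlation panel on disease-model mice
(n = 24): reduced cryptdin correlates positively with the inflammatory
score (r = +0.75, p < 1e-4) and Bacteroidaceae, negatively with both
α-diversity indices and with Lachnospiraceae/Ruminococcaceae, while
oxidized cryptdin shows no significant diversity correlation — and reports
that each of these clauses holds in ≥ 18 of 20 independently seeded
cohorts.

The same functionality is exposed as a CLI for file-based inputs:
`ileodef simulate|score|crp-quant|diversity|associate|run` (see
`ileodef --help`).

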