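# Methods

## Statistical model and procedure

The unit of quantification is the ion: one peptide sequence with one
modification state and charge, with one label-free intensity per sample.
The pipeline treats the two experimental groups as independent samples of
lognormally distributed intensities and asks, peptide by peptide, whether
proteolytic susceptibility differs between them.

Per-ion tests run on log2-transformed intensities (variance stabilization
for multiplicative noise), while the reported effect is the log2 ratio of
raw-intensity means — the convention of the upstream LFQ tooling this
package consumes. Welch's unequal-variance t-statistic with the
Welch–Satterthwaite degrees of freedom is appropriate because the two
cohorts differ in size and biological variability; no equal-variance
assumption is made. Ions with fewer than two available values on either
side are excluded from testing rather than erroring: partial coverage is
the norm in LiP data.

Ions merge to peptides keyed by (accession, bare peptide sequence);
charge states and modifications are the ion dimension. The merged ratio is
the median of ion ratios (robust to a single aberrant charge state). The
merged p-value uses Fisher's method, which assumes independent tests —
charge states of one peptide are positively correlated, so the combination
is anticonservative at the margin; the direction-agreement gate (all ion
log2 ratios must share a strict sign, a zero ratio breaks agreement,
otherwise p = 1) is the counterweight, discarding ions that disagree even
nominally. Input p-values of exactly 0 are clamped to 1e-300 before the
log.

The per-protein Benjamini–Hochberg correction reflects the hypothesis
structure: the null is "this protein has no structural difference", and
each of its peptides is one opportunity to reject it. Correcting within
the protein (rather than across the whole table) prevents high-coverage
proteins from being called purely by number of attempts. Proteins are
called at ≥2 significant peptides; with a single peptide a call would rest
on one test, and proteins with fewer than two valid peptides are reported
as insufficient rather than negative.

Normalization against the trypsin-only control subtracts the protein-level
control log2 ratio when the control shows a >2-fold change at Welch
p < 0.01. The protein-level control ratio (per-sample sum of the protein's
ions, tested on log2 sums) is the default because the control experiment's
purpose is to measure protein *abundance*; a `matched_peptide` mode
implements the literal per-peptide reading for users who prefer it.
Normalization is additive in log space and idempotent (a `normalized` flag
guards re-application).

### Imputation policies

- `none` — the strict analysis. Most conservative; with the conjunctive
  missingness filter it discards feature-level evidence that rests on
  absent data.
- `general` — one group >66% missing (strict inequality on the exact
  fraction; at 10 vs 7 this means ≥7/10 or ≥5/7 missing) *and* the other
  group >55% present (≥6/10 or ≥4/7). Only then are the missing cells of
  the high-missing group drawn from N(10 000, 1 000²) on the raw intensity
  scale, truncated below at 1 so log2 stays defined. The rationale: a
  one-sided missingness pattern in LiP data is itself evidence of a
  structural change (the peptide exists in one conformation only), and the
  low constant places the imputed group near the detection limit. If both
  groups are high-missing, nothing is imputed — the rule requires the
  complementary presence.
- `all_or_nothing` — the refoldability preset: impute only when one group
  is entirely missing and the other entirely present.

Imputation precedes filtering, mirroring the upstream order (the imputed
table is the filter's input). The missingness filter drops an ion only
when it exceeds the per-group threshold in *every* group — a deliberately
conjunctive reading: an ion well-covered in one group is retained because
the general policy may rescue the other side.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `fc_threshold_log2` | 1.0 | peptide effect-size gate (2-fold) |
| `alpha_adjusted` | 0.05 | per-protein BH-adjusted significance level |
| `normalization_fc_log2` / `normalization_alpha` | 1.0 / 0.01 | control-abundance trigger |
| `impute_mean` / `impute_sd` | 10 000 / 1 000 | imputation Gaussian, raw intensity units |
| `max_missing_per_group` | CA1 {AU 5, AI 3}; DG/CA3 {AU 4, AI 3} | conjunctive filter thresholds |
| `min_significant_peptides_for_call` | 2 | protein calling rule |
| `min_peptides_for_assessment` | 2 | below this, "insufficient" |
| `min_obs_per_group` | 2 | per-ion testability |
| permutations | 3 | null relabellings for the FDR estimate |

The permutation FDR estimator is mean(null calls)/observed calls; the
max-based variant is also reported since at three permutations the mean is
noisy. Permutations draw label assignments uniformly while preserving
group sizes; at small n duplicate permutations can occur and are allowed.

## Peptide localization conventions

Protein N- and C-termini count as trypsin-conforming boundaries (standard
proteomics convention). The structural site is the PK cut residue for
half-tryptic peptides and floor((start+end)/2) for fully tryptic ones —
deterministic and within half a residue of any midpoint convention.
Peptides are matched literally (no I/L equivalence) at their leftmost
occurrence in the accession given by the ion table; matches elsewhere in
that protein or in other proteins set a `multi_match` flag, and
multi-mapping peptides do not count toward protein calls by default
(`require_unique_mapping`). Site-level analyses deduplicate identical
(accession, residue) sites across peptides by default; raw record counts
are always reported alongside so the alternative denominator can be
audited, and the same applies to the proximity contingency, whose
fractions are computed over included (not near-both/near-neither) sites
per row.

## The synthetic study generator

The generator emulates what the analysis assumes about real data: random
proteomes with ~11% combined K/R (so tryptic peptides of realistic length
exist), in-silico tryptic digestion, a configurable fraction of
half-tryptic peptides from uniform interior PK cuts (defaults 47% in LiP
tables, 8% in trypsin-only controls), per-ion lognormal baselines,
within-group CV of 0.20, a 10-vs-7 two-group design with water-maze
learning indexes consistent with the cohort labels (cutoff 240, ties to
the impaired side), planted multiplicative effects of |log2| = 2 on 2–4
peptides of 15% of proteins (LiP table only), protein-level abundance
effects in the control table only, and missingness as the union of a hard
detection threshold (MNAR) at the imputation constant's scale and
independent 3% random dropout (MCAR). Effects multiply group *means*
rather than individual replicates so the Welch assumptions hold by
construction. Ions per peptide are geometric with mean 1.5 (unreported
upstream; config-exposed).

What it does **not** emulate: chromatography and spectral noise,
charge-state intensity envelopes, correlated missingness across samples,
match-between-runs artefacts, shared peptides between homologous proteins,
and covariate–call associations (annotations are drawn independently of
planted effects, so enrichment analyses on synthetic data exercise the
null path unless an association is planted explicitly). Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the stated noise model, not that any particular biological dataset
will behave identically.

## Numerical choices and degenerate inputs

- Both group variances zero: p = 1 if the means agree, 0 otherwise
  (clamped at the Fisher step).
- Single-ion peptides pass through unmerged (Fisher with k = 1 is the
  identity anyway).
- Fisher's exact test reports the sample odds ratio (a·d)/(b·c), infinite
  when b·c = 0 with a·d > 0, undefined (NaN) when both products are 0; a
  proximity 2×2 with no included sites returns p = 1 rather than erroring.
- Chi-square enrichment drops empty bins; tables left with one row or an
  empty margin report p = 1. Numeric covariate bins are ordered
  categoricals end to end, so output rows follow the numeric bin order.
- All intensity cells of 0, "", or "NA" are missing on input (LFQ writes 0
  for unobserved); outputs serialize p-values in scientific notation and
  other numbers to six significant digits with a fixed column order and
  deterministic row ordering.
- All randomness (imputation draws, permutations, simulation) flows from
  explicit integer seeds; identical seeds give bit-identical outputs.

## Problem sizes used in the checks

The shipped acceptance checks run the default 200-protein study
(≈1 700 ions, 10 vs 7) for recovery, 20 null studies of 80 proteins each
for calibration, 3 label permutations for the FDR estimate, a 10 000-draw
Monte-Carlo for the Welch test's size, and an exhaustive sweep of all 2×2
tables with N ≤ 30 for the exact test. These sizes were chosen to make
each estimate's Monte-Carlo error small relative to the property being
checked.

## Known limitations

- Fisher's method over correlated charge states is anticonservative; a
  peptide-level mixed model would be the principled alternative and is out
  of scope (as are moderated/limma-style variance estimates).
- The permutation FDR at 3 permutations has high variance; the estimator
  divides by the observed call count and is undefined when nothing is
  called.
- On data with strong planted signal, permuted labels can retain partial
  group alignment, so the general-analysis FDR estimate is pessimistic
  relative to the strict analysis — the same pattern the imputation-
  permissive analysis shows on real data.
- Protein inference is taken from the ion table as given; razor-peptide
  logic and protein grouping are upstream concerns.
- Disorder, domain assignments, amyloidogenicity and lifetimes are
  consumed as annotation tables, never computed.
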