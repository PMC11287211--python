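# Methods

This note documents the models implemented in `corrsoil`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Genome role classification

A genome's corrinoid ecological role is a total function of two booleans:
presence of at least one corrin-ring biosynthesis marker gene, and presence
of at least one corrinoid-dependent enzyme. The default markers are the
three ring-contraction/methylation steps with anaerobic/aerobic orthologue
pairs — cbiC/cobH (K06042), cbiF/cobM (K05936), cbiL/cobI (K03394) — whose
presence is strongly correlated with a complete de novo pathway in
reference genomes. Corrinoid-dependent functions are matched by KEGG
orthologue, with one deliberate exception: the class II (corrinoid-
dependent) ribonucleotide reductase is matched by Pfam PF08471, because KO
K00525 mixes class I and class II RNRs; the configuration validator rejects
K00525 as a dependent marker outright.

The full corrinoid-dependent vocabulary varies between annotation
pipelines, so the marker sets ship as an editable YAML file
(`src/corrsoil/markers_default.yaml`) seeded with the four paired functions
(methionine synthase MetH/MetE, methylmalonyl-CoA mutase vs the
methylcitrate pathway, epoxyqueuosine reductase QueG/QueH, RNR class
II/class I). Identifiers are opaque strings to the rule engine; users are
expected to substitute their own lists. Producer/non-user calls carry a
warning flag because that category cannot be verified from annotation
alone.

The redundancy report emits percentages over two denominators: all genomes
(`pct_all`), and genomes in which the function was detected at all
(`pct_detected`). RNR statements conventionally use the second; epoxy-
queuosine reductase and methionine synthase statements the first.

## Bioassay standard curve

The assay's response (OD₆₀₀ of a corrinoid-requiring indicator strain) is
monotone and saturating in corrinoid concentration but has no single agreed
parametric form, so the calibration model is a monotone piecewise-linear
interpolant of mean OD against log₁₀ concentration — it reproduces every
calibration point exactly and is auditable. Censoring is explicit:

* limit of detection (OD): blank mean + 3·blank sd;
* saturation (OD): 95 % of the plateau OD (the top calibration mean); the
  assay plateaus near 1 nM cobalamin, carried as `saturation_conc`.

The reported quantitation range is obtained by pushing these two OD bounds
back through the interpolant and clipping to the calibration span; readings
outside them return `below_LOD` / `above_saturation` flags rather than
numbers, and exactly one of {value, flag} is set per sample. Replicates are
averaged before inversion by default (per-replicate inversion by flag).
Because distinct corrinoids elicit different sensitivities, all outputs are
cobalamin equivalents; no corrinoid-specific correction is attempted. The
LOD and saturation thresholds are defaults of this implementation, not
values inferred from any particular instrument.

## Partition model

The equilibrium model assumes a single dimensionless partition coefficient
K_d = [B12]_aq / [B12]_soil (molar over molar) that is identical at every
extraction round, with the aqueous phase at round n equilibrated against
the post-round soil pool. Combining this definition with the mass balance
soil_{n+1} = soil_n − aq_{n+1}·vol_aq/vol_soil yields the per-pair
estimator

    K_d = vol_soil (aq_n − aq_{n+1}) / (vol_aq · aq_{n+1}),

whose denominator uses the *later* round. A variant with aq_n in the
denominator circulates in print; it is inconsistent with the forward model
(it under-estimates K_d by the factor aq_{n+1}/aq_n) and is available as
`kd_form="printed"` for comparison only — the discrepancy is surfaced, not
silently resolved. Only the self-consistent form is exactly inverted by the
back-extrapolation factor (1 + K_d·vol_aq/vol_soil)^k.

Defaults: vol_aq = 0.01 L, vol_soil = 0.001 L (1 g of soil at a density of
1 g/ml), giving a per-round depletion leverage vol_aq/vol_soil = 10.
Concentrations enter in nM cobalamin equivalents; the single audited unit
conversion (`aqueous_nM_to_pmol_per_g`) maps one round's aqueous signal to
pmol per gram of soil. K_d estimates below zero or from non-decreasing
pairs raise `NonIdentifiableError` — they are never clamped. The
round window is a required explicit argument: on real extractions early
rounds carry desorption/lysis transients and a late window (e.g. rounds
6–9) is appropriate; on synthetic series, which have no transients, the
full window maximises the number of pairs and is what the recovery
experiments use. `kd_sd` is the standard deviation over pair estimates
(ddof = 1), labelled as such; it is not an error-propagated quantity.

Below-LOD rounds are censored, never zero-filled; `total_pool` propagates
them as [0, LOD] contributions, so the pool becomes an interval whose
endpoints coincide when nothing is censored. `molecules_per_cell` converts
pmol/g through Avogadro's number at a conventional 10⁹ cells per gram of
soil and reports the nearest power of ten. `partition_upper_bound` turns a
spike non-detection into an upper bound K_d ≤ detection limit / (spiked
amount per soil volume), echoing its full-adsorption assumption in the
result record; because the spike geometry of any particular experiment is
not standardised, all quantities are explicit inputs.

## Community statistics

Counts are normalised to per-sample relative abundances before distance
computation (no rarefaction). Aggregation sums zOTU counts sharing a label
at the requested rank; per-sample totals are invariant across ranks, and
missing ranks are filled `unassigned_<rank>` so marginals still sum.

Bray–Curtis and Jaccard (on presence/absence) dissimilarities come from
scipy; PCoA eigendecomposes the Gower-centred squared-distance matrix.
Negative eigenvalues — expected for semi-metric dissimilarities — are
reported as-is and excluded from variance proportions; no Lingoes/Cailliez
correction is applied by default. ANOSIM (R, rank-based) and PERMANOVA
(pseudo-F from within/between squared distances) are computed in-package
with an explicit permutation loop so that every test records its seed and
permutation count; p = (1 + #{perm ≥ obs}) / (1 + n_perm) with 999
permutations by default. The statistics themselves are permutation-free
and deterministic; both are cross-checked against scikit-bio in the test
suite.

The Kruskal–Wallis screen tests, per taxon at a rank and per timepoint,
whether relative abundance differs across corrinoid treatments over
replicates. Significance is called at raw P ≤ .05 — no multiple-testing
correction, matching common practice for these screens — and a
Benjamini–Hochberg column is always emitted alongside so the choice is
visible. Taxa observed in fewer than two treatment groups at a timepoint
are skipped and logged; fully tied taxa get H = 0, p = 1. Uninoculated
controls are excluded from treatment screens (metadata-driven) but retained
for inoculated-vs-control ordinations.

Two distinct "fraction responsive" summaries are kept as separately named
operations because they answer different questions: the count-based
fraction (union of taxa significant at any timepoint over all observed
taxa — the enrichment-style summary) and the abundance-weighted fraction
(summed mean relative abundance of significant taxa at one timepoint — the
microcosm-style summary).

A known small-sample property, verified by simulation in this package's
calibration tests: with 7 treatment groups the chi-square approximation to
the Kruskal–Wallis null is conservative at low replication — the intrinsic
level at 5 replicates per group is about 0.033 and about 0.040 at 6, even
for continuous (untied) data, and sparse count data with many tied zeros
pushes it lower. Type-I calibration is therefore checked on the
6-replicate design at sequencing depths where ties are rare (level
≈ 0.04–0.05); screens on 5-replicate designs inherit a conservative bias,
which makes the responsive-fraction summaries conservative too.

## Synthetic generators

Every generator returns its dataset plus a `SimulationTruth` (scenario,
seed, planted parameters); regeneration from the same scenario and seed is
deterministic, and downstream recovery tests read the truth rather than
re-deriving it.

* **Annotations**: roles are sampled (or planted as exact counts) and the
  marker sets are then constructed to force each role, so the classifier
  must decode them; corrinoid-independent alternatives are sprinkled freely
  since they never change the rule outcome. A dedicated stand-in builds a
  503-genome table planting the role mix (398/102/2/1) and redundancy
  structure observed in a grassland-soil MAG survey, for study-scale
  exercises when no real annotation table is at hand.
* **Extractions**: the forward model is the exact inverse of the estimator
  (geometric soil-pool decay, aqueous = K_d × soil), with multiplicative
  lognormal measurement noise (default sd 0.05, i.e. ~5 % — typical
  bioassay repeatability) on observed aqueous values; the truth records the
  noiseless series and residual pool, so mass conservation is checkable
  exactly.
* **Communities**: 7 corrinoid conditions (water control + six corrinoids).
  The enrichment design uses two media (M9, R2), 6 replicates and one
  uninoculated control per condition at weeks 1, 2, 12, 14; the microcosm
  design uses soil, 5 replicates at days 0, 3, 10, 30, 50. Expected
  relative abundances are log-normal across taxa (sd 1.5 by default, a
  typical rank-abundance spread; 1.0 in the deep calibration scenarios);
  per-replicate lognormal wobble sd 0.2 reproduces replicate CVs of ~20 %
  seen in such designs; responder taxa are multiplied by per-corrinoid fold
  changes (FC < 1 models suppression) before renormalisation; counts are
  multinomial at the requested depth, with optional Dirichlet-multinomial
  overdispersion (off by default — simplest noise model first, switchable).
  `baseline_shares` can pin designated taxa at exact baseline community
  shares for quantitative recovery scenarios.
* **Standard curves**: a four-parameter-logistic response with plateau at
  the configured saturation concentration (default 1 nM), sampled on a
  log-spaced grid with lognormal OD noise, plus blank wells.

What the generators do **not** emulate: phylogenetic correlation of
abundances, temporal autocorrelation across timepoints, compositional
spike-ins, chimeras/contamination beyond a crude sparse uninoculated
profile, PCR/primer bias, or mechanistic corrinoid exchange between guild
members. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated models, not robustness to every artefact of
real amplicon data.

## Problem sizes

The recovery experiments use 100 seeded extraction series (12 rounds each),
a 503-genome role table, 2 000-taxon null tables at depth 2×10⁵ for type-I
calibration, a 1 195-taxon enrichment-shaped surrogate at depth 10⁴ over 86
samples, and a 150-taxon microcosm surrogate at depth 5×10⁴ — sizes chosen
so each check is statistically informative while the whole suite runs in
well under a minute per module.

## Known limitations

* The role classifier is only as good as the annotation vocabulary supplied;
  transporter-based corrinoid-uptake prediction is deliberately out of
  scope.
* The bioassay curve model is interpolatory: it does not extrapolate beyond
  the calibration span, and different corrinoids' sensitivities are folded
  into "cobalamin equivalents".
* The partition model is equilibrium-only (no sorption kinetics) and treats
  all corrinoids as one pool; intracellular vs extracellular corrinoid is
  not distinguishable from extraction data.
* ANOSIM/PERMANOVA p-values at very small group sizes are floor-limited by
  the number of distinct relabellings (e.g. 3 + 3 samples cannot reach
  p < 0.1).
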