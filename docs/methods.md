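# Methods

## Measurement model

A field of view is a 3-channel confocal z-stack: DAPI marks nuclei, FITC
marks Homer-1a transcription foci and Cy3 marks Arc foci. Intranuclear IEG
foci report neuronal firing during a time window set by each gene's
expression kinetics; with two 5-minute test entries separated by 20 minutes
and sacrifice immediately after the second, Homer-1a foci index the first
entry and Arc foci the second (the IEG→entry map is a config value,
`descriptors.DEFAULT_IEG_MAP`, because the assignment follows from the
timing protocol, not from the image).

Analysis is strictly per-layer 2-D: each z-layer is segmented and classified
independently, and per-class fractions are aggregated by the median over
retained layers. A nucleus spanning several layers is intentionally counted
on each (the median makes the estimate robust to this and to layer-to-layer
segmentation noise). The three bottom-most and three top-most layers are
always discarded so that only whole cells contribute; a stack must therefore
have at least 7 layers. The median of an even number of layers is the mean
of the two central values. Hemispheres are pooled by concatenating nucleus
lists *before* computing fractions, weighting each hemisphere by its cell
count rather than averaging two fractions.

### Nucleus segmentation

Gaussian smoothing (σ = 2 px default) → threshold (Otsu by default, absolute
available — acquisition settings are assumed fixed per slide) → marker-
controlled watershed on the Euclidean distance transform (markers =
distance-transform peaks at a minimum separation) → area and solidity
filters → one ellipse per region from second-order image moments.
Coordinates are pixel-centred, 0-based, x = column, y = row (down); ellipse
angles are measured from +x, counter-clockwise in image coordinates.

### Focus ("dot") detection

A scale-normalised negated Laplacian-of-Gaussian response (σ = 1.2 px
default) with non-maximum suppression and a separable quadratic sub-pixel
refinement. The detector threshold is either absolute or a robust automatic
value (median + 8 · 1.4826 · MAD of the response). This is the same operator
class as wavelet-based spot finders used interactively in microscopy suites,
but fully parameterised and testable.

### Classification and the co-localisation coefficient

A focus belongs to a nucleus iff its center satisfies the ellipse
inequality; when ellipses overlap, the focus goes to the ellipse it is
deepest inside (smallest normalised ellipse-equation value; ties to the
lower id). A nucleus is positive for an IEG when its dot count reaches the
positivity threshold (default 1 — the threshold at which "active" and "has a
focus" coincide in the synthetic ground truth; configurable). The four-class
fractions give the descriptor set (`any`, `first`, `second`, `first_only`,
`second_only`, `both`) and

    coloc = f_both / (f_first · f_second),

which is 1 under independent activation across entries, < 1 under exclusive
activation and > 1 under re-activation of the same sub-population. `coloc`
is undefined (missing, never 0) when either marginal is zero: a 0 would be a
false signal of exclusivity, and the imputation step downstream handles
missing values explicitly. The coefficient is computed from the final
(median) fractions, not per layer and then medianed; with per-layer
fractions the ratio of medians and median of ratios differ only at the
noise level of a layer, and the final-fraction form keeps the published
definition literal.

## Synthetic data

The generator produces every input the pipeline consumes, with ground truth:

- **Nuclei**: ellipses (major semi-axis 5.5–8 px, aspect 0.6–0.95) placed by
  rejection sampling inside an ROI polygon at a per-layer density; two
  nuclei on the same layer must satisfy center distance >
  (a_i + a_j) · overlap_factor. Non-overlap is enforced within a layer only:
  the analysis is per-layer 2-D, so cross-layer overlap is immaterial and
  global enforcement would make realistic densities unpackable.
- **Activity**: a bivariate Bernoulli with marginals (p_first, p_second) and
  correlation ρ; P(both) = p₁p₂ + ρ√(p₁q₁p₂q₂), validated against the
  Fréchet bounds. ρ = 0 is the independence null the co-localisation
  coefficient is calibrated against. Active nuclei carry
  1 + Poisson(dot_count_mean − 1) foci per IEG (so active ⇔ ≥ 1 focus in
  ground truth); foci are placed uniformly inside the ellipse shrunk by a
  margin (0.8) and kept ≥ 4 px apart so each focus is an isolated blob.
- **Imaging**: filled ellipses on DAPI blurred by a Gaussian PSF; foci as
  Gaussian peaks of the PSF width; Poisson-Gaussian noise
  (pixel ~ Poisson(signal·scale)/scale + N(0, σ)) over a constant
  background. Defaults (background 10, nucleus amplitude 60, spot amplitude
  150, σ_noise 2, PSF 1.2 px) give bright foci over a clearly visible
  nucleus — free parameters of the artifact, documented here, not claims
  about any study's imagery, which also does not report densities, dot
  counts or SNR.
- **Trajectories**: a Metropolis random walk (Gaussian step, reflected at
  the walls) whose acceptance ratio is the ratio of per-region
  attractiveness weights, so long-run occupancy density is proportional to
  the weights; equal weights give a plain reflected walk. A fully biased
  walk still pays a start-up transit from the release point at the cage
  center, so its correctness score approaches 1 asymptotically rather than
  identically.
- **Descriptor tables**: i.i.d. standard-normal columns; planted columns are
  shifted by an effect size (in SD units) in the second group; missingness
  is completely at random.

What the generator does **not** emulate: optical sectioning and z-blur,
chromatic aberration, uneven illumination, tissue autofluorescence,
segmentation-hostile nuclear morphologies, and any behavioural structure
beyond region preference (no rearing/grooming, no temporal strategies).
Passing tests therefore demonstrate the correctness of the computational
chain under a controlled forward model — not robustness to every real-world
imaging pathology.

## Behaviour

The 1 m × 1 m cage has four square corner regions (side default ⅓ of the
cage side — the physical partition geometry is configurable) and a center
region; boundary points belong to the corner. Each inter-sample interval of
a trajectory is attributed to the region containing its earlier sample (no
interpolation; the attribution bias vanishes at camera frame rates). The
correctness score is corner-dwell(conditioned) / corner-dwell(total),
undefined if the animal never enters a corner; added center time cannot
change it. Trajectories are consumed as given — no trimming of
door-opening frames at entry start. USV counts are associated with
correctness via the two-sided Spearman test on raw counts (rank-based, so
log-scaling for display does not affect it).

## Statistics

- **Mann-Whitney-Wilcoxon**: exact null for ≤ 10 per group without ties,
  otherwise normal approximation with tie correction and (by default)
  continuity correction. Two identical samples return p = 1 with a
  degeneracy flag.
- **Stratified MWW**: van Elteren's combination — per-stratum centred
  mid-rank sums weighted by the locally-best 1/(N_s + 1), tie-corrected
  variances, standard-normal reference. Strata missing either group (or
  fully tied) are skipped and reported. No continuity correction is applied
  to the combined statistic (there is no standard one for a weighted sum),
  so a single-stratum call equals the plain test with continuity off;
  against a within-stratum label-permutation oracle at 3 strata and n ≤ 6
  per group the approximation agrees to |Δp| ≈ 0.007 on average. The
  combination rule itself is a design choice — "stratified MWW" names a
  family, and van Elteren with locally-best weights is its canonical member.
- **Multiplicity**: Holm step-down for hypothesis families, Benjamini-
  Hochberg step-up for the correlation-network edge families, applied
  within each descriptor class separately (7 families) to match the
  per-class presentation of the networks.
- **Spearman**: mid-ranks; exact permutation null for n ≤ 9, t-approximation
  above. Correlation networks test all unordered structure pairs on
  pairwise-complete observations (≥ 4 pairs; pairwise rather than listwise
  deletion maximises the small n), BH-adjust within the class, and keep
  edges with adjusted p < α carrying ρ, sign and adjusted p.

## Feature selection

`rf_importance` is a scikit-learn Random Forest (classification for a
categorical response, regression for a real one) reporting
mean-decrease-in-impurity importances; 50,000 trees is the documented
full-scale setting, and configs/tests scale it down (importance *rankings*
at n ≈ 16 animals stabilise far below that). `boruta_run` implements the
shadow-feature scheme: each iteration appends a column-wise permuted copy of
every feature, fits the forest, and scores a hit for every real feature
beating the maximum shadow importance; two-sided binomial tests on hit
counts (null probability ½), Bonferroni-adjusted over the number of
features, confirm (hits above half) or reject (below) at α = 0.01; whatever
is undecided at the iteration cap (default 100) stays tentative. Two
implementation details matter at n = 16:

- the shadow pool always contains a permuted copy of **every** original
  feature, even after rejections, keeping the hit bar at the maximum of a
  full set of null draws — with a shrinking pool, features that are
  correlated with the response by chance hover at the bar and survive;
  rejected real features do leave the forest fit;
- shadow permutations are seeded from a hash of (feature name, seed,
  iteration) and features are processed in sorted-name order, so results
  are invariant to input column order.

`stable_select` wraps median imputation (k-NN available) plus `boruta_run`
in `n_repeats` independently seeded repeats; a feature counts as selected
in a repeat when confirmed *or* tentative (with ~16 animals, discarding
tentative features would discard most of the signal), and is finally
reported when its selection fraction reaches the stability threshold
(default: half of 30 repeats). Known limitation, by construction: a null
feature whose sample correlation with the response is the most extreme of
~30 candidates is genuinely informative *in-sample* and tends to stay
tentative in every repeat — at n = 16 the procedure bounds, but does not
eliminate, such false selections (the acceptance test allows up to 3 of 28
noise features). Selected features are reported as per-animal rank tables
(rank 1 = lowest value), the form used for heatmap display.

## Pipeline

`catfish run --config cfg.yaml` executes simulate → quantify → describe →
behave → stats → select; each stage reads/writes the owning module's file
formats (channel-major multi-page TIFF + JSON ground-truth sidecar, polygon
JSON ROIs, `t,x,y` trajectory CSVs, tidy statistics CSVs, GraphML/JSON
networks) so stages also run standalone. A manifest records the config
hash, seed, package version and outputs; deterministic stages are
bit-reproducible from the config. All randomness flows from explicit seeds.

## Problem sizes used in tests

Acceptance-style checks run at: 200 structures × 2000 nuclei for the
co-localisation null (±0.02 on the mean); 10 rendered 8-layer stacks of
~500 nuclei at default noise for ground-truth recovery (±0.03 on mean
recovered fractions); 20 small instances × 10,000 permutations for the
stratified-test oracle; 16 animals × 30 descriptors × 10 repeats × 10 base
seeds at 500 trees and 20 Boruta iterations for selector power/specificity;
200 replicates of 16 × 14 null tables for network FDR; 3000 s walks for
behaviour calibration. These sizes were chosen as the smallest at which the
binomial/Monte-Carlo error of the check is comfortably below its tolerance.
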