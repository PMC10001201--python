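# Methods

This note documents the models implemented in `pdxsynergy`, the numerical
and design choices behind them, what the synthetic-data generators emulate,
and the limits of what the tests demonstrate.

## Viability normalization

Raw luminescence (CellTiter-Glo-style) signals are normalized per model:
if cell-free blank wells are present their mean is subtracted first
(post-subtraction negatives are clipped to zero with a warning — they are
instrument noise, and preserving them would propagate negative
viabilities); each well is then expressed as percent of the vehicle-well
mean. Replicates of a condition are averaged by default. Viability is kept
on the 0–100 percent scale at every file boundary and converted to a 0–1
fraction exactly once (`assay_io.pct_to_fraction`) before any synergy
arithmetic; values above 100% (growth stimulation) are legitimate and kept.

## Mutation panel queries

The packaged 34-model table transcribes a clinical targeted-sequencing
panel (mutations, amplifications, fusions per model). Every listed call is
treated as pathogenic — the table contains only reportable calls — so
"model carries gene g" means g appears among its mutation or amplification
calls; fusion partners are deliberately excluded (a fusion partner is not
an activating aberration of that gene in this context). Asterisks marking
repeat-sequencing confirmation are stripped during parsing; semicolons
inside parentheses (multi-part HGVS annotations) do not split entries.

## Median-effect model and CI/DRI

The median-effect equation `fa/fu = (D/Dm)^m` is fitted by unweighted
least squares on `log10(fa/fu)` vs `log10(D)` — the convention of the
standard desktop implementation of this analysis. Choices:

- **fa clipping.** Observed fa values are clipped into [0.005, 0.995]
  before linearization. Points outside (0,1) arise routinely (viability
  above vehicle); clipping with a warning rather than dropping keeps the
  design balanced. The clip bounds cap the leverage of near-saturated
  wells at ±2.3 logit10 units.
- **Flagged fits.** A non-positive fitted slope (response decreasing with
  dose) yields a flagged fit with `Dm = NaN` rather than an exception:
  screens legitimately contain inactive compounds, and downstream CI/DRI
  calls refuse flagged fits explicitly.
- **Combination fitting.** A fixed-ratio mixture is fitted on *total*
  dose; the ratio is by concentration. The default CI is the mutually
  exclusive two-term form; the non-exclusive third term is available via
  `exclusive=False`.
- **Grid.** The default CI/DRI profile grid is 99 points at fa =
  0.01…0.99, with the high-kill range of interest marked at fa ≥ 0.75.

An important model fact that shapes the tests: a Loewe-additive (dose
additive) mixture of two median-effect drugs is itself exactly
median-effect **only when the drugs share the slope m** — the
parallel-curve assumption under which the two-term CI is exact. With
unequal slopes the mixture's linearized curve is slightly convex and a
straight-line fit deviates from CI = 1 by up to ~0.1–0.15 at the grid
edges. The dose-additivity consistency check therefore draws drug pairs
with a shared slope (m ~ logU[1, 2.5]) and independent potencies
(Dm ~ logU[0.5, 10] µM); unequal-slope behaviour is asserted only
qualitatively (a Bliss surface's CI is not identically 1).

## CDI scoring and anchor screens

`CDI = v_AB/(v_A·v_B)` on viability fractions. Classification bands:
CDI < 0.7 significantly synergistic; up to 1 − τ synergistic; within
1 ± τ additive; above antagonistic, with τ = 0.05 by default — an additive
*band* is required because CDI exactly 1 has measure zero in noisy data.
When the single-agent product falls below ε = 10⁻⁶ the CDI is reported as
undefined rather than a number: the compound is effectively single-agent
lethal and the ratio is uninformative. In anchor screens, compounds with
solo viability below 0.1 (configurable) are flagged `single_agent_effective`
and withheld from synergy labels for the same reason. CDI is computed on
replicate means; a per-replicate CDI with a one-sample t-test against 1 is
provided as a secondary statistic but does not drive the primary labels
(the threshold rule is the primary definition of "significant" synergism
here; a replicate-level test answers a different question and requires a
replicate structure screens often lack).

Hit intersection across screens returns per-screen hit sets
(defined CDI < threshold), every k-way intersection, and exclusive Venn
region counts.

## In-vivo synergy

Tumor size is caliper length × width (mm²) — dimensionally an area, and
recorded as such. The endpoint is the last measurement day of the trial;
animals without a measurement on that day (euthanized early) are excluded
per-protocol by default, or carried forward by last observation with
`carry_forward=True`. Arms are compared with a one-way ANOVA on final
sizes plus Tukey-HSD-adjusted pairwise p-values (the single-agent vs
combination pairs are the comparisons of interest); fully degenerate data
short-circuits to p = 1. The in-vivo CDI divides each arm's mean final
size by the vehicle mean and applies the in-vitro ratio to these relative
values; group means (not per-animal pairing) are used because arms are
independent animals, with a median option behind a flag. The statistic is
invariant to global unit rescaling and to swapping the single-agent labels.

## Expression arm

- **Signature scores** are means of Log2 TPM over a signature's genes;
  genes absent from the matrix are dropped with a warning and scores run
  over the intersection (a missing gene should not zero out a signature).
- **Clustering** of signature × model profiles uses average linkage on the
  1 − Pearson distance, rows and columns independently; similarity
  matrices are exact-symmetrized with a unit diagonal and summarized by
  off-diagonal extremes and the negative-pair count out of C(k, 2).
- **Single-cell QC** is computed per sample before any merging. The MAD is
  the raw median absolute deviation — no 1.4826 normal-consistency factor,
  since the recipe is stated in plain MAD units (`mad_scale` exposes the
  scaled variant). nFeature and nCount are cut at > n_mads (default 3)
  MADs from the sample median in either direction; the mitochondrial
  cutoff is min(median + 3 MAD, 25%), with the median and MAD computed
  only over cells at ≤ 50% mito so dying cells do not drag the center up.
  Comparisons are strict, so a zero-MAD (constant) sample keeps all cells.
- **Signature-restricted PCA** runs on the centered, unit-variance-scaled
  (toggleable) submatrix of the signature's present genes, with k capped
  at min(genes, cells) − 1. Scaling is the default because signature genes
  span very different expression ranges and the embedding should not be
  dominated by the most expressed ones.
- **Antibody arrays**: each probe is divided by its own background, then
  by the mean background-normalized positive-control level, cancelling
  global exposure differences between membranes; fold changes are
  probe-wise treated/control ratios of these normalized values.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of a `SimulationSpec`; streams are keyed
by (seed, scenario, entity id) so enlarging a simulation never perturbs
existing draws. Noise is multiplicative log-normal with mean 1 everywhere
(viabilities and tumor sizes are positive, scale-dependent quantities),
parameterized by its CV — 5% for plate assays, 10% for caliper
measurements, with 20% inter-animal baseline spread.

- **Dose-response plates**: true viability 1 − fa(D) from chosen (m, Dm),
  replicate wells with independent noise, vehicle wells included so tables
  round-trip through normalization. The default dose design places 8 doses
  so the true effects span fa 0.1–0.9 evenly — the classical
  median-effect-plot guidance (bracket the IC50 inside the informative
  10–90% window). Under that design, 8 doses × 3 replicates at 5% CV give
  ~4% median parameter error; a naive ±10× log series nearly doubles it
  because near-saturated wells are uninformative after linearization.
- **Combination surfaces**: Bliss (viabilities multiply), Loewe (dose
  additivity solved by bisection on fa to 10⁻¹⁰), or interaction(κ)
  (Loewe with all single-agent equivalent doses scaled by κ, so the true
  CI is κ at every effect level; κ < 1 plants synergy).
- **Anchor screens**: 516 compounds by default, one dose per compound;
  solo viabilities uniform 0.4–1.0; planted synergists get true CDI
  uniform in [0.3, 0.65], others exactly 1; a configurable head of the
  library is single-agent lethal (< 5% viability).
- **Tumor trials**: exponential growth (rate 0.08/day) from ~25 mm² at
  seeding, treatment from day 14 to day 42, measurements every 3 days,
  8 animals per arm. Arm effects are parameterized as target relative
  final sizes versus vehicle (defaults 0.5 and 0.6) and converted to
  post-treatment growth rates; the combination's effect is the product of
  the single-arm effects times a synergy factor σ, so σ is exactly the
  noise-free in-vivo CDI. This reconciles "effects scale the growth rate"
  with "combination effect is the product of single-arm effects".
- **Expression cohorts**: flat Log2 TPM baseline (2.0) with per-sample
  shifts added to signature-gene blocks and additive Gaussian noise in
  log2 units; true per-sample signature means are returned.
- **Cell QC metrics**: baseline metrics drawn from bounded (uniform)
  distributions whose support sits inside the 3-MAD acceptance band, so
  baseline cells are never filtered; outliers are planted at 6 baseline
  MADs beyond the median (alternating directions) or at 30% mitochondrial
  reads.

What the generators do **not** emulate: plate-position and batch effects,
dose-dependent error structure, drug interactions beyond the three
reference surfaces, tumor regression/plateau kinetics and animal dropout,
mean–variance relationships and dropout in expression data, and any
correlation between QC metrics and expression. Passing tests therefore
demonstrate the correctness and internal consistency of the statistics
under their own model assumptions, not robustness to every artifact of
real screens.

## Problem sizes

The bundled benchmark runs use 100 simulated plates for parameter
recovery, 5 drug pairs for dose-additivity consistency, 200 compounds ×
8 replicates for Bliss calibration, 200 replicate tumor trials per synergy
level, 50 random profile matrices (6–10 × 5–8) for the clustering
cross-check, and 20 simulations × 500 cells for QC recovery — sizes at
which every stochastic summary (median error, mean CDI, exceedance
fraction) is stable to well under its acceptance margin across seeds.

## Known limitations

- No confidence intervals on CI/DRI (the algebraic delta-method estimator
  of the reference desktop tool is not implemented in v1); no ≥3-drug
  combinations; no checkerboard (dose-matrix) designs.
- The Bliss/Loewe duality means CDI- and CI-based calls can disagree for
  strongly unequal drugs; both are reported, neither is "corrected"
  toward the other.
- Mixed-effects longitudinal growth modelling is out of scope; only the
  final-measure analysis is provided.
- Gene-signature scoring assumes Log2 TPM input; no within-matrix
  re-normalization is attempted.
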