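# Methods

## Study design being modelled

The pipeline targets a two-session pharmacological crossover: every animal
is scanned once under psilocybin and once under saline, in randomized
order. Each run of 1450 frames (TR 1.5 s) is split positionally into a
pre-injection baseline epoch (first 340 frames) and a post-injection epoch
(last 340 frames); all treatment effects are expressed as post-minus-pre
changes, so slow session-level drifts cancel within subject. Two groups are
compared: animals with an alcohol-deprivation-effect (ADE) relapse
phenotype and controls. The relapse phenotype is quantified dimensionally
as the normalized relapse rate, 100 · relapse intake / baseline intake (%
of baseline, both in g/kg).

The epochs are defined by frame count, not by timestamps: the nominal
acquisition bookkeeping (1450 × 1.5 s = 36.25 min) does not exactly match a
36 min 30 s run description, and a positional definition makes the split
independent of that discrepancy.

## Synthetic cohort generator

The generator is first-class, tested code; it defines the study conditions
under which every downstream guarantee is verified.

**Signal model.** Regional BOLD signals follow a linear latent-factor
model. The 44 regions are partitioned into three signal communities —
DMN/cortical (20 regions, containing the 12-region DMN), sensorimotor (7)
and subcortical (17) — and region *i* in community *c* is

    x_i(t) = λ · f_c(t) + σ · ε_i(t),   λ = 0.8, σ = 1.0,

with unit-variance community factors f_c and idiosyncratic noise ε_i, all
band-limited to 0.01–0.1 Hz (white noise passed through the same
forward-backward Butterworth filter the preprocessing uses). This is the
simplest generative structure whose correlation pattern exhibits the
modular organization the graph analysis assumes; baseline within-community
correlations are λ²/(λ²+σ²) ≈ 0.39 (Fisher z ≈ 0.41), a realistic cortical
coupling level.

**Treatment effect.** Under psilocybin, during the post-injection epoch
only: (a) the DMN/cortical loadings shrink to λ·(1−drop); (b) an extra
shared factor couples the hypothalamus (HypR) and dorsal raphe (DRN) hubs
(loading `hub_gain`) to the cortical community (loading `hub_gain`/2),
producing hub-to-cortex hyperconnectivity. Under saline one generating
model covers the whole run.

**Relapse blunting.** For ADE animals the drop is attenuated linearly in
the normalized relapse rate above 100%:

    drop = dmn_drop · max(0, 1 − β · (relapse_norm − 100)/100).

Linearity is a modelling choice; only a monotone negative association is
asserted by the recovery tests.

**Defaults and why.**

| parameter | default | rationale |
|---|---|---|
| cohort | 15 ADE + 6 control | the modelled design |
| frames / TR | 1450 / 1.5 s | the modelled acquisition |
| baseline intake | N(6.35, 1.75) g/kg, floored at 1 | group mean ± SD of the modelled phenotype |
| relapse intake | baseline + \|N(1.75, 0.8)\| | reproduces the ~8.1 g/kg relapse mean (~128% normalized) while keeping relapse > baseline |
| `dmn_drop` | 0.5 | with β = 2.0, gives replicate-level Spearman(relapse, DMN drop) ≈ −0.5 and ≥95/100 sign recovery — the generator's qualitative-recovery contract |
| `blunting_beta` | 2.0 | see above; spreads the realized drop over ≈0–0.5 across the relapse range |
| `hub_gain` | 0.6 | hub–cortex z-increase ≈ 0.1, detectable at the edge level in a 21-subject paired design without dominating the cortical effect |
| `noise_sd` | 1.0 | sets the baseline coupling level above |
| motion spikes | p = 0.003/frame, 0.2 mm | flags <1% of frames, satisfying the <10% censoring budget of the design |

**Motion.** Six-parameter traces (3 translations mm, 3 rotations rad) are
slow sub-threshold drifts plus single-frame spike excursions, so each spike
raises framewise displacement on the spike frame and the frame after —
exercising the scrubbing path.

**Voxel volumes.** On request a session gets a small 4D grid (default
16×16×8, 0.3 mm in-plane) whose in-mask voxels copy their region's signal
plus voxel noise. That suffices for the voxel-wise GBC, entropy and
cluster-correction pathways at desk scale; there is no hemodynamic forward
model, no physiological-noise simulation and no anesthesia model.

**What passing tests do and do not show.** The generator realizes the
modular, band-limited, Gaussian-factor case with exactly matched epochs and
stationary noise. Real data add scanner drifts, non-Gaussian physiological
noise, spatial autocorrelation, registration error and inter-animal
anatomical variability; tests passing here verify the *statistical
machinery* (correctness, calibration, recovery under the assumed model),
not robustness to those artifacts. One visible consequence: thresholded
graphs from the three-factor model are more modular than empirical
connectomes, so their small-world propensity sits near the lattice limit
rather than in the empirical small-world regime (the SWP machinery itself
is verified on lattice, random and Watts–Strogatz graphs).

## Preprocessing

- **Framewise displacement** is the Power-style sum of absolute
  differentials of the six parameters, rotations converted to mm as arc
  length at a 5 mm head radius (rat). FD(1) = 0.
- **Scrubbing** replaces frames with FD > 0.05 mm per region by a cubic
  spline fitted through unflagged frames; flagged frames outside the first/
  last unflagged anchor use nearest-neighbour extension because splines
  extrapolate poorly. A flagged fraction above 10% is surfaced as a
  warning flag, not an error; an all-flagged series is an error.
- **Confound regression** projects each region onto [intercept | motion
  parameters] by least squares in a single joint design (the ordering of
  motion vs other confound regression is not meaningful for a joint fit).
  Rank-deficient designs raise, naming the collinear columns via pivoted QR.
- **Band-pass** is a zero-phase (forward-backward) second-order Butterworth
  at 0.01–0.1 Hz. Zero-phase filtering preserves epoch alignment; the gain
  is ≥0.9 through the central band and ≤0.1 an octave outside, but — as for
  any IIR band-pass — reapplication further attenuates band-edge content,
  so pipeline idempotence holds exactly only for mid-band signal.

## Connectivity

Pearson r per region pair, Fisher z = atanh(r) with |r| clipped at 1−1e−7
(so duplicated signals stay finite at z ≈ 8.1); constant regions are
flagged missing rather than zero. GBC is the signed mean z of each mask
voxel to all others (self excluded); the signed convention matches
connectivity t-maps with both directions of effect. Gaussian smoothing
(FWHM 0.6 mm default; sigma = FWHM/2.3548/voxel size) precedes GBC and
voxel-wise entropy. No global-signal regression anywhere in the pipeline.

## Network-based statistic

Observations are per-session difference matrices (2 per subject). The
treatment statistic at each edge is the one-way GLM F between the two
condition groups of those 2n observations, df (1, 2n−2) — for n = 21 the
upper 1% critical value is F = 7.31. (A published description of the same
design prints this threshold with df (1, 19), but 7.31 is the 1% point of
F(1, 40), not F(1, 19) ≈ 8.18; the df are therefore exposed explicitly
everywhere rather than hard-coded.) The interaction statistic is the
one-way F between groups on per-subject (psi − sal) responses, df (1, n−2).

Suprathreshold edges (F > F_pt) are grouped into connected components;
the component statistic is extent (edge count). FWE-corrected p-values
compare each observed extent with the permutation null of the maximum
extent: condition swaps within each subject's exchange block for the
treatment contrast (2^n group; sampled, not enumerated), group relabeling
between subjects for the interaction. p = (1 + #{null ≥ obs})/(K + 1)
(Phipson–Smyth), so p ∈ [1/(K+1), 1]. Edges with zero residual variance
report F = +inf (always suprathreshold). Because extent is integer-valued,
the FWE test is exact-or-conservative; at stringent primary thresholds the
null suprathreshold graph is very sparse and the discreteness makes it
measurably conservative — the calibration suite therefore checks the
nominal level at a lenient threshold where the extent statistic is
near-continuous, and only validity (not tightness) at stringent ones.

## Graph metrics

Weights are Pearson correlations with negatives zeroed (nonnegativity is
required by the weighted clustering and SWP definitions) and normalized by
the maximum. Proportional thresholding keeps the ⌊p·E⌋ strongest edges with
a deterministic tie-break (weight descending, then node pair), giving
nested edge sets across the 10–50% grid (41 thresholds, 1% step).
Per-threshold metrics are averaged with flagged (disconnected/degenerate)
thresholds excluded.

- Clustering: Onnela geometric-mean form; path length: Dijkstra with
  distance 1/weight; disconnected graphs are flagged at the threshold level.
- Random references (20 per threshold by default, a runtime/accuracy
  compromise): connectivity-preserving double-edge swaps of the binary
  topology (preserving the degree sequence) with the weight multiset
  reshuffled onto the rewired edges. Lattice reference: observed weights
  sorted descending onto node pairs ranked by ring distance.
- SWP = 1 − √((ΔC²+ΔL²)/2) with ΔC, ΔL clipped to [0, 1]; degenerate
  normalizations (references coincide) are flagged missing. Limiting
  behaviour: ring lattices and dense random graphs both give
  SWP → 1 − √½ ≈ 0.293; Watts–Strogatz graphs at 10% rewiring exceed 0.6.
- Participation uses a fixed modular partition (Louvain on networkx,
  seeded, best modularity of 50 restarts) so that changes reflect
  connectivity, not partition churn; the intended baseline is the
  group-mean saline-TP1 graph. Both the standard coefficient
  P_i = 1 − Σ_s (κ_is/k_i)² (default) and the literal
  intermodule-strength/total-strength ratio are implemented behind a
  switch, since the two readings of "participation index" differ.

## DMN and entropy

DMN connectivity is the mean over the 66 within-DMN pairs; within-DMN
strength of a region is the mean of its 11 DMN edges (the mean of the 12
strengths equals the DMN mean — a double-counting identity used as a
regression test). Sample entropy uses m = 3, r = 0.2 on mean-subtracted
series; "standardized Euclidean" template matching divides each embedding
coordinate by its across-template SD, with match criterion
distance ≤ r·√dim, keeping r = 0.2 commensurate with the conventional
Chebyshev r·SD rule. Standardization is per series (which also makes
SampEn affine-invariant); N−m templates are used at both lengths, and
self-matches are excluded. Constant series and B = 0 are flagged missing;
A = 0 reports +inf. Voxel-wise entropy is averaged within regions, and the
DMN summary averages the 12 region means (not voxel-pooled).

## Inference

For the 2×2 mixed design all effects reduce to the per-subject session
difference d_i = Δpsi_i − Δsal_i: the treatment main effect tests the
unweighted (Type-III-style, MATLAB-convention) grand mean of d across
groups, the interaction tests the group difference of d; both are
F(1, n−2) = squared t of an effect-coded OLS fit. For unbalanced groups
this deliberately differs from size-weighted conventions (e.g. pingouin's),
which is why the pingouin cross-check in the tests runs on balanced data
and the unbalanced cross-check uses the OLS route. Permutation analogues:
sign flips of d (session swaps) for treatment, group relabeling for the
interaction, both +1-smoothed; under Gaussian errors the permutation p
tracks the parametric p to ≲0.02 (median) at 10 000 permutations, and under
skewed errors it keeps nominal type-I level where the parametric test may
not.

Spearman correlations use average ranks for ties; two-sided p from the t
approximation at N ≥ 10 and exact rank-permutation enumeration below.
ρ → t uses the absolute-value form t = |ρ|/√((1−ρ²)/(N−2)) (so correlation
t-maps are one-signed; |ρ| = 1 flags +inf). BH-FDR supports a family size
m larger than the supplied list (implemented by padding with ones, which
is algebraically the m-test step-up). Critical thresholds are reported to
two decimals, matching their use as map-thresholding constants.

Cluster-extent correction thresholds voxel t-maps at a cluster-defining
threshold, labels face-adjacent (6-connected; 18/26 configurable)
suprathreshold components, and compares extents with the permutation null
of the maximum extent — sign flips of subject difference maps for paired
contrasts, covariate shuffling for correlation maps. Permutation was chosen
over random-field theory as the assumption-light, desk-scale equivalent;
the thresholds are shared with the parametric convention. A sequence-effect
screen (session order as a between factor) is available through the same
ANOVA surface.

## Simulation sizes in the verification suite

Calibration checks run at sizes chosen for a single CPU: 200 null
replicates for the NBS-FWE, cluster-FWE and permutation-ANOVA levels (500–
1000 permutations each; 12 subjects; 24-node graphs; 10×10×5 smoothed
maps), 1000 replicates for the parametric ANOVA level, and 100 replicate
cohorts for relapse-correlation sign recovery. Rejection-rate assertions
use the exact central 95% binomial interval around 0.05.

## Known limitations

- The generator's step change at the post-injection epoch ignores drug
  onset kinetics between the epochs (frames 341–1110 carry no effect).
- Cortico-cortical correlations inside a community are exchangeable —
  there is no distance-dependent structure, so spatial cluster shapes in
  voxel analyses are driven by the synthetic label geometry.
- The mixed ANOVA covers exactly the 2×2 between-within design; no
  mixed-effects regression, covariate adjustment beyond the
  baseline-drinking screen, or Bayesian variants.
- Sample entropy is single-scale; no multiscale entropy or Lempel–Ziv
  complexity.
- NBS offers extent-based components only (no intensity/mass statistics,
  no TFCE); connectivity matrices are full-correlation only (no partial or
  sliding-window variants).
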