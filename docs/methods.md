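# Methods

This note documents the statistical procedures implemented in `iegnet`,
the conventions chosen where more than one was defensible, what the
synthetic generator does and does not emulate, and the problem sizes the
test suite uses.

## Data model and normalization

Input is a long-format table: one row per (animal, group, ROI, section)
with a non-negative relative-dpm value, plus a reference channel ("gcc",
genu of the corpus callosum — white matter, expected signal-free) per
animal.  Three adjacent sections per animal are averaged (sample SD
reported; the replicate count is data-driven and a count ≠ 3 is logged,
not rejected).  Normalization divides each analysis-ROI mean by the
same animal's gcc mean (**ratio mode**, the default): published
relative-dpm group means of order 0.1–1 with differences of 0.1–0.7 are
consistent with a ratio scale.  A subtractive mode shares the
interface.  Normalization is per-animal, not by the group-mean gcc;
both scopes would share the interface, and the per-animal form is the
one that makes the gcc a true within-animal covariate.  Missing
(animal, ROI) cells are hard errors — with five animals per group
imputation would be indefensible.  Group labels are free strings; the
four study labels are defaults of the synthetic generator only.

## ROI contrasts

Per ROI, a two-sample t test of (first group − second group): classical
pooled-variance by default (df = n₁+n₂−2, i.e. 8 for 5 vs 5), Welch as
a per-run flag — published reports in this design mix both, so neither
is asserted as canonical.  The 95% CI uses the same variance estimate
and df as the test, so CI-excludes-zero and p < α are equivalent (this
duality is asserted in tests).  Family-wise control is Bonferroni over
the m = 33 ROIs (0.05/33, displayed as 0.0015 at 4 decimals).  Display
rounding (t and CI to 2 decimals, p to 3) lives only in the report
writer; internal values keep full precision.  Degenerate inputs: zero
variance in both groups with equal means gives t = 0, p = 1; with
unequal means, p → 0 and the result is flagged.

## Correlation connectome

Within each group, Pearson r over animals for all ROI pairs; two-sided
p from the exact transform t = r√((n−2)/(1−r²)) with n−2 df (n = 5 →
df = 3).  Animal-level means (not pooled section replicates) enter the
correlation, matching the averaging step of the data model.  Constant
columns make their pairs undefined: flagged, excluded from edge
candidates, and fatal for the display ordering until dropped.

Networks retain pairs with **raw** p < 0.05 — deliberately uncorrected
across the 528 pair tests, a sensitivity/specificity trade-off; a
stricter threshold is a flag.  Edge weight is the signed r (negative
couplings are findings, not noise).  ROIs without any retained edge are
dropped from the node list; this is what lets 33 quantified ROIs yield
networks of 28–32 nodes.  The heatmap display order comes from
agglomerative clustering with average linkage on distance 1 − r; the
linkage choice is a display convention and is recorded in run
manifests.

## Graph metrics

* **Density** = E/(N(N−1)), the ordered-pair convention.  This is the
  convention under which the published node/edge/density triples are
  internally consistent (e.g. 128/(32·31) = 0.129, 34/(28·27) = 0.045),
  and it implies a complete undirected graph has density 0.5 — asserted
  and documented rather than hidden.
* **Path length, clustering, components, betweenness** are computed on
  the unweighted thresholded topology: correlation weights carry sign,
  and negative weights have no shortest-path semantics.
* **Characteristic path length** averages shortest-path lengths over
  connected node pairs only, so multi-component networks keep a finite
  value.
* **Clustering coefficient** defaults to the mean local coefficient
  (degree < 2 contributes 0); global transitivity is available, and
  neither variant is claimed to be "the" published one (the published
  values are data-dependent and unverifiable).
* **Betweenness** is unnormalized by default; the normalized variant
  divides by (N−1)(N−2)/2.
* **Global strength** is Σ|r| over all unordered pairs of the **full**
  correlation matrix — the whole-network statistic the permutation
  comparison uses; a thresholded variant sits behind a flag.

## Permutation comparison

Whole animals are the exchangeable unit: the n₁+n₂ animals are pooled
and reassigned to pseudo-groups of the original sizes.  All three
statistic families — edge-wise r differences, the global-strength
difference, and per-node degree/betweenness differences of the
re-thresholded networks — are evaluated on one shared set of
assignments, which keeps the 595 test units of a 33-ROI comparison
mutually coherent and the computation to a single pass.

When C(n₁+n₂, n₁) ≤ the requested B, every distinct assignment is
enumerated once (the 5+5 design gives 252, fewer than the conventional
B = 1000) and p is exact: the count of assignments with |statistic| ≥
|observed| over the total, the identity assignment included, so
p ∈ [1/K, 1].  Otherwise B uniform assignments are drawn from the
given seed and p uses the add-one estimator (count+1)/(B+1), which is
never 0.  A `force_monte_carlo` flag reproduces the literal
B-random-permutations setting.  Two-sided testing throughout, on
absolute differences.  Degenerate pairs arising under a permutation
(constant pseudo-group column) enter the null as 0 and are counted in a
warning counter — dropping those permutations would bias the null.
A node absent from a thresholded network carries degree and betweenness
0.  No multiple-testing correction is applied across edges or nodes,
mirroring the raw-0.05 working point of the network construction.

Inside the permutation loop, thresholding uses the critical |r| that is
exactly equivalent to p < 0.05 at the pseudo-group's df, and
betweenness is computed by a direct Brandes pass over the boolean
adjacency (`iegnet._fastgraph`) — a calibration run evaluates on the
order of 10⁵ small graphs, where graph-object construction would
dominate.  The fast path is asserted equal to the
networkx-based route in the test suite.

## Synthetic generator

Animal-level ROI vectors are multivariate normal — the distributional
assumption of the analysis itself (normality-gated t tests, Pearson r)
— with a target correlation matrix imposed via its eigenvalue square
root, per-ROI means and SDs, and independent Gaussian section noise.
The gcc channel is drawn independently (mean 1, SD 0.05 by default) and
the raw section value is emitted as (normalized value × same-animal
gcc), so the full data-model path (averaging + ratio normalization)
round-trips the generated table exactly at zero section noise.  Raw
section values are clamped at 0 (optical density cannot be negative);
the analysis-level values are not clipped by default, preserving the
target correlation structure exactly (a strict-positivity flag exists).

Presets (defaults are the study conditions: 4 arms × 5 animals ×
33 ROIs × 3 sections):

* **null** — identical generative parameters in all four arms, with a
  block-structured baseline correlation over anatomical families
  (septal, ventral-striatal, dorsal-striatal, insular, cortical;
  within-block r = 0.6, between 0.2 — a one-factor-plus-block-factors
  decomposition, PSD by construction).  Real ROI panels are strongly
  inter-correlated, and this baseline yields thresholded networks of
  realistic density (~0.04–0.1); an independence baseline would make
  the centrality nulls degenerate.
* **paper_like** — baseline arms plus a challenge arm (KET/VEH-like)
  whose indusium-griseum (IG) row is set to −0.6 and repaired to the
  nearest correlation matrix by eigenvalue clipping, with lowered
  dorsal-striatal/medial-septum means; the challenge+drug arm restores
  the baseline (positive) structure with raised means.
* **edge_difference** — two arms differing in exactly one specified
  pair's correlation (default Δr = 0.9 on an identity background), for
  power studies.

What the generator does **not** emulate: measurement-floor censoring,
between-section spatial trends, animal-level covariates, heavy-tailed
or skewed dpm distributions, and any attempt to mimic the actual
unpublished values.  Passing tests therefore demonstrate correctness of
the machinery and its calibration under the stated model, not
robustness to non-normal real data.  Section noise dilutes observed
correlations toward zero; calibration presets default to zero section
noise so target correlations are exact.

## Numerical choices

* Correlation p-values use the t transform, not permutation, matching
  standard practice for these matrices; |r| = 1 maps to p = 0.
* Sample SD uses ddof = 1 everywhere; a single replicate has SD 0.
* PSD validation tolerates eigenvalues ≥ −1e−8; preset repair clips at
  1e−10 and rescales the diagonal.
* Permutation tie handling needs no epsilon: the observed row is
  evaluated through the identical vectorized path, and complement
  assignments produce bitwise-negated differences, so ties are exact.
* Hierarchical ordering and spring layouts are seeded/deterministic;
  identical configs and seeds reproduce byte-identical artifacts.

## Problem sizes in the test suite

Unit tests run on 5-ROI subsets and ≤8-node random graphs against
brute-force oracles.  The acceptance suite uses the study geometry:
200 replicate null datasets (5 animals/arm, 252 exhaustive assignments)
for type-I calibration of all three test families; B = 10,000
Monte-Carlo draws against the 20-assignment exhaustive null at
3+3 animals; 50 replicates at 20 animals/group for the injected-edge
power check; and n = 1000 animals for marginal/correlation recovery.
The whole suite completes in a few minutes on one CPU.

## Known limitations

* Five animals per group make individual Pearson coefficients extremely
  noisy (df = 3); the package reproduces the published workflow but the
  workflow's power limitations are inherited, not repaired.
* Discrete centrality statistics (integer degree differences, tied
  betweenness values) make their permutation tests conservative at
  small n; calibration shows rejection rates slightly below nominal
  (≈0.03–0.045 at α = 0.05) rather than above.
* The exhaustive-p convention counts the identity assignment, so the
  smallest attainable p at 5+5 is 1/252 ≈ 0.004; claims below that
  resolution are not possible at this design size.
* Welch-vs-pooled ambiguity in the source workflow is surfaced as a
  flag, not resolved.
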