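# Methods

## Scope and model

`hiertier` analyses the degree hierarchy of structural connectomes:
binary networks whose nodes are parcellated brain regions and whose links
are tractography-derived white-matter connections.  The pipeline has five
scientific stages.

1. **Network construction.**  Streamline counts weighted by SIFT2 give a
   fiber-density matrix `w_ij = mu * sum_s sc_s` over streamlines with
   endpoints `{i, j}`.  Each subject's matrix is thresholded to a target
   edge density and binarized: the `m = floor(d * n(n-1)/2)` strongest
   connections are kept.  Floor guarantees the realized density never
   exceeds the target; ties are broken by (weight descending, i, j)
   so that thresholding is deterministic and edge sets are nested across
   a density sweep.  The default density is 0.30 on 84 nodes (1045
   links), with a sweep range of 0.20–0.40 for robustness checks.

2. **Hierarchical complexity (HC).**  For a node of degree p, its
   neighborhood degree sequence is the ascending list of its neighbors'
   degrees.  With `K_p` the set of nodes of degree p and `mu^p(j)` the
   mean j-th entry over that class,

       R = (1/D) * sum_{p : |K_p|>1} [1/(p(|K_p|-1))]
             * sum_j sum_{i in K_p} (s_i^p(j) - mu^p(j))^2

   where D counts all distinct degrees, including singleton classes
   (which contribute zero to the sum but still scale the average; the
   implementation exposes this convention explicitly).  R = 0 for any
   vertex-transitive graph; large R means regions at the same level of
   the degree hierarchy are wired in diverse ways.  Tier-restricted HC
   averages the per-degree terms over the degrees inside a tier's range.
   Degenerate inputs (no repeated degree — only possible at n = 1) yield
   R = 0 with a warning flag rather than an error.

3. **Tier discovery.**  Degrees of all nodes of all subjects in a group
   are pooled and a 1-D Gaussian mixture with per-component variances is
   fitted for K = 2..6 by EM (k-means++ initialization, 10 restarts,
   tolerance 1e-6); the K minimizing BIC = (3K-1) ln N − 2 loglik is
   selected.  Tier boundaries are the crossings of the weighted component
   densities `pi_a N(m_a, s_a^2)` between adjacent means, found by root
   bisection on the log-density difference; if a component dominates
   throughout, the midpoint of means is used with a warning.  Tier 1 is
   the highest-mean component.  A degree exactly equal to a threshold is
   assigned to the lower-degree tier.  **Variance floor:** because
   degrees are integers, EM with a purely numerical floor can collapse a
   component onto a single repeated integer value (sigma ≈ 0.03) whose
   spike likelihood outweighs the BIC penalty, inflating the selected K.
   The floor is therefore set to 0.5 (sigma ≥ ~0.7, the integer rounding
   scale); planted components have sigma ≈ 3, so real fits are
   unaffected.

4. **Configuration-model nulls.**  The null for HC preserves each
   subject's degree sequence exactly and randomizes everything else.
   Stubs are matched at random; a drawn pair creating a self-loop or a
   duplicate link is rejected and redrawn.  A full-restart reading of the
   rejection rule is not viable at connectome densities: the probability
   that a uniformly random complete pairing of stubs is simple is
   approximately `exp(-lambda/2 - lambda^2/4)` with
   `lambda = <k^2>/<k> − 1 ≈ 25` at 30% density, i.e. below 1e-100, so a
   pass-level restart rule would never terminate.  Instead the matcher
   processes the node with the most open stubs first (for stub matching
   the processing order leaves the pairing distribution unchanged) and,
   when a stub is blocked, relocates an existing link: a link (x, y)
   with x unattached to the blocked node u and y unattached to another
   open node v is replaced by (u, x) and (v, y), consuming two stubs —
   the same progress as a regular pairing, so a pass always terminates.
   A pass that exhausts its repair budget is restarted (capped at
   10,000 restarts); degree preservation and simplicity are exact in
   every emitted replicate.  One replicate per subject mirrors a
   subject-wise null comparison; independent per-replicate RNG streams
   make many-replicate ensembles reproducible.

5. **Tier topology and statistics.**  The hemispheric symmetry score of
   a homotopic pair (l, r) is `observed / expected` with
   `observed = |N(l) ∩ mirror(N(r))|` counted over all n regions and
   `expected = k_l k_r / n`, the mean overlap of two independently drawn
   neighborhoods; 1 is chance, and the maximum for matched degrees k is
   n/k.  Joint absences are not counted.  A region is *commonly*
   connected to a tier if it links to at least 80% of the tier's regions
   and *uncommonly* if it links to more than none but at most 20%
   (boundaries inclusive).  Connections are classified into seven
   categories from endpoint tissue class and hemisphere (cortical,
   central, cerebellar; intra- vs inter-hemispheric for
   cortico-cortical).  The group connectome keeps links shared by at
   least two-thirds of subjects (`ceil(2S/3)` with an epsilon guard on
   the product), and a node's consensus tier requires the same two-thirds
   occupancy.  Edge and pair attribution to tiers uses the better-ranked
   (lower-numbered) tier of the two endpoints.  Connection lengths are
   normalized by `volume^(1/3)` by default so the quantity stays in
   length-like units; the exponent is a parameter.  Group contrasts use
   the two-sided Wilcoxon rank-sum test (exact enumeration when the
   pooled sample has ≤ 25 observations and no ties, otherwise the normal
   approximation with tie and continuity corrections), Cohen's d with
   (n1−1, n2−1)-weighted pooled SD, Pearson correlations for tier
   consistency, Pearson chi-square without continuity correction for
   category proportions, and the Scheirer–Ray–Hare rank-based two-way
   analysis for crossed group x tier designs (cell-mean sums of squares,
   exact for the balanced layouts the pipeline produces; its interaction
   type-I error is verified by simulation).  All P-values of one run form
   a single Benjamini–Hochberg family at q = 0.05, and the realized
   cutoff (largest rejected p) is reported.

## Synthetic cohorts

No public connectome data accompany the analysis, so the testbed is a
generator that plants exactly the features the pipeline is designed to
detect.  Defaults describe a neonatal-like cohort: 84 regions (41
homotopic pairs + 2 midline central nodes), 30 subjects per group, and a
four-component degree mixture with means 13/27/44/70, SDs 3 and weights
0.40/0.40/0.15/0.05, emulating a four-tier aggregated degree
distribution at 30% density (mean degree ≈ 26, density ≈ 0.31).

* **Anatomy.**  A cohort-level component assignment (one component per
  homotopic pair, resampled until every component is represented) plays
  the role of the parcellation: regions keep their tier identity across
  subjects, as in a real study population.
* **Degrees.**  Per subject, degrees are drawn from the component
  normals, rounded, clipped to [1, n−1], and Erdős–Gallai-checked with
  bounded resampling.  A pair shares one draw with probability
  `mirror_prob` (mirror-symmetric wiring requires matched left/right
  degrees) and draws independently otherwise — at `mirror_prob = 0` this
  keeps homotopic degrees uncorrelated, which is what makes the symmetry
  score's chance level equal 1.  Midline degrees are rounded to even
  numbers because their mirror copies consume stubs in steps of two.
* **Wiring.**  The mirrored stub matching described above creates each
  link and copies it to its mirror image with probability `mirror_prob`;
  at `mirror_prob = 1` the adjacency is exactly mirror-symmetric and
  every homotopic pair attains its analytic maximum score n/k.
* **Order knobs.**  Per-tier `eta in [0, 1]` interpolates a target mean
  pairwise Jaccard overlap between the configuration-model baseline
  (estimated from 20 null realizations) and an upper bound from nested
  neighborhoods.  Degree-preserving double-edge swaps are proposed
  toward popular-within-tier neighbors and accepted only if they raise
  the tier's shared-neighbor count without increasing per-degree
  complexity in the affected degree classes, or strictly lower the
  tier's own per-degree complexity — so ordering one tier cannot leak
  disorder into the rest of the hierarchy.  Swaps stop at the target, at
  a proposal cap (default 4000 per tier), or after a stagnation window;
  achieved overlaps are reported in the manifest.  Mirror-orbit links
  are never removed by ordering swaps.  The `term_like_config` preset
  plants ordered hubs and diverse mid-tiers (eta = 1/0/0/0 for tiers
  1..4); `preterm_like_config` additionally homogenizes the mid-tiers
  (eta = 1/0.6/0.6/0).
* **Geometry and weights.**  Regions are embedded at mirrored 3-D
  coordinates with mid-tier nodes in a tighter cluster (tier radius
  scales 1/0.6/0.6/1), so mid-tier connections are shorter on average;
  lengths are Euclidean distances plus Gaussian noise (SD 2 mm, floor
  1 mm).  Brain volume is lognormal around 4e5 mm^3 (≈ neonatal brain
  volume).  Planted links carry i.i.d. lognormal weights (sigma 0.5);
  non-links carry weak "spurious" weights strictly below every planted
  weight, emulating the near-fully-connected matrices of probabilistic
  tractography.  Thresholding at the planted density therefore recovers
  the planted adjacency exactly, while thresholding above it adds random
  spurious links rather than degenerate tie-break artifacts.

What the generator does **not** emulate: spatial wiring costs beyond the
coordinate embedding, modular/community structure, weighted-network
organization, measurement noise correlated across subjects, and any
biophysics of tractography.  Passing tests therefore demonstrate that
the pipeline detects the planted hierarchy, symmetry and group
contrasts under its own statistical assumptions — not that those
assumptions hold in MRI data.

## Numerical choices

* Edge counts use `floor(d n(n-1)/2 + 1e-9)`; the epsilon protects
  exactly-integer products (e.g. a density recorded as 2m/n(n-1)) from
  floating-point round-down.
* Weighted-matrix text output uses 17 significant digits so write/read
  round-trips are bit-exact.
* PDF crossings are bracketed between component means and solved to
  1e-12; thresholds must be strictly increasing.
* The two-thirds rules use an epsilon guard before `ceil`.
* All randomness flows through `numpy.random.Generator` seeded from
  explicit integer lists; cohort manifests record every seed, and a
  rerun of `run_study` on the same cohorts and seed is bit-identical.

## Problem sizes

Default test and acceptance workloads are sized for a laptop-class
single core: oracle equivalence on 100 random graphs (n ≤ 30), 1000
configuration-model sources (n ≤ 50), mixture recovery on pooled degrees
of 50 subjects × 84 nodes over 10–20 seeds, 50 hub-order replicates, 30
subjects per group for the planted contrast, and 100 replicate cohorts
for symmetry calibration.

## Known limitations

* The stub-matching sampler with rejection and relocation repairs is
  near-uniform over simple graphs with the given degrees but not exactly
  uniform (no practical exact sampler is; the relabelling-invariance of
  its HC null distribution is verified by a KS test).
* The eta knob's overlap target is not always attainable (hub
  neighborhoods saturate); the generator reports achieved overlaps and
  the planted *direction* is what the acceptance checks rely on.
* Tier labels are comparable across groups only through degree ranges
  and consensus maps; the optional merge map (e.g. {1: "A", 2: "B",
  3: "B", 4: "C"}) is a configuration choice, not an algorithm.
* Scheirer–Ray–Hare sums of squares are computed from cell means and are
  exact only for balanced designs.
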