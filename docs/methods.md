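# Methods

## Problem and model

`flocknet` infers an affiliation network for a group of N animals from
their trajectories: positions (x_t(n), y_t(n)) in metres at H shared
observation times inside a bounded region. The working premise is that an
affiliation shows up as *statistically significant* similarity in movement,
judged against a null model in which every animal moves independently
according to its own fitted movement model.

The pipeline is:

1. **Discretise space.** The bounded region is partitioned into D
   rectangular cells that cover it and are pairwise disjoint. Disjointness
   is exact under a half-open convention: a cell owns `[low, high)` per
   axis, with the region's top/right border closed on the outermost cells.
   Two constructors exist: a regular `nx x ny` grid, and a recursive
   balanced construction that repeatedly splits the cell holding the most
   observations perpendicular to its longer side (ties split on x) at an
   observed coordinate that equalises the children's counts as far as ties
   allow. The balanced construction concentrates cells where animals spend
   their time, which matters in heterogeneous habitats (feeding or watering
   sites).
2. **Fit per-individual occupancy models.** Either a categorical model —
   pi(i) = C_i / H, the relative occupancy counts, ignoring temporal order —
   or a first-order Markov model with column-stochastic transition matrix
   T(i|j) = (transitions j to i) / (departures from j) and initial
   distribution p0 equal to the point mass at the first observed cell.
   The departure count in the denominator is the occupancy count of j minus
   one if the sequence ends in j. Both models can be pooled across animals
   (summed counts); a pooled Markov fit keeps each animal's own p0 so
   per-animal occupancy marginals still differ. Transition columns of cells
   never departed from are undefined under maximum likelihood; they are
   flagged, and propagating probability into them raises an error instead
   of imputing, surfacing data insufficiency rather than biasing the null.
3. **Test each pair.** The statistic is the co-occurrence count e: the
   number of observations at which the pair shared a cell. Under the
   categorical null the per-time co-occurrence probability is the inner
   product p = <pi_n, pi_n'> and e ~ Binomial(H, p). Under the Markov null
   the probability varies with time (inner product of the two forward
   marginals) and e follows a Poisson-binomial distribution, computed
   exactly by a dynamic programme over time (O(H^2) time, O(H) memory; a
   conservation check |sum(pmf) - 1| <= 1e-10 guards precision — for the
   window counts this package targets, H up to ~10^4, no log-space variant
   is needed). The null is rejected when the inclusive tail
   P(E >= e_obs) <= alpha, equivalently when e_obs exceeds the critical
   value beta = max{e : P(E >= e) > alpha}. Because the test statistic is
   discrete, the achieved level is at most alpha (the test is exact but
   conservative). No multiple-testing correction is applied by default; an
   optional Bonferroni flag exists and is logged when used.
4. **Assemble networks.** Binary: an edge per rejected pair. Weighted,
   baseline approach: w = (e_obs - beta) / (H - beta) when e_obs > beta,
   else 0 — the co-occurrences attributable to chance are discounted from
   numerator and denominator. Weighted, segment averaging: the observation
   period is split into sub-periods (user-supplied or equal-length; no
   automatic change-point detection), a binary network is built per
   segment, and the mean adjacency is reported. The movement model is
   trained either once on all data (Markov transition counts summed per
   segment, so no spurious cross-segment transition enters) or per
   segment. Pruning (weights < 0.1 zeroed) is available for reporting and
   plotting only; statistics always use unpruned networks.

A consequence of testing against *fitted* individual models is robustness
to heterogeneous environments: a shared hotspot raises the null
co-occurrence probability, hence the critical value, so habitat preference
is not mistaken for affiliation. The package exposes this directly:
beta under pi = (0.25, 0.25, 0.5) (p = 0.375) is at least beta under a
uniform 3-cell model (p = 1/3) at equal H and alpha.

## Baselines and structure tests

**Gambit of the group.** The standard field heuristic is included for
comparison: a pair is affiliated in an observation window iff their
separation is within d metres (closed, <= d) for at least beta% of the
window's time points; with all animals observed in every window the
simple-ratio index applies (edge weight = affiliated windows / windows).
Windows are non-overlapping, aligned to the first time point, trailing
partial windows dropped — the same convention as the median windowing.
A sweep helper tabulates the strong sensitivity of the result to d, the
motivation for the significance test.

**Two-group permutation test.** Given two group labels, six statistics are
computed: connectivity level (proportion of realised edges) and mean
non-zero edge weight, within each group and between groups. Group labels
are permuted uniformly (group sizes preserved; one shared draw of
permutations serves all six statistics), and one-sided p-values use the
finite-sample correction (1 + count) / (n_perm + 1), which guarantees
validity; at n_perm = 10,000 the difference from the raw count is
negligible. Directions are fixed a priori: within-group statistics are
tested in the upper tail, between-group statistics in the lower tail
(configurable). The mean of an empty non-zero edge set is reported as 0
and flagged.

## Synthetic data: what it emulates and what it does not

The generators produce occupancy panels (and, separately, reflected
Gaussian random walks for continuous-space plumbing) with known ground
truth:

- `null_categorical` / `null_markov` / `hotspot_null` — exact nulls for
  calibration studies; the hotspot default places mass 0.5 on one cell
  (pi = (0.25, 0.25, 0.5) at D = 3).
- `leader_follower` — a follower copies the leader's current cell with
  probability rho, else moves independently.
- `subflocks` — one latent cell sequence per group; each member copies its
  group's latent with probability rho, else draws independently. With an
  i.i.d. uniform latent each animal's *marginal* stays uniform, so the
  fitted categorical null is exact while within-group co-occurrence is
  inflated to roughly rho^2 + (1 - rho^2)/D — a clean, tunable effect
  size. An optional flock-level coupling `rho_between` (default 0) adds a
  shared latent that an animal copies, with that probability, whenever it
  did not copy its group latent. This emulates a genuinely mixing flock:
  sub-flock ties stronger than, but not exclusive of, flock-wide
  association, which is the regime in which all six permutation statistics
  carry signal (with fully independent sub-flocks the inferred network has
  no between-group edges and the two within-group mean-weight statistics
  are degenerate under label permutation).

Each animal (and each latent group, and each random walk) draws from its
own named PRNG stream derived from the master seed, so equal seeds give
bit-identical data and adding animals never perturbs existing tracks.

The generators make no attempt at behavioural realism: no
attraction/repulsion zones, no circadian structure, no measurement noise,
no missing observations. Passing tests therefore demonstrate statistical
correctness of the inference machinery under its own model assumptions and
under known planted structure — not that real trajectory data satisfy
those assumptions (real data violate within-window independence in
particular, which is why median windowing with long windows is used in
practice to reduce autocorrelation).

## Numerical and interface choices

- **Even-count medians** are the mean of the two middle order statistics;
  windows are non-overlapping and aligned to the first sample, trailing
  partial windows dropped.
- **Completeness** is enforced by dropping animals with missing time
  points (logged), not by imputing; smoothing belongs upstream.
- **Cell indices are 0-based** throughout (NumPy-native); cell order is
  stable and documented per constructor.
- **Split ties** in the balanced partition go to the smaller left count; a
  split must leave observations on both sides, and a cell whose points
  coincide on both axes is an error naming the cell.
- **Sampling-rate analysis**: `interpolation_error` keeps every k-th
  sample (k = round(1/keep_fraction)), linearly interpolates the rest
  (ends repeat the first/last kept value), and reports the mean Euclidean
  reconstruction error over all original samples with a
  normal-approximation 95% CI. Kept samples contribute zero error; on
  straight-line constant-velocity motion the error is identically zero.
- **Tests at scale**: the statistical acceptance checks use 500 simulated
  pairs (H = 500, D = 25 or 3) for type-I calibration, 50 replicates of a
  20-animal sub-flock scenario for structure recovery, a 30-animal
  genuinely-mixing replicate for the six-statistic permutation test
  (n_perm = 1,000), and a 10^5-step chain for Markov parameter recovery
  (total-variation < 0.05 per column) — sizes chosen so the whole suite
  runs in well under a minute on one CPU while keeping Monte-Carlo margins
  (99% normal bounds) meaningful.

## Known limitations

- The Markov null assumes first-order dynamics on the chosen partition;
  too-short observation windows make the assumption fail on real data and
  inflate false positives.
- No observational-bias correction: all animals must be observed at every
  time point (partially observed groups need the correction literature the
  gambit community uses).
- Consistency of the test as the partition is refined with sample size is
  not addressed; the partition granularity is a user choice, though the
  inference is empirically robust over a broad range.
- p0 under maximum likelihood is a point mass, so Markov nulls condition
  on each animal's first observed cell.
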