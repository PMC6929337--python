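# Methods

This note records the models, parameter choices and numerical decisions
behind `decoyrank`, in enough detail to reproduce or audit any number the
package computes.

## Structural representation

Structures are CA-only traces. Decoy files produced by fragment-assembly
pipelines are minimal single-model coordinate files, and both the clustering
distance (RMSD) and TM-score are conventionally computed on CA atoms, so
nothing finer is represented. PDB reading honours `ATOM` records of the
first model only, skips `HETATM`, orders residues by residue sequence number
(insertion code as tiebreak) and keeps the first alternate location of a
duplicated CA. PSSM rows are matched to residues positionally (row i ↔
residue i); no re-alignment is attempted, and a profile whose row count
disagrees with the decoy length is rejected (or dropped with a warning when
auto-discovered).

## Distance measures

**RMSD.** Superposed RMSD is computed from the Kabsch/SVD solution with the
determinant correction that excludes reflections: for centred point sets the
optimal residual is ‖P‖² + ‖Q‖² − 2(σ₁+σ₂±σ₃). A raw (unsuperposed) variant
is available for callers that have already aligned coordinates. The
all-pairs matrix used by clustering evaluates the same closed form with
batched SVDs, which keeps a 60-decoy matrix (1 770 pairs) under 0.1 s.

**TM-score.** TM = max over rigid motions of (1/Lₙ) Σ 1/(1 + (dᵢ/d₀)²).
Because decoys of one protein share the native's length and residue order,
the correspondence is positional and Lₐ = Lₙ always; the different-length
case is out of scope. The length scale d₀ = 1.24·(Lₙ−15)^⅓ − 1.8, floored
at 0.5 Å, is the standard normalisation and is configurable through
`TMScoreParams`.

The maximisation is heuristic but deterministic, in three phases:

1. *Seeding*: superpositions fitted on non-overlapping contiguous fragments
   of lengths L, L/2, L/4 (minimum 4 residues).
2. *Subset iteration*: each seed is refined by repeatedly superposing on the
   residues within a cutoff, for a cutoff schedule from d₀ down to 1.0 Å in
   0.5 Å steps, until the included set is stable (at least 4 residues are
   always kept).
3. *Polish*: the best superposition of every seed is refined by a direct
   ascent on the TM objective. Each per-residue term is convex and
   decreasing in d², so its tangent is a global lower bound and maximising
   the tangent sum is a *weighted* Kabsch problem with weights
   1/(1 + d²/d₀²)²; iterating this majorise-minimise step increases the
   score monotonically and converges to a stationary point.

The polish exists because the true optimum is generally not the
least-squares fit of any residue subset; without it the subset iteration
can undershoot by ~2 % on short, noisy chains. Tests verify agreement with
a multi-start brute-force search oracle to 1e-5 Å (RMSD) and 1e-3
(TM-score) on ≤10-residue instances.

## Clustering

A shrinking-scale procedure: scan 40 evenly spaced cutoffs d_c in
[1.0, 8.0] Å and take the smallest whose densest neighbourhood covers at
least 15 % of the decoys still unassigned (else 8.0 Å); the max-neighbour
decoy becomes the centroid, its neighbourhood the cluster; members are
removed and the step repeats until K clusters exist or decoys run out
(fewer than K is an explicit error, mirroring the exclusion of proteins
whose decoy sets cannot support K candidates). All four constants live in
`ClusterConfig` and are serialised with every run; they are pragmatic
defaults, not values taken from any reference implementation. Clustering is hard (each decoy in at most
one cluster), the distance is RMSD rather than TM-score, and the centroid
is an actual decoy, never a mean structure. Candidate order is cluster size
descending, ties broken by lower centroid mean intra-cluster RMSD, then
lexicographic centroid id — fully deterministic and invariant to input
order.

External candidate tables (`rank  filename  cluster_size`) bypass the
clusterer. Such tables carry no membership, so members are assigned to the
nearest declared centroid by RMSD; intra-cluster features computed from an
external table are therefore approximate.

## Features and labels

The vector is [length | PSSM block | size | intra-RMSD | intra-TM |
inter-RMSD | inter-TM], total 6 + MAXN·M. MAXN defaults to 200 (longer
chains truncate to their first MAXN rows, shorter ones zero-pad); M is 20.
PSSM integers enter raw — tree ensembles are invariant to monotone feature
scaling, so no normalisation is applied. A singleton cluster contributes
(0, 1) as its intra-cluster statistics (the centroid is its own perfect
neighbour), avoiding missing values. Labels: the candidate with minimum
RMSD-to-native among those currently in play gets 1, everyone else 0; an
exact tie goes to the earlier-ranked (larger-cluster) candidate, which
keeps labelling deterministic and encodes the size prior.

## The cascade

K−1 binary forests for K positions — the last position needs no
classifier. Stage s is trained, per protein, on the candidates not yet
consumed by stages < s, where the *true* (label-derived) best candidate is
removed after each stage and labels are recomputed among the remainder;
class imbalance (1 positive to K−s negatives) is corrected per stage by
duplicating positives with replacement until parity, leaving the negative
multiset untouched. Forests are scikit-learn `RandomForestClassifier`
instances with `criterion="entropy"`, 100 trees, bootstrap bagging and √D
feature subsampling per split; per-stage seeds derive deterministically
from the run seed via `SeedSequence`. At prediction time each stage's
remaining candidate with the highest class-1 probability (fraction of trees
voting 1) takes the next position, ties going to the earlier-ranked
candidate. Probability argmax is used instead of hard 0/1 labels because a
hard rule is undefined when zero or several candidates are voted positive;
it reduces to the hard rule when exactly one candidate is confidently
positive. The output is always a permutation of the K candidates.

`entropy()` implements Shannon entropy −Σ Pᵢ log₂ Pᵢ (0·log 0 = 0) for any
class count, and splits are chosen to maximise information gain (parent
entropy minus weighted child entropy) — the conventional direction.

## Synthetic benchmark

The generator emulates the statistical structure the method assumes while
keeping ground truth exact:

* **Native**: a self-avoiding CA trace built by internal-coordinate (NeRF)
  placement from alternating helical (pseudo-angle 91°, pseudo-torsion 50°)
  and extended (123°, 195°) segments of 5–15 residues with 3° jitter; bond
  length 3.8 ± 0.01 Å, non-consecutive CAs ≥ 2.0 Å apart. Lengths are drawn
  uniformly from 40–120 residues.
* **Decoys**: native + i.i.d. per-coordinate Gaussian noise at one of five
  levels σ ∈ {0.5, 1.5, 3.0, 5.0, 8.0} Å, then a random rigid motion. The
  hidden σ of each decoy is recorded for test oracles; superposed
  RMSD-to-native concentrates near σ√3·c with a superposition shrinkage
  c < 1 that tests estimate by Monte Carlo rather than assume.
* **Level weights** (0.25, 0.30, 0.20, 0.15, 0.10): the most populated tier
  is the *second*-best one, so the largest cluster is the nearest-native
  candidate for only part of the proteins (measured 0.35–0.65 across
  seeds). This is the regime the method targets — cluster size informative
  but imperfect — and makes the learning task neither trivial nor
  impossible.
* **PSSM**: log-odds sharpened at the native residue (5–9 there, −6–1
  elsewhere). It exercises encoding, padding and truncation; it carries no
  ranking signal, deliberately, so recovery results measure the structural
  features.

What passing synthetic tests does *not* show: real decoy sets have
correlated, anisotropic errors, multiple conformational basins, and
energy-dependent cluster shapes; the PSSM of a real protein correlates with
fold class. Synthetic recovery therefore validates the machinery
(clustering, features, cascade, determinism), not biological performance.

## Parameter recovery experiment

`benchmark.run_recovery(seed)` generates 40 proteins × 60 decoys, clusters
to K = 5, builds features once, and evaluates the cascade with protein-level
5-fold cross-validation (folds assigned round-robin), so every protein is
scored by a cascade that never saw it. Reported: held-out first-position
accuracy (random baseline 1/K = 0.2), and the mean RMSD-to-native of the
re-ranked first model against (i) the random-order baseline — the
expectation over uniform orders, i.e. the mean candidate RMSD — and (ii)
the size-rank baseline (largest cluster first). Problem sizes were chosen
so one seed completes in about a minute on a single core; five seeds are
used for the headline numbers.

## Comparison protocol

Given per-protein first-model RMSDs before/after re-ranking: *better* ⇔
reranked < original − tol, *worse* ⇔ reranked > original + tol, *same*
otherwise, with tol = 0.01 Å inclusive — one unit in the last digit of a
two-decimal table, i.e. equality at display precision. The percent
improvement of the mean is computed from the means rounded at that same
display precision (the convention such tables use when quoting, e.g.,
"from 5.36 to 4.91 = 8.40 %"); full-precision means are reported alongside.
The bundled 43-protein reference table ships as TSV; two of its rows report
a first-model RMSD below the "best decoy" column, so that relation is not
enforced as a validation rule.

## Determinism

Every stochastic component (trace generation, decoy noise, rigid motions,
PSSM sampling, oversampling, per-tree randomness) derives from a single run
seed through `numpy.random.SeedSequence`; fixed config + seed reproduces
byte-identical benchmarks, archives and rankings. Tie-breaks are documented
and total (lexicographic ids, earlier rank) so no ordering depends on
floating-point happenstance beyond the stated tolerances.

## Known limitations

* TM-score for different-length chains (alignment-based Lₐ < Lₙ) is
  unsupported by design.
* The shrinking-scale constants are pragmatic defaults; real SPICKER uses
  its own scheme, so clusterings will differ in detail.
* Intra-cluster features from external candidate tables rely on
  nearest-centroid membership assignment.
* The cascade does not calibrate probabilities and is not a
  learning-to-rank model; each stage is an independent binary classifier,
  so stage probabilities are not comparable across positions.
* MAXN truncation keeps leading residues; C-terminal profile information of
  chains longer than MAXN is discarded.
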