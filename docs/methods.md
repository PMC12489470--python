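# Methods

## Model and procedure

The package models a doped reselection of a click-ligating DNAzyme.
The library is an 82-nt single strand: a fixed 21-nt 5′ primer-binding
site (PBS), a 40-nt catalytic domain synthesized with per-position doping,
and a fixed 21-nt 3′ PBS. Doping is per-position independent: each doped
position carries a non-reference base with probability equal to the
mutation rate (default 0.45), the replacement drawn uniformly from the
three alternatives. This is the standard doped-synthesis assumption; real
phosphoramidite doping can deviate slightly per coupling, which the
generator does not model.

Selection treats ligation as stochastic survival. A molecule with
ligation rate k (h⁻¹) incubated for t hours survives with probability
1 − e^(−kt); the realized survivor fraction is the round's ligation
percentage. Re-amplification between rounds is multinomial resampling to
the configured pool size, i.e. error-free PCR with no polymerase bias —
mutation therefore enters only through the initial doping. Two default
stringency schedules are provided: the 11-round de novo schedule
(8 h × 6, 4 h × 2, 2 h × 3) and the 7-round reselection schedule
(8 h × 4, then 6, 3, 1.5 h). Pool sizes are simulator molecule counts
(default 20 000 per round), a configurable stand-in for picomole-scale
pools; they control sampling noise, not chemistry.

The sequence→activity map of the real enzyme is unknown, so the simulator
uses a declared synthetic ground truth: an `ActivityModel` that assigns
k_max to sequences carrying the required base at every constrained
position and multiplies the rate by a penalty factor (default 0.2) per
violation. Its only purpose is to make conservation-profile recovery
testable: constrained positions must come back conserved, everything else
neutral.

## Pool processing

Reads are anchored by locating each PBS with a substitution-only
(Hamming) scan, leftmost placement first, allowing a configurable
mismatch budget (default 2 per PBS). The interior between the anchors is
kept only if its length equals the doped length, so reads with indels are
rejected (`wrong_length`) rather than aligned — the Variation Index needs
a gap-free 40-column alignment to a fixed-length reference. Reads whose
PBS cannot be placed are rejected as `no_anchor`. Rejects are tallied
data, not errors.

Families are built by greedy abundance-ordered centroid clustering: the
highest-count unassigned unique sequence (ties broken lexicographically)
seeds a family and absorbs every unassigned sequence within a Levenshtein
radius (default 7, ~15% of the 40-nt domain; distances via edlib's banded
aligner). The primary literature does not define "family"; this greedy
rule was chosen because it is deterministic, order-invariant given the
canonical count/lexicographic sort, and checkable against an exhaustive
re-implementation.

## Conservation profiling

At each doped position, N counts units matching the reference base and
N_t all units with a called base there (bases read as N are excluded from
both counts rather than treated as mismatches, which would bias VI
upward). VI = (1 − N/N_t)/rate; N_t = 0 yields a not-evaluable position,
never VI = 0. Classification against the neutral threshold (default 1) is
three-way — important (<), tolerant (>), boundary (exact tie, reported
separately. Exact ties essentially only occur in constructed inputs).
VI is not clamped; estimator noise can push it slightly above 1/rate
conceptually but not by construction, and values are reported as-is.

Counting units are configurable because published read totals are often
ambiguous between reads, unique sequences and families: `per-read`
(default) weights by read counts, `per-unique` gives every distinct
sequence weight 1, `per-family` uses family centroids weighted by family
totals. A "most populated" pre-filter can keep the families (or unique
sequences) covering a top fraction of reads (default 0.95 when enabled)
before counting. The secondary-structure element map (paired regions P,
loops L, junctions J) is user input consumed for reporting only; the
package ships a synthetic placeholder map matching its placeholder
reference and never predicts structure.

## Quantification

Gel metrics follow the standard densitometry definitions (see README);
inputs are assumed pre-quantified band intensities, with no background
subtraction. Kinetics fits minimize unweighted least squares of
Y(t) = Y_max(1 − e^(−k_obs t)) with box constraints k_obs ∈ (0, 10] h⁻¹,
Y_max ∈ (0, 100]%, via `scipy.optimize.least_squares` (TRF). The
single-exponential form is an interpretation: it is the standard
single-turnover ligation model consistent with reporting a (k_obs, Y_max)
pair. Initialization is multi-start — a log-spaced grid of five rate
candidates (10⁻³–10^0.5 h⁻¹) plus an earliest-slope estimate
y(t₁)/(Y_max⁰·t₁), with Y_max started at the maximum observed value; ties
between starts break by lowest residual sum of squares, then lowest
k_obs. An all-zero time course returns a flagged no-activity result (the
inactive-control behavior) instead of parameters. At least three distinct
positive timepoints are required.

## Randomness and determinism

Every generator takes one integer seed (or a NumPy `SeedSequence` /
`Generator`). Composite simulations split their seed with
`SeedSequence.spawn`, two child streams per round (resampling, survival)
plus one for the final re-amplification, so trajectories are reproducible
bit-for-bit and insensitive to refactoring within a round. Fixed seeds
reproduce byte-identical pools, time courses and CLI artifacts; the CLI
writes a run log with the seed and a SHA-256 hash of the effective
configuration.

## What the synthetic data does and does not show

The generators reproduce the statistical structure the analysis assumes:
doping at a known rate, activity-dependent survival, exponential
saturation kinetics with Gaussian noise, and back-solved gel intensities.
They do not emulate sequencing error profiles, quality scores, PCR
mutation or bias, chimeras, paired-end artifacts, or any chemistry of the
azide–alkyne reaction. Passing recovery tests therefore demonstrates that
the estimators are correct under the stated model, not that real pools
satisfy the model. Problem sizes used throughout (20 000-molecule pools,
200 replicate fits) were chosen as the smallest at which Monte-Carlo
error is comfortably below the effects being measured.

## Known limitations

- Lineage coalescence under strong selection inflates the variance of
  per-position VI in simulated final pools (few founding molecules carry
  the whole pool); the median over unconstrained positions is the stable
  neutrality summary, and the tests use it.
- Hamming-only PBS anchoring drops reads with PBS indels entirely.
- Greedy clustering is O(centroids × sequences) pairwise alignments;
  it is intended for enriched (post-selection) pools, not for clustering
  a fully random library at large radius.
- The shipped 82-nt reference and element map are synthetic placeholders;
  analyses of real data must supply the actual clone sequence and
  structure map through the configuration.
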