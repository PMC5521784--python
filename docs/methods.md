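# Methods

This note records the models, numerical choices and limitations behind
`anaerobenet`, at the level of detail a user needs to judge what the
results do and do not mean.

## Abundance tables and the differential rule

Input tables are taxa × time-point matrices of relative abundances
(fractions; the `--percent` flag divides by 100 at I/O). Internally
everything is a fraction; percentages appear only in reports. Mean
abundance per taxon divides the summed abundance by the number of samples
in which the taxon is present (not by the total number of samples), so a
sporadically observed taxon is characterized by its typical level when
present; a taxon absent everywhere gets mean 0. Abundance classes are HIGH
(> 1%), LOW (0.1%–1%, inclusive on both ends) and RARE (< 0.1%).

Fold changes between conditions are set to 0 — "ignored" — whenever either
condition reports a zero, since a ratio against a missing observation is
meaningless in either direction. The differential rule splits the series
at `t_cut` (default 7 of 10 samples) and requires at least `early_min = 4`
differential points before the cut *and* `late_min = 2` after it; the
boundary comparisons are inclusive (a fold of exactly 2 counts). Both
reference directions are evaluated; a taxon qualifying in both directions
is reported as CONFLICT rather than silently resolved, because on sane
data that cannot happen.

Shannon diversity uses natural logarithms. Rarefaction is computed from
the exact hypergeometric expectation
`E[S(d)] = Σ_i (1 − C(T−c_i, d)/C(T, d))` rather than by resampling, so
curves are deterministic; the binomial ratios are evaluated in log space.

## gLV inference

The discretization is exponential-Euler / log-ratio gradient matching:
per-capita log growth over each transition, divided by the day spacing,
regressed on the community state at the transition's left endpoint. This
form was chosen over an additive Euler step because it keeps simulated
abundances positive and makes the paired simulator exactly invertible:
with no noise and no compositional closure, inference recovers the
generating `(r, M)` to machine precision (the suite asserts 1e-6
relative). Rescaling all day labels by a constant divides all inferred
rates and effects by that constant, as the units (per day) require.

Zeros are replaced by half the smallest nonzero value in the table before
taking logs — the standard compositional pseudocount choice; it affects
both responses and predictors.

The per-target regression is NIPALS PLS1: predictors centered and scaled
to unit variance (ddof 1; constant columns left unscaled), response
centered only, deterministic deflation, coefficients back-transformed to
the original scale. PLS1 was preferred over SIMPLS/PLS2 as the simplest
deterministic variant; at full component count it coincides with ordinary
least squares, which the tests verify against a normal-equations oracle
and against scikit-learn's `PLSRegression` as an independent
implementation. Component extraction stops early when the response
residual is numerically exhausted, so a constant response yields all-zero
coefficients with the intercept at the response mean.

The component count per target is selected by leave-one-out
cross-validation over 1..min(n−2, p), choosing the smallest count whose
PRESS is within a relative 1e-8 of the minimum (ties break downward, and
flat PRESS profiles are not chased through float noise). With fewer than
three transitions the selector falls back to one component. The whole
coefficient path is computed in a single deflation pass per fold, which
keeps the resampling filter affordable. A fixed count can be passed
instead (`n_components=3` is used in the large determinism checks, where
selection stability across 100 resampled fits is not the point).

## Consensus filter

For each of `n_sim` runs, `n_nbrp_sample` NBRP taxa are drawn uniformly
without replacement (one `numpy` Generator seeded once per invocation;
the seed is recorded in the output), the combined community is re-fitted,
and per ordered BRP pair the fraction `P` of runs with a positive effect
is accumulated. Classification follows the four-condition scheme:
activation needs `P ≥ p_threshold` *and* a positive raw-network strength;
repression needs `P ≤ 1 − p_threshold` *and* a negative raw strength. A
strength of exactly 0 never yields an edge, and intermediate `P`
(between `1−thr` and `thr`) is always non-confident — the only
edge-producing cases are the two agreement conditions, so raising the
threshold can only remove edges (asserted as a property). Study defaults
are `n_sim = 1000`, `n_nbrp_sample = 120`, `p_threshold = 0.95`; tests
and the acceptance script run `n_sim` at 50–100, which changes only the
resolution of `P`, not the mechanics.

## Topology

Edges carry direction (source influences target), so in-degree and
betweenness are computed on the directed graph; betweenness is the raw
(unnormalized) Brandes pair count with fractional credit for tied
shortest paths, via networkx, and is verified against an exhaustive
Floyd–Warshall path-enumeration oracle on small graphs. Eigenvector
centrality is computed on the *symmetrized* graph — importance by
association does not depend on the direction of an effect, and this
matches the convention of the usual network-visualization tools — by
power iteration, rescaled so the top node scores 1; a dense eigensolver
serves as the test oracle. Nodes outside the dominant connected component
may legitimately score ≈ 0; a graph with nodes but no edges returns
uniform centrality 1. "Strongest" edges are ranked by |strength| with
lexicographic (source, target) tie-breaks, so top-k selection is
deterministic and idempotent. The influential-taxon report flags nodes
with out-degree ≤ 1 (configurable) as "influenced but rarely
influencing".

## Concordance

Species-pair complementarity/competition indices are averaged into
ordered family pairs. Network edges join the index table on
(source, target); the indices are directional, and a symmetrized mode is
deliberately not the default. Strengths > 0 are regressed on
complementarity and strengths < 0 on competition by ordinary least
squares; R² is reported with the F-test p-value on (1, n−2) degrees of
freedom (identical to the two-sided t-test on the slope). R² is invariant
to which variable is regressed on which and to affine rescaling, so the
reported value does not depend on that convention; the slope is reported
for strength-on-index. Degenerate inputs (fewer than 3 records, constant
index) raise rather than returning NaN.

## Synthetic data generator

The generator emulates the *shape* of a two-reactor 16S study: 173
family-level taxa sampled at days 18, 24, 30, 34, 38, 42, 46, 50, 58, 60;
sparse random interactions (each ordered pair active with probability
0.10, effects N(0, 1)); self-limitation −30 on the diagonal; growth rates
uniform on (0, 0.3) per day; multiplicative lognormal noise with σ = 0.05;
compositional closure. With closure on, the state is renormalized to the
simplex after every step; self-limitation then penalizes whichever taxon
is currently abundant, which keeps ~170 taxa coexisting with Shannon
diversity ≈ 4.8 and a realistic spread of high (> 1%), low and rare
(< 0.1%) families. These defaults were fixed once on stability and
diversity grounds; an earlier candidate with signed growth rates and weak
self-limitation collapsed to a single dominant taxon over the 42-day
span and was rejected for that reason.

Planted differential taxa are scaled by the effect fold (default 3) at
every time point *before* closure, and the planted taxa are chosen among
the lowest-abundance ones so the compositional renormalization neither
erases the planted folds nor fabricates compensating folds elsewhere;
with a large planted mass closure would do both, which the tests document
by asserting the non-planted folds stay inside (0.5, 2).

The recovery and consensus tests use a smaller, deliberately informative
family of systems (5–12 taxa, denser and stronger interactions, no
closure, 12 samples at 2-day spacing): gradient-matching inference is
only as good as the transient information in the data, and near-
equilibrium trajectories identify nothing. Replicate draws whose
absolute-unit trajectories blow up (positive-feedback loops; the
simulator raises rather than returning Inf) are rejected and redrawn.
Under these conditions the noise-free round trip is exact, the median
sign accuracy at σ = 0.05 stays above 0.75, and recovery RMSE is
monotone in σ over {0, 0.05, 0.2}.

What the generator does *not* emulate: sequencing counts and their
sampling noise, read errors, chimeras, copy-number effects, taxonomic
misassignment, or any resemblance between the random interaction matrix
and the real digester community. Passing tests therefore demonstrate
correctness of the inference chain under its own model assumptions, not
accuracy on real reactors.

## Pipeline

`run_all` executes differential → per-condition (raw network → consensus
→ confident network → top-k topology) → concordance (mesophilic
condition, on the top-k edges), writing TSVs, GraphML/GEXF and a JSON
manifest echoing every threshold and seed actually used plus per-sign
edge counts; reruns with the same seed are byte-identical. Any stage
failure aborts with the stage name. The resampling loop is serial by
design — results must not depend on scheduling.

## Known limitations

- Nine transitions cannot identify 172 predictors per target; PLS gives a
  useful low-rank projection, and the resampling filter screens sign
  stability, but inferred strengths remain shrunken, scale-compressed
  estimates. The concordance regressions should be read accordingly.
- Compositional closure distorts gradients (a common per-transition
  offset that varies over transitions); inference on closed data is
  approximate even without noise.
- The consensus probability is a sign-stability score under NBRP
  resampling, not a posterior edge probability; no multiplicity control
  is applied over the 1260 candidate pairs.
- Trophic indices cover only taxa present in the underlying metabolic
  model database; unmatched edges are dropped (and counted) at the join.
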