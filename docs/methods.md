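# Methods

This package reimplements, as a tested pipeline, a differential network
analysis of 16 circulating miRNAs (14 cellular, 2 KSHV viral) measured by
qRT-PCR in the plasma of four patient groups — septic patients (n=99),
healthy controls (n=53), pre-surgery (n=19) and post-surgery (n=11) — and the
mechanistic competition model proposed to explain why the sepsis network
loses edges ("miRNA sponging").  Abundances are on the 2^-ΔCt scale,
normalized against a cel-miR-39-3p spike-in.  Only the published per-group
means and standard deviations are publicly available; all sample-level data
in this repository are synthetic.

## Synthetic expression generator

**Model.** Gaussian copula with log-normal marginals.  For each miRNA the
published (mean, sd) is moment-matched to a log-normal via
σ² = ln(1 + sd²/mean²), μ = ln(mean) − σ²/2.  A latent correlation matrix R
couples the standard-normal scores; observed values are exp(μ + σz).

**Why log-normal.** The published SDs frequently exceed the means several
fold (e.g. 0.141 ± 0.669) on a strictly positive scale — incompatible with a
normal marginal; a two-parameter positive, right-skewed family matched by
moments is the minimal faithful choice.

**Dependence scale.** R is specified on the latent (log) scale.  Pearson
correlation of the raw 2^-ΔCt values is attenuated relative to the latent r
by the heavy-tailed marginals (for two equal σ: r_raw = (e^{rσ²}−1)/(e^{σ²}−1)
< r), so network construction on synthetic data uses the log view, where the
sample correlation estimates the latent r directly.  Both views are exposed.

**Ground-truth structure.** The default structure encodes the published
differential finding: the six C-group miRNAs (miR-21, miR-23, miR-26a,
miR-26b, miR-93, miR-223) and five S-group miRNAs (miR-16, miR-29a, miR-146,
miR-155, miR-182) form one equicorrelated block (default latent r = 0.95);
the two viral miRNAs and the remaining nodes are independent, matching their
isolation in every published network.  Sponging is emulated by
`inject_sponge`, which shrinks every latent correlation incident to the
sponged set to sign(r)·min(|r|, residual) (default residual 0.1) — a sponge
transcript sequesters the free pool of those miRNAs, destroying their
covariation with everything else.  Positive semi-definiteness is restored,
when an edit breaks it, by eigenvalue clipping at zero followed by diagonal
renormalization; repairs are logged.

**What the generator does not emulate:** qRT-PCR measurement noise and
censoring at high Ct, patient covariates, within-group heterogeneity
(mixtures), and any raw-scale dependence beyond what the copula induces.
Passing tests therefore demonstrate that the pipeline recovers a planted
sponging signal of realistic marginal shape and cohort size — not that the
published networks themselves would be recovered from real plasma data.

**Marginal-recovery tolerance.** The sample SD of a log-normal with σ² ≈ 2
(the heaviest published cells) has relative standard error
√((κ−1)/4n) ≈ 12% even at n = 50,000 (κ = kurtosis ≈ e^{4σ²}).  The
convergence test therefore holds each cell to five standard errors of its
own estimator (floor 3%), and additionally checks the log-scale mean and SD
— which identify (μ, σ) directly — to five (fast-converging) standard
errors.

## Network construction

All three methods take a samples × miRNAs table and return an undirected
network on all 16 nodes; isolated nodes are always retained and serialized,
because isolation is the finding of interest.

**Correlation method.** Pairwise Pearson r; edge wherever r ≥ 0.8.  The
threshold is deliberately high (typical co-expression studies use 0.3–0.5)
to keep the 16-node network sparse and interpretable.  Only positive
correlations create edges by default (the published threshold is "+0.8");
an absolute-value mode exists.  Ties at exactly the threshold are included.
Constant columns get r = 0 with a warning rather than an error.  Default
scale is raw for published-data fidelity; the synthetic pipeline uses the
log view (above).

**Cluster method.** The miRNAs are clustered agglomeratively on their
profiles across subjects (SPSS-style defaults: between-groups/average
linkage on squared Euclidean distance), the tree is cut into k = 4 clusters
(the cut the source analysis retained; 2 and 6 are available), and every
within-cluster pair becomes an edge.  Profiles are z-scored per miRNA by
default: the 16 miRNAs span seven orders of magnitude, so unstandardized
distances would be dominated by miR-16 alone.  Each edge carries the
cophenetic distance between its endpoints (the merge height at which they
first join; the raw pairwise dissimilarity is available as an alternative)
and a strength bin 1–6.  The six bins' five cut points default to the
six-quantile points of the network's own edge distances and are recorded on
the network for reproducibility, since the published threshold table is not
available.  "Total distance" is the sum of edge distances — the published
totals (control 1595 < sepsis 7370 with *fewer* sepsis edges) are only
consistent with distances, not edge counts, dominating this scalar.

**Bayesian method.** Expression is quantile-discretized per miRNA into 3
equal-count levels (ties at a cut fall in the lower bin); DAG structures are
scored with the BDe marginal likelihood (likelihood-equivalent Dirichlet
prior, equivalent sample size 1, so Markov-equivalent DAGs score equally and
sparsity is implicitly rewarded); the space is searched by Metropolis
simulated annealing over single-edge changes (add/delete/reverse, parent cap
4, acyclicity enforced on every proposal) from an empty initial graph, with
geometric cooling (T₀ = 1, factor 0.999 every 100 moves, 20,000 iterations
by default) and single-best tracking.  Proposals are drawn uniformly over
(ordered pair, move-slot) cells, so accepted proposals are uniform over the
legal neighborhood; draws that would break acyclicity or the parent cap are
discarded as null iterations.  The source describes its annealing
acceptance as "higher score accepted with a probability", which inverts the
standard convention; standard Metropolis (better always, worse with
probability e^{Δ/T}) is implemented.  Search knobs beyond the metric,
proposer, discretization and single-best tracking are not published; the
defaults above are recorded in every run manifest.  Edge counts for
comparisons use the undirected skeleton, the direction being kept as an edge
attribute.

## Comparison statistics

Percentage change is 100·|e_A − e_B| / max(e_A, e_B) — the only denominator
convention consistent with all five published percentages (59.62, 28.79,
23.33, 82.14, 31.03).  Edge counts are tested with a two-sided Fisher exact
test on [[e_A, M−e_A], [e_B, M−e_B]], M = C(n,2) possible edges (n = 16 for
the correlation/Bayesian networks, 15 for the cluster networks, which the
source built out of 15 miRNAs).  This convention reproduces the published
P-values exactly (0.0125, 0.3505, 0.1999 and P < 0.0001 for 52 vs 21); the
one exception is the pre/post-surgery cluster pair (49 vs 37), published as
P = 0.0763, which this convention puts at 0.1224 — the published value
corresponds to M = C(13,2) = 78, suggesting those two networks effectively
had 13 nodes.  Distance totals are compared with a Yates-corrected 1-df
goodness-of-fit chi-square against equal expectation, as in the source;
applying a count test to continuous distance totals makes this a
descriptive index rather than a calibrated P-value, and it is flagged as
such in reports.

The differential network partitions edges into kept / lost / gained, and
nodes into the **C group** — the maximum clique of the graph of kept edges,
computed exactly (trivial at n = 16; the source identified it by
inspection) with ties broken by size then lexicographic order — and the
**S group** — nodes with degree ≥ 4 in the first condition and degree 0 in
the second (the degree floor is configurable).

## The competition ("sponging") model

Two miRNA species X, Y (predators) and up to two mRNA targets A, B (preys),
all produced at a shared constant rate ρ and removed pairwise by mass
action:

    dx/dt = ρ − α₁₁xa − α₁₂xb        da/dt = ρ − α₁₁xa − α₂₁ya
    dy/dt = ρ − α₂₁ya − α₂₂yb        db/dt = ρ − α₁₂xb − α₂₂yb

with ρ = 0.002, x₀ = 0.25, y₀ = 0.35, a₀ = 0.3, b₀ = 0.2 — illustrative
values, not fitted to anything.  Scenarios: S1 α = (0.5, 0.5) one prey;
S2 α = (0.75, 0.25) one prey; S3 two preys, α = [[0.9, 0.5], [0.9, 0.1]]
(the second prey is the sponge: high affinity for X, low for Y).  One-prey
scenarios set b₀ = 0 with zero B-column rates, which keeps a single 4-state
integrator; B is still produced at ρ, so b(t) = ρt exactly there (a useful
closed-form check).  Integration uses LSODA with rtol 1e-8 / atol 1e-10 on
a 1001-point grid over t ∈ [0, 1000] (the source shows but does not number
its time axis); the model is positivity-preserving, and undershoots beyond
100·atol abort with an error.  The S1 rate 0.5 is a choice (the source
states equality of the two rates but not their value).

**Correlation readouts.** How a deterministic trajectory pair maps onto the
"linear correlation between nodes" of a patient-population network is not
stated in the source; two readouts are implemented and both are reported:
Pearson r between x(t) and y(t) along the trajectory (default, optional
time window), and Pearson r between endpoint x and endpoint y across
replicate systems whose initial concentrations are jittered log-normally
(each replicate standing for one subject).

**Model-vs-figure disagreement.** Under these equations every predator's
loss terms vanish as its preys are depleted, after which all predators grow
at rate ≈ ρ·(its share); in S1 and S2 both predators end up on a common
production ramp, and their trajectory correlation is ≥ 0.999 at the default
horizon; only S3, which reaches a genuine steady state, dips (r = 0.896 —
still above the 0.8 threshold).  The ensemble readout orders the scenarios
differently but also never pushes S2/S3 below 0.8 at these parameters.  The
source's narrative for S2/S3 (the high-rate predator "increases", the
low-rate one "decreases") is only possible if consumption *benefits* the
predator, i.e. a different model from the printed equations, and its
disconnected network panels for S2/S3 are accordingly not reproducible from
the equations as printed.  The package implements the printed equations,
reports both readouts, and the acceptance test for the S2/S3 disconnection
claim is left failing by design rather than tuned into agreement.  The S1
claim (connected at 0.8) and all quantitative integration checks hold.

## Problem sizes and determinism

Every stochastic stage takes an explicit seed (NumPy `default_rng`);
identical configuration and seed reproduce outputs bit-for-bit, and each
pipeline run writes a manifest (config hash, seed, versions, edge counts)
from which it can be regenerated.  Test-suite problem sizes: marginal
convergence at n = 50,000 draws; oracle-equivalence suites at ≥ 200 random
instances per operation on ≤ 16 nodes; annealing recovery on 20 seeded
3-node datasets of 400–500 samples against exhaustive 25-DAG enumeration;
the fixed-step RK4 cross-check at dt = 1e-4 (agreement within 1e-6); the
end-to-end sponging emulation at the study cohort sizes (53/99) over 20
seeded replicates.

## Known limitations

* The cluster method's published threshold table and the exact SPSS options
  are unavailable; the defaults above are explicit choices, configurable.
* The Fisher/chi-square contingency constructions are reverse-engineered
  conventions (validated against the published P-values), not published
  formulas.
* The sponging emulation plants a block-structured latent correlation; real
  co-expression is not block-constant, so recovery rates here bound the
  idealized, not the clinical, case.
* Target-prediction and pathway-enrichment stages of the original analysis
  depend on external databases and are out of scope.
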