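# Methods

`profilenet` implements the full inference chain used in person-centred
psychometric network studies of questionnaire data: quality screening →
latent profile analysis with formal class enumeration → per-class Ising
networks → centrality and bootstrap stability → simulated node
interventions → a Gaussian-graphical-model robustness check.  The package
is written around the SE-NNC instrument (27 five-point Likert items on
nurses' self-efficacy in nutritional care for older adults, in three
dimensions: knowledge NCK, assessment/evidence utilization AEU, care
delivery CD), but every stage accepts arbitrary item sets.

## Synthetic data generator

Real survey data of this kind are rarely deposited, so the generator is a
first-class component: it produces data with exactly the structure the
analysis chain assumes, which makes every downstream stage testable against
known truth.

Each respondent belongs to one of several latent classes.  Class k has a
27-vector of latent item means, and latent responses are multivariate
normal with common within-class standard deviation (default 0.45) and a
block-exchangeable correlation: 0.3 between items of the same dimension,
0.15 across dimensions — items within a dimension hang together more, which
is what produces dimension-clustered networks downstream.  Latent values
are discretized at fixed cut points (1.5, 2.5, 3.5, 4.5) and clipped to
[1, 5]; cutting at integer midpoints preserves the interpretation of the
class profile as the approximate conditional item mean.

The default configuration is a three-class population of 510 respondents
with class shares 81/510, 251/510 and 178/510 (≈ 0.16 / 0.49 / 0.35) and
low / moderate / high profiles whose item means sit near 2.0, 3.05 and 4.3.
Completion times are normal (mean 420 s, SD 120 s, floored at 30 s) so the
too-fast screening rule has realistic work to do.  What the generator does
*not* emulate: item-specific variances, skewed or bimodal within-class
response styles, acquiescence and social-desirability artifacts, missing
data (the instrument is administered with all items mandatory), and
demographic structure beyond optional categorical columns.  Passing tests
therefore demonstrate that the estimators recover the structure this model
encodes, not that any particular real population has that structure.

An exact Ising sampler (full enumeration of all 2^P states, P ≤ 15) serves
as the oracle for the network stages; the Gibbs sampler used at scale is
tested against it in total variation.

## Quality screening

Four rules, applied in a fixed precedence (too-fast → logic error →
response regularity → duplicate key), each excluded row counted once under
the first rule it violates, so the itemized counts always sum to the total
excluded.  Completion under 180 s is "too fast" by default.  "Logical
errors" are user-supplied predicates (none by default; such checks are
instrument-specific).  "Regularity" means zero response variance or a run
of at least 24 identical consecutive responses out of 27 — straight-lining
— the threshold is configurable because genuinely consistent responders
exist.  Reliability is Cronbach's α = k/(k−1)·(1 − Σ var_i / var_total)
with sample variances; descriptives use n−1 SDs throughout, the reporting
convention for questionnaires.  The network sample-size rule is
P + P(P−1)/2 (thresholds plus pairwise couplings), i.e. 378 cases for 27
nodes.

## Latent profile analysis

The LPA model is a Gaussian mixture over the item vectors with diagonal,
class-invariant covariance (the classic LPA specification; class-varying
diagonal variances are available behind a flag and are cross-checked
against scikit-learn's diagonal Gaussian mixture).  Parameters are counted
as (K−1) + K·27 + 27.  EM runs from one k-means start plus n_starts−1
random starts (default 50), keeps the best likelihood, and asserts
monotonicity of the log-likelihood at every iteration; convergence is
Δℓ < 1e−6, and per-item variances are floored at 1e−4 of the pooled
variance (the shared-variance structure already rules out degenerate
spikes).  Components are re-ordered by profile mean total (low → high) at
fit time so class labels are stable across runs.

Fit indices: AIC = −2ℓ + 2k, BIC = −2ℓ + k·ln n, aBIC = −2ℓ + k·ln((n+2)/24),
and classification entropy E = 1 − Σ −p·ln p / (n ln K) (undefined at K=1).

Two K-vs-(K−1) tests are provided.  The **BLRT** is a parametric bootstrap:
simulate B datasets from the fitted (K−1)-solution, refit both class counts
on each, p = (1 + #{bootstrap LR ≥ observed}) / (B_effective + 1).  Its
measured type-I error at the package's simulation design (n=100, four
items, B=99, 200 replicates) is ≈ 0.03–0.05, consistent with its finite-B
validity guarantee.  The **LMR** test shrinks 2Δℓ by the adjustment factor
1 + 1/((3K−1+d)·ln n) and refers it to χ² with **2d** degrees of freedom,
where d is the parameter difference.  The exact null law is a weighted
chi-square mixture, heavier than χ²(d) because the mixing weight sits on
the boundary; a χ²(d) reference was measurably liberal (null rejection
≈ 0.20 at nominal 0.05), while 2d keeps the test slightly conservative
(0.003–0.010 across the (n, P) combinations checked).  The LMR p-value is
therefore advisory; the BLRT is authoritative when they disagree.

**Class enumeration** fits K = 1..K_max and recommends a class count by
walking K upward and accepting a further class only while (a) LMR and BLRT
are both significant at 0.05 against K−1, (b) no modal class is smaller
than 13% of the sample (small classes ruin interpretability), and (c)
entropy does not drop more than 0.02 below the last accepted solution.
Rule (c) exists because with discretized Likert indicators the bootstrap
LRT stays significant long past the interpretable solution (the mixture
genuinely fits the non-Gaussian within-class shape better with more
components); an arbitrary split of one true class leaves assignment
uncertain between the two halves, which shows up as a marked entropy
collapse (≈ 0.99 → 0.94 in the package's reference conditions), whereas a
real additional class does not.  The recommendation is advisory — the
enumeration table carries everything an analyst needs to decide otherwise.

Label-recovery evaluation aligns fitted to generating classes by Hungarian
assignment on the confusion matrix (mixture labels are only identified up
to permutation; the low→high ordering makes alignment trivial in practice).

## Ising networks (eLASSO)

Likert items are dichotomized before network estimation (the Ising model is
a binary model).  The default cut maps responses ≥ 4 — the "confident" /
"completely confident" end — to 1; a per-item median split
(strictly-greater convention) is available as a sensitivity analysis.
Columns that become constant are excluded from the network and recorded;
this happens routinely in extreme classes (e.g. nearly nobody in a
low-self-efficacy class answers 4 or 5), and is information, not an error.

Estimation is eLASSO: for each node an L1-penalized logistic regression on
all remaining nodes, over a 100-point log-spaced penalty path from the
smallest λ giving the empty model down to 0.01·λ_max, warm-started; per
node the path model minimizing EBIC = −2ℓ + J·ln n + 2γ·J·ln(P−1) is kept
(J = selected neighbours, γ = 0.25 by default).  Directed estimates are
combined by the AND rule (edge present only when both directions select
it; OR available), with the edge weight the mean of the two coefficients
and τ the selected model's intercept.  The model lives on {0,1}, matching
the nodewise-logistic parameterization.

The penalized solver is written in-package (numba-compiled IRLS coordinate
descent with an exact sign-iterated linear solve on the active set): the
case-dropping bootstrap refits networks thousands of times, and a solver
with warm-started paths is what makes that tractable.  Its solutions agree
with scikit-learn's saga L1 logistic regression to ~1e−9 at matched
penalties (tested).  Apparent separation (a coefficient exceeding 25)
triggers one ridge-stabilised refit (ℓ2 = 1e−4) of the whole path, flagged
in the node metadata.  The coefficient-change tolerance is 1e−5 per
reweighting cycle.

## Centrality and stability

Strength Σ|β_ij|, expected influence Σβ_ij, and closeness/betweenness on
the graph of nonzero edges with distance 1/|β|.  Closeness is harmonic
(mean inverse distance), which stays defined on the disconnected networks
that sparse per-class estimation produces.  Indices are also reported as
z-scores across nodes (n−1 SD); an index with no variance across nodes gets
z = 0, and a fully empty network is flagged degenerate with z undefined.

Edge precision: nonparametric bootstrap (resample rows, refit eLASSO,
percentile 2.5/97.5 CIs; default B=1000).  Bootstrap samples that make a
column constant are redrawn and counted.  Centrality stability: the
case-dropping bootstrap spreads B iterations (default 1000) evenly over
drop fractions 0.05–0.75; an iteration succeeds when the subsample
centrality correlates ≥ 0.7 (Pearson) with the full-sample values, and the
CS coefficient is the largest fraction up to which every smaller fraction
keeps a ≥ 95% success rate (degenerate subsample networks count as
failures).  The 0.7/0.95 internals and the 0.25 ("acceptable") / 0.5
("strong") interpretation thresholds follow the established convention for
cross-sectional psychological networks.

## Simulated node interventions

On a fitted network, each node j in turn has its threshold shifted by
±c·SD(τ̂) (c = 2 by default; the shift falls back to an absolute c when the
thresholds have no spread, flagged), responses are re-simulated, and the
node is scored by Δ_j, the change in the expected network total score —
the mean number of active binary items per simulated person.  A positive
shift is "simulated enhancing", a negative one "simulated weakening"; the
largest |Δ| identifies the candidate intervention target per direction
(ties resolved to the first node and flagged).  The total is explicitly a
network-derived quantity on the dichotomized items, not the raw Likert sum.

Sampling is sequential-scan Gibbs with independent person-chains (burn-in
100 sweeps, thinning 1 by default), validated in total variation against
exact enumeration.  Baseline and every perturbed run reuse one seed stream
(common random numbers), so Δ estimates are differences of strongly
positively correlated averages — the independent-samples standard error
used in the tests is therefore conservative.  With no couplings Δ_j has
the closed form logistic(τ_j + c·SD) − logistic(τ_j), which the simulation
matches within Monte-Carlo error; with all-positive couplings, raising
every threshold can only raise the expected total (checked exactly by
enumeration), and perturbing a well-connected hub moves the total more
than perturbing an isolated node.

The iteration counts are tunable; analyses in this package's examples use
100–1000 recorded sweeps of n-person chains, recorded in each result's
spec echo.

## GGM robustness check

Because dichotomization can reshape connections, a Gaussian graphical
model is also fitted to the raw item scores treated as continuous:
graphical lasso on the Pearson correlation matrix over a 100-point log
penalty path, selecting by EBIC = −2ℓ + E·ln n + 4γ·E·ln P (γ = 0.5,
E = nonzero pairs), with partial correlations ρ_ij = −κ_ij/√(κ_ii·κ_jj)
from the selected precision matrix κ.  After selection, entries with
|ρ| below the detection bound √(ln(P(P−1)/2)/n) are set to zero: the
glasso solution at the EBIC-optimal penalty retains a scatter of tiny
partial correlations (≈ 0.005–0.02 at n = 5000) that are not
distinguishable from noise at the given sample size, and the bound —
standard practice for EBIC-glasso networks — removes exactly those.  The
cross-model check reports top-k centrality overlap and per-node rank
shifts between the Ising and GGM networks.

## Pipeline

`run_pipeline` executes the chain from a single declarative config with one
master seed: generate or load → QC → descriptives → enumeration → per-class
and pooled networks → centrality (optionally edge bootstrap and CS) → NIRA
in both directions → GGM on the pooled sample.  Per-class networks whose
class n falls below the P + P(P−1)/2 rule are fitted anyway but stamped
"underpowered"; classes too small or too extreme to support estimation are
skipped with the reason recorded.  The GGM stage is optional and its
failure does not abort the run.  Every run writes a manifest (config echo,
per-stage seeds and wall times, SHA-256 of every output file); rerunning
the same config reproduces identical checksums.

## Numerical choices and limitations

- EM: absolute Δℓ tolerance 1e−6, max 1000 iterations, variance floor
  1e−4 × pooled variance; k-means initialisation uses a single restart
  (randomized restarts carry the exploration burden).
- Penalized logistic: coefficient tolerance 1e−5, separation cap 25,
  ridge fallback 1e−4.
- BLRT inside enumeration uses reduced starts (max(3, n_starts/10)) per
  bootstrap refit; replicates with a persistently negative LR are dropped
  and counted.
- Tests and the acceptance script run the simulation suites at reduced
  sizes (e.g. 6–10-node networks, B=250 case-dropping iterations, 39–99
  BLRT replicates); these sizes are the package's chosen reference designs
  and are recorded alongside each result.
- The LMR p-value is an approximation by construction; treat it as
  advisory screening, not inference.
- CS values are grid-resolved to 0.05 and depend on B; with few iterations
  per drop fraction the 95% criterion is coarse.
- The NIRA ranking is a property of the fitted Ising model, not causal
  evidence about respondents; it inherits every limitation of the
  dichotomization and of cross-sectional estimation.
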