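# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic-data generators do and do not emulate,
and the fixture scales the test suite runs at.

## Trees, ages and units

All branch lengths are in Myr; node ages run backward from the present
(tips at 0, crown at the tree height), and all rates are events/lineage/
Myr.  A tree is treated as ultrametric when its tip depths agree to
1e-8 × height — dated trees are ultrametric only to numerical precision —
and time-dependent likelihoods reject anything worse, while signal and PD
metrics accept non-ultrametric trees.  Polytomies are preserved by the
newick reader, accepted by PD metrics, and rejected by every likelihood
that assumes a binary tree (BiSSE, birth–death, OU); soft polytomies are
not resolved automatically because any resolution would silently change
the likelihood.  The simmap dialect stores per-branch regime segments in
curly braces, listed root-to-tip; segment durations define the branch
length and must sum to it within 1e-8 relative.

## Diversity extrapolation and trait coding

Chao1 uses the classical form S_obs + f1²/(2 f2) and switches to the
bias-corrected S_obs + f1(f1−1)/(2(f2+1)) when no doubletons exist (the
result carries a flag).  The two-step global estimate multiplies the
described-species count by the reference region's Chao1/S_obs ratio and
adds newly delimited species; state-specific sampling fractions partition
the total by the reference region's state ratio and are clipped into
(0, 1] with a warning.

The conservative depth range per species is min over stations of the
station *maximum* and max over stations of the station *minimum*;
constant-depth stations enter both sides.  A single broad dredge can
invert the pair, in which case the ordered interval is returned with a
"wide-station" flag rather than an error, since single-station species
are real.  Depth is binarized on the species *minimum* depth with an
inclusive ≤ 100 m rule ("found above 100 m" read as the shallowest
certain occurrence); the threshold and the choice of anchor are
configurable because the coding convention is a genuine judgment call.
Shell size ≤ 25 mm codes "small" (large = strictly exceeding 25 mm).
Protoconchs with ≥ 3 whorls are multispiral (planktotrophic), ≤ 2.25
paucispiral (lecithotrophic); the intermediate 2.5-whorl morphology is
resolved by the nucleus-size flag when recorded and otherwise deferred
to manual examination rather than guessed.

## BiSSE

The likelihood integrates the standard coupled equations for E_i (no
sampled descendants) and D_i (observed subclade) tipward-to-rootward,
with tip conditions E_i(0) = 1 − f_i, D_i(0) = f_i at the observed state,
D_left·D_right·λ_i at nodes, FitzJohn relative-D root weighting and
crown-survival conditioning (both switchable to flat/fixed weights).
Because the tree is ultrametric and E does not depend on the branch, E is
integrated once as a function of age; D is then a linear 2-component
system shared by all branches and advanced for every active branch
simultaneously between successive node ages by fixed-substep RK4, with
per-branch log-rescaling.  The substep is the smaller of (root age)/1000
and 0.4/(max total event rate) — the second bound is the RK4 stability
requirement, without which very high transition rates (explored by the
optimizer) produce spuriously high likelihoods.  An independent
per-branch RK4 integrator of the full 4-component system at step 1e-4
serves as the test oracle.

Fitting is multi-start Nelder–Mead in log-rate space with box bounds
[1e-8, 1e3]; constraints are name→name equalities or fixed values, and
the shipped scenario lattice covers the full model, each single equality,
the state-independent null, and irreversible (q₁₀ = 0) variants.  Model
choice applies ΔAIC > 2 together with Akaike weight > 0.5; anything less
decisive is reported "ambiguous" with the full table.

## Time-varying birth–death

Rates are r(t) = r₀ e^{a·t} with t the age (r₀ the present-day rate);
the exponent is bounded at |a| ≤ 1 /Myr because joint λ,μ blow-up toward
the root is a known likelihood ridge with no biological meaning.  The
likelihood solves one auxiliary ODE for (E, G), where
G(t) = ∫₀ᵗ (λ+μ−2λE), and assembles branch factors e^{−ΔG}, node factors
λ(x_k), tip factors f, crown-survival conditioning 1/(1−E(T))², with the
root's λ factor removed.  Constant-rate inputs switch automatically to
the classical closed forms (p₀/p₁), which are algebraically identical to
the ODE path — the two routes agreeing to 1e-6 is a standing test.
Conditioning is on the crown (both root children surviving); AICc uses
n = number of tips.  Nesting violations after fitting trigger a restart
of the super-model from the sub-model's embedded optimum.

## Signal and phylogenetic diversity

Pagel's λ rescales only the off-diagonal of the phylogenetic covariance;
σ² and the root mean are profiled analytically by GLS and λ is optimized
on [0, 1] by bounded scalar search (tolerance 1e-8), with the endpoints
checked explicitly so the reported optimum never falls below λ = 0 or 1.
The D statistic estimates each internal node as the unweighted mean of
its children, sums |parent − child| over edges, and standardizes the
observed sum between a tip-shuffling null (D = 1) and a Brownian-
threshold null (D = 0) at the observed prevalence.  The Brownian null
uses antithetic pairs (Z, −Z), which makes D exactly invariant under
recoding the trait 0↔1 and halves the Monte-Carlo variance.  Faith PD
includes the root path by default (rooted-PD convention, switchable);
SES metrics use unrestricted tip-label shuffling holding community sizes
fixed, and all Monte-Carlo p-values use the (count+1)/(n+1) correction.

## Mk, stochastic mapping, OU suite

The Mk model is the symmetric two-state chain (single rate q), fitted by
bounded scalar ML on the pruning likelihood; an optional MCMC mode
samples q under an exponential prior with mean set to the ML estimate
(1000 iterations, thinned by 10), since a Bayesian search is sometimes
preferred but no prior is canonical.  Monomorphic data drive q to the
boundary and are flagged, not rejected.  Stochastic maps draw node
states from their joint conditional distribution and then each branch
path by uniformization at rate q — for the symmetric chain every virtual
jump is a real flip, so the flip count is parity-restricted Poisson and
sampling is exact with no rejection loop.  Map tip regimes equal the
observed states by construction, and map node-state frequencies are
tested against independently computed pruning marginals.

The OU likelihood composes each branch from its regime segments: over a
segment of duration d in regime r, the trait decays toward θ_r with
factor e^{−α_r d} and accumulates variance σ²_r(1−e^{−2α_r d})/(2α_r)
(Brownian limit σ²_r d at α_r = 0; expm1 forms guard the small-α
regime).  Tip covariance is the MRCA variance damped by all subsequent
decay on both paths; optima are profiled by whitened least squares.  The
root sits at the root regime's optimum with its stationary variance by
default ("root.station" convention); the "fixed" alternative estimates
the root value as an extra GLS parameter, and it is under this treatment
that OU1 → BM1 as α → 0 (the stationary root variance diverges in that
limit, which is why the default cannot have the BM limit).  Parameter
counts are computed from the model structure (profiled optima included).
α is capped at 50 /Myr and capped fits are flagged.  Two pathologies are
flagged and excluded from cross-map parameter averages: non-positive
finite-difference Hessian eigenvalues at the optimum (in log-parameter
space), and optima whose whitened design direction nearly vanishes
(α → 0 ridge, where θ is unidentifiable and the min-norm GLS keeps it
finite but meaningless).  AICc uses n = number of tips, not tips × maps:
each map is an alternative painting of the same n observations.

## Synthetic data

Trees are simulated forward with thinning against a supplied rate bound
(exact for time-varying rates), extinct lineages pruned, extant tips
retained independently with probability f, and the result conditioned on
≥ 2 sampled tips by rejection (cap 1000).  Under a taxon-count stop the
present is drawn uniformly between the stopping event and the next
event, which avoids zero-length pendant branches.  The BiSSE simulator
retains the true lineage-state history of the reconstructed tree for
diagnostics.  OU traits are sampled exactly segment-by-segment (no
Euler discretization); the root value is fixed at the root optimum by
default or drawn from the stationary law to match the likelihood's
default root treatment.  Occurrence records place a true point uniformly
in the species interval and widen it by uniform dredge margins (clipped
at the surface), with a configurable share of constant-depth stations —
so every station interval provably contains a true occurrence.
Abundance samples are multinomial draws from uniform or log-series
(p_i ∝ x^i/i) relative abundances.

What the generators do *not* emulate: spatially structured sampling,
detection covariance between stations, measurement error in traits or
depths, gene-tree/species-tree conflict, and non-random (e.g.
depth-biased) taxon sampling.  Tests passing on these fixtures show the
estimators are correct under their own assumptions, not that those
assumptions hold for any real collection.

Default fixture scenario: a few hundred sampled tips, sampling fraction
0.26, crown age of order 50 Myr — the scale of a medium-sized tropical
gastropod radiation.  The abundance calibration fixture uses 100 species
with log-series shape 0.95 sampled at 20 000 specimens, a regime chosen
so sampling is moderately complete (singletons and doubletons present
but few unobservable species): Chao1 is a lower-bound estimator and is
only expected to be near-unbiased in that regime.

## Test-suite problem sizes

The suite runs every stochastic claim at a desk scale chosen as a
compromise between statistical resolution and a single-CPU run: D and λ
calibrations at 60–100 trees of 100–200 tips; BiSSE parameter recovery
at 25 replicates of 300-tip trees (true rates λ = 0.4/0.8, μ = 0.3,
q = 0.3 — a high-turnover, fast-mixing point; extinction rates are only
weakly identified from reconstructed trees, and at low-turnover or
slow-mixing parameter points their mean relative bias at this tree size
exceeds 20% no matter the estimator, so the calibration point is one
where every rate carries information);
constant birth–death recovery at 25 replicates with f = 0.26; OU-suite
recovery at 10 replicates of 120-tip trees with the regime set-points
θ = 70 vs 21, σ² = 83.15 vs 15.1, α = 0.30 vs 0.67; decision-rule
conservatism at 60 state-independent replicates.  `scripts/acceptance.py`
runs the D/λ calibrations at their full scale (200 and 100 trees of 200
tips).

## Known limitations

- ML extinction-rate estimates from reconstructed trees are noisy and
  right-skewed at a few hundred tips; recovery experiments average over
  replicates and the per-parameter means (not single fits) are the
  calibrated quantity.
- The BiSSE lattice treats "irreversible" as q₁₀ = 0 only; reverse
  irreversibility can be expressed via a custom constraint dict.
- Stochastic mapping assumes the symmetric two-state chain the study's
  mapping step used; asymmetric rates would need a general uniformization
  sampler.
- The pipeline orchestrates files, not provenance beyond checksums; it
  is not a workflow engine.
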