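# Methods

This note records the modelling choices behind `trajgrn`: the assumptions of
each pipeline stage, the tunable parameters with their defaults, what the
synthetic generators do and do not emulate, and the numerical decisions made
where the design was genuinely open.

## Trajectory preprocessing

Expression is library-size normalized as `log2(CPM/100 + 1)` — a simple
variance-compressing stand-in for heavier variance-stabilizing schemes;
pre-normalized input can bypass it. Per-gene trajectories are fitted by an
ordinary least-squares cubic B-spline with 4 interior knots at pseudotime
quantiles (a Gaussian-error stand-in for a negative-binomial GAM: identical
interface, no count model), then evaluated on a uniform grid of M = 201
points spanning pseudotime [0, 1] *inclusive of both endpoints* (step 0.005).
Two scalings coexist deliberately: standardized trajectories (population
standard deviation) feed shape clustering and reporting, while max-scaled
trajectories (maximum exactly 1, values shifted positive if needed) feed the
Hill-function fits, whose inputs must be non-negative.

## Shape clustering

Turning points are strict sign changes of the first finite difference, with
plateaus absorbed into the preceding trend (a discrete grid has no canonical
turning-point definition; this one is insensitive to ties). Segments with
amplitude (max − min) below 0.2 on the standardized scale are merged into
their neighbours — first/last segments surrender one delimiting turning
point, interior segments both — and pruning iterates to a fixed point so the
surviving segment signs always alternate. Exactly six labels are possible
("+", "−", "+−", "−+", "+−+", "−+−"); trajectories keeping more than two
turning points are excluded, as are genes whose processed-data standard
deviation falls below 0.25 (the filter applies to processed, not
standardized, values).

## Core TFs and the initial network

TF target sets are tested for over-representation in each shape cluster with
a one-sided Fisher exact test against the background of all expressed genes;
Benjamini–Hochberg adjustment is applied jointly across all TF × cluster
pairs (the adjustment scope was unstated; joint control is the conservative
reading) and a TF is selected when any pair has q < 0.1. TF pairs whose
target sets overlap at p < 1e-20 are deduplicated in favour of the TF with
the higher expression variance, processing pairs in ascending-p order. The
initial network unions curated edges with motif-predicted edges of NES > 1
(union, not intersection: the source text reads additive) and removes
disconnected nodes.

## Model fitting

The fitting target is the log2 quasi-steady-state prediction against **log2
of** the max-scaled trajectory values. The source convention mixes scales (a
log2 prediction against untransformed values); with the consistent log2
convention the generating model is a member of the fitted family, and sign
recovery on noiseless synthetic problems improves markedly (12/20 → 19/20
in our tests), so the consistent convention is the default and
`FitConfig.target_scale = "linear"` restores the literal one.

Optimization is bounded trust-region least squares with an analytic
Jacobian. Bounds: λ in (1.001, 100] for activation, [0.01, 0.999) for
inhibition; n in (0.001, 10]; R in (0.001, 10·max y]; C in [−20, 20].
Initial draws follow the stated ranges (λ from (2,4) or (0.25,0.5), R from
(0.3, 0.7)·max y, n from (0.01, 0.99), C from (−2, 2)); n's initialization
range does not constrain the optimizer. Five-fold cross-validation assigns
point l to fold l mod 5 (interleaved by pseudotime; contiguous blocks would
force pure extrapolation at the ends — a config switch provides them).

Stage 3 (reduced regulatory scenarios) has two refinements over a literal
transcription of its description, both needed for the reducibility index to
measure edge dispensability rather than optimizer artefacts:

* the reference MSEs (MSE_ori,h) are the *no-removal, regularization-free*
  refits of the top stage-2 models, so the empty scenario scores exactly the
  number of reference models and every other index isolates the effect of
  the deletions (raw regularized MSEs deflate all ratios by shrinkage bias);
* scenario refits lift the per-sign λ bounds and warm-start from those
  polished reference fits. The scenario stage tests topology, not signs —
  signs are re-decided in the final stage by majority pattern — and
  sign-locked refits from wrong-sign references can never fit well after a
  deletion, contaminating I with basin-trapping effects.

The default reducibility cutoff is 11.0 on the 10-reference-model scale
(rescaled proportionally when fewer reference models are used); emitting one
network per cutoff over a [10, 14] grid reproduces a family of network
sizes. The per-gene candidate cap is 12 regulators (4096 patterns).

Reduced-restart schedules: `FitConfig.reduced()` (no stage-1 restarts, pool
30, 10-point tuning grid, 3 scenario reference models) and
`FitConfig.benchmark()` (pool 20, 6-point tuning grid, 2 reference models,
the removable set capped at the 6 most sign-ambiguous edges, and a stage-1
screen that fits each sign pattern on every third grid point with a small
iteration budget before refitting the keepers on the full grid). Both run
every stage of the procedure; they trade restart depth for runtime and are
the schedules used by the package's own benchmark harness and test suite.
The problem sizes used there — 20 recovery problems with 2–3 regulators, the
81-case suite, the 3-gene circuit — are the package's chosen demonstration
scales.

## Driving simulations

Fitting identifies only C = log2(g/k); simulation-ready models set k = 1 and
g = 2^C (unit relaxation timescale). Pseudotime [0, 1] maps linearly onto a
simulation window of S = 100 time units (slow relative to 1), integrated
with fixed-step RK4 (2000 steps). The forward run starts from the relaxed
steady state at the trajectories' initial values and clamps the driver TFs
to their observed max-scaled trajectories at every RK4 sub-step; the
backward run starts from the forward endpoint with time-reversed drivers.
`msd_data` compares forward non-driver outputs with the observed
trajectories after independent per-gene min-max rescaling to [0, 1];
`msd_hysteresis` compares forward and time-reversed backward outputs under a
*joint* per-gene rescaling, so coinciding paths give exactly zero. In the
adiabatic limit a monostable system retraces its path (hysteresis MSD falls
roughly quadratically with S), while driving a bistable switch across its
fold leaves a finite gap.

## Ensemble mapping

Given only a signed topology, kinetic parameters are drawn per model from
the canonical random-circuit ranges: g ~ U(1,100), k ~ U(0.1,1), fold change
f ~ U(1,100) with λ = f (activation) or 1/f (inhibition), integer Hill
coefficients 1–6, and thresholds U(0.02, 1.98) times the source's
unregulated level g/k of the same draw (a per-draw stand-in for the
median-based half-functional rule). 10,000 models are integrated to steady
state (batched RK4, relative stationarity 1e-4; non-converged draws are
resampled and an overall failure rate above 20% is an error).

Each gene's simulated distribution is transformed log2(u + shift) with the
shift chosen from a 31-point grid (log2-shift even in [−10, 5]) to maximize
histogram intersection (50 bins over the pooled range) with the observed
trajectory distribution, then standardized. Reference states are the
standardized trajectory values at 6 evenly spaced grid indices (0, 40, ...,
200); each reference's cutoff D_r is the 5th percentile of distances from
10,000 per-gene-normal random profiles. A model maps to a reference when its
distance is within D_r, ties resolved by minimum D/D_r. The weighted mapping
percentage weights each model by its inverse local density ρ = 15/(π R^v),
R the distance to the 15th neighbour, computed both in the full gene space
and in the first three principal components; headline numbers use the
low-dimensional variant because full-dimensional densities are heavily
skewed. Entropy uses mapped-model shares normalized to 1 (a config switch
provides the all-models denominator). The deviation metric is
ω = (d_u − 1)/(d_θ − 1), with d_u (d_θ) the mean minimum normalized distance
of unmapped (random) profiles; ω is reported as missing when d_θ ≤ 1.

## Synthetic benchmark

Ten candidate trajectories come from random degree-4/5 polynomials
(coefficients U(−1,1)) rescaled to minimum 0.1 and maximum U(1,5) on the
201-point grid — a reconstruction of the source's unavailable formulae that
preserves what matters: smooth, positive, non-monotone curves. A case picks
m regulators (2–7) and m_d decoys (1 to 9−m) and simulates the target by the
steady-state relation with log2 λ ~ ±U(1,3), R ~ U(0.1,0.9)·max x,
n ~ U(2.5,4.5), C ~ U(−2,2); three random assignments per (m, m_d) give 81
cases. The printed bound "9 ≥ m + m_d ≥ 4" would exclude (2,1) and give 78;
the enumeration that matches the printed total of 81 is used. Multiplicative
Gaussian noise G' = G + γ·N(0,1)·G (floored at 1e-6) is applied per point;
the default sweep is γ ∈ {0, 0.05, 0.1, 0.2}.

Rankings are scored by AUROC/AUPRC with the rank weight log(A − π_e + 2)
used as each candidate's confidence score (rank-monotone; an
instance-weighted mode is available since the source wording is ambiguous).
The fitter's scenario output converts to a regulator ranking by taking the
lowest-index scenario per retained-edge count and ranking candidates by
their frequency across these best combinations (ties by lower mean index,
then name). The signed-edge evaluator counts a true positive only when the
sign agrees with the literature edge, a false positive when it disagrees,
and a false negative for a missed literature edge; F0.1 weights precision
heavily.

## The ICM–TE ground-truth circuit

Oct4/Cdx2/Esrrb plus an FGF input reproduce the inner-cell-mass vs
trophectoderm decision: mutual inhibition Oct4 ⊣ Cdx2, the coherent
feed-forward Cdx2 ⊣ Esrrb → Oct4, and FGF acting on Cdx2. The input signal
is the half-cosine ramp 150 → 25 over the first half of T = 1000. Because a
*decreasing* signal must complete the ICM → TE transition, FGF is wired as
an inhibitor of Cdx2 (falling FGF releases Cdx2); the prose description of
an "increasing FGF signal" and this functional orientation cannot both hold,
and the shipped orientation is the one that makes the stated protocol work.

The original parameter table is unavailable, so the package ships its own
set, chosen to satisfy every qualitative property the circuit must show and
verified by the test suite: a contiguous bistable window of the signal that
contains 150, with a single attractor above (ICM) and below (TE); completion
of ICM → TE under the ramp protocol; and commitment — reversing the signal
from the endpoint leaves the system in the TE branch. Expression levels are
Oct4 ≈ 114, Cdx2 ≈ 3 → 400, Esrrb ≈ 80 with heterogeneous turnover
(k = 0.5, 0.2, 0.5) and regulation thresholds placed so each gene switches
at a distinct time along the transition. Two choices specifically protect
the identifiability of the reconstruction benchmark: Cdx2 ⊣ Esrrb uses a
steep Hill coefficient (n = 8) so Esrrb behaves as a switch — a graded
response would be an invertible transform of Cdx2 and make the direction of
the Cdx2–Esrrb edge unidentifiable from trajectories — and the reconstruction
fixture adds γ = 0.05 multiplicative noise to the sampled trajectories,
emulating the roughness of smoothed experimental data and giving all models
a common error floor so reducibility ratios are well conditioned (ratios of
near-zero residuals are meaningless).

## What the synthetic generators do and do not emulate

The fixture dataset (six trajectory shape classes with TF → target groups
and multiplicative noise), the polynomial benchmark curves, and the circuit
trajectories capture smooth pseudotime dynamics, regulator/decoy confusion,
measurement noise, and dynamical lag. They do not emulate count sampling
noise or dropout, branching trajectories, cell-cycle or batch structure, or
indirect regulation through unobserved intermediates. Passing tests
therefore demonstrate correctness of the algorithms and recoverability under
the stated conditions, not performance on raw single-cell data.

## Known limitations

Quasi-steady-state fitting on a single monotone transition is only weakly
identifiable: any monotone regulator can partially explain any monotone
target, and feedback cycles blur edge direction. Recovery relies on
distinct switching times, lags, and curvature; data with a single
synchronous jump will defeat it. The scenario stage is exponential in the
number of removable edges (capped), and the ensemble integrator assumes
non-stiff kinetics within the sampled ranges.
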