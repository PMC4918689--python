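# Methods

This note records the modelling assumptions, numerical choices and design
decisions behind `phmmdfc`, and what the synthetic studies do and do not
demonstrate.

## Windowed correlation

The taper is the full discrete convolution of a unit rectangle of
`rect_len` TRs with a truncated Gaussian of `gauss_len` taps and width
`gauss_sigma` TRs, renormalized to sum to one. The Gaussian's support and
width are free parameters of the construction; the defaults
(`rect_len=15`, `gauss_len=4`, `gauss_sigma=1.0`) give an 18-tap taper and
therefore exactly 103 fully contained windows on 120 usable volumes at
step 1 — the canonical protocol geometry (a 45 s nominal window at
TR = 3 s). Only fully contained windows are used; there is no partial-edge
handling, so T = T_full − L + 1 at step 1.

Correlation is the *taper-weighted Pearson correlation*: the weights enter
the means, variances and covariance, rather than multiplying the signals
before an unweighted correlation. This is the standard weighting semantics
for tapered-window DFC and keeps the estimator exactly invariant under
positive affine rescaling of either series. A window in which either
series is constant raises an error naming the window index; values are
clipped to [−1, 1] against floating-point rounding.

Inputs are already-trimmed time-courses (the first acquired volume, used
as an ASL reference in the motivating acquisition scheme, is assumed
dropped by the caller). Whether the printed window count derives from 120
or 121 volumes with a different taper support is ambiguous; this package
fixes one consistent reading (support 18 on 120 volumes) and exposes all
window parameters.

## Product HMM

**State space and encoding.** K two-state channels give 2^K joint states.
Channel 0 is the most significant bit of the joint index and sub-state +1
maps to bit 1; the encoding is fixed so transition matrices are comparable
across runs and serialized models declare it explicitly. Labels use the
case convention (channel name upper-case when correlated).

**Emissions.** Per channel and sub-state, unimodal Gaussians; the joint
emission is their product, i.e. a diagonal-covariance Gaussian on the 2^K
space whose mean vector is read off the sub-states. A third "decorrelated"
sub-state is deliberately out of scope. Emission parameters are
initialized from the sign-split data (positive observations →
(μ₊₁, σ₊₁), negative → (μ₋₁, σ₋₁)) and **never re-estimated** during EM:
on 103-window sequences the 64×64 transition matrix already strains the
data, and fixing the emission table keeps decoding stable without
measurable loss. Sample stds use ddof=1; a split with a single sample
falls back to the grand std, a split with no samples to the grand mean ±
one grand std (with a logged warning); all stds are floored at σ ≥ 1e-3 to
prevent density blow-up on near-constant channels.

**Learning.** Baum–Welch with per-step scaled forward–backward. Π is
re-estimated alongside A (a standard EM choice; only the emission freeze
is a protocol constraint). Emission likelihoods are rescaled per time-step
by their column maximum before the recursion so the scaling constants stay
in range for any K. Convergence: log-likelihood improvement < 1e-4
(default `tol`) or 100 iterations; non-convergence returns the best model
with a flag rather than raising. Rows whose expected transition mass is
zero keep their previous values. An independently scaled backward
recursion exists purely as a numerical cross-check; forward and backward
log-likelihoods agree to 1e-8 in the tests.

**Decoding.** Log-space Viterbi; argmax ties break toward the lower state
index, making decoding deterministic. The decoded path's joint
log-probability is returned and is bounded above by the total
log-likelihood.

**Generation.** Hidden paths are sampled by inverse-CDF lookup from the
cumulative transition rows, observations from the per-state Gaussians; all
generation is deterministic given a seed and returns the hidden path for
recovery tests.

## Model distance

The generation-based distance follows the printed definition
D(λ₁, λ₂) = (1/T_gen)[log P(Y₍₂₎|λ₁) − log P(Y₍₂₎|λ₂)], normalized by the
*generated* length (the only consistent reading when sequences are
generated rather than observed). Under this sign convention the directed
distance of distinct models is typically negative — the generator explains
its own data better — and dissimilarity grows with magnitude; the
group-level t-test is two-sided, so the convention is immaterial to the
protocol. One sequence is generated per directed distance by default
(replicate averaging would only sharpen the already-decisive group
contrast).

**Seed policy.** `symmetrized_distance` derives a single generation seed
from the call's master seed and uses it for both directions, so the
symmetrized value is *exactly* invariant under swapping the two models.
The group pipeline, which knows subject identities, instead derives each
directed generation's seed from (master seed, reference-network label,
unordered pair ids, generating-subject id) via CRC32-hashed
`SeedSequence` entropy: direction-aware, order-independent, and still
exactly symmetric because the generating subject — not the argument
slot — selects the stream.

## Group protocol

All control–control and control–patient pairs enter the comparison
(C(n_c, 2) and n_c·n_p distances; 190 and 320 at the canonical 20 + 16
group sizes); patient–patient distances are computed and written for
inspection but excluded from the test. The test is Student's pooled
two-sample t-test, two-sided — the plainest reading of a "two-sample
t-test" — with Welch available by flag; the decision is h = 1 iff
p < α (default 0.01), with no multiple-testing correction across reference
networks (a correction can be applied downstream; the protocol itself uses
the bare threshold).

Transition-matrix summaries: loopback(i) = a_ii (temporal stability of
state i) and reach(j) = mean over i of a_ij (the column mean; the mean
one-step probability of entering j). Reach values over all j sum to 1 for
any row-stochastic A. Sequence statistics are run-length encodings of the
decoded joint path; mean dwell in seconds is mean run length × TR; "long"
occupancy means a run longer than one window. Pattern occupancy constrains
any subset of channels to ±1 with wildcards elsewhere and reports the
fraction of windows matched; occupancy rates are compared across groups
with the Kruskal–Wallis rank test (the degenerate all-constant case
returns H = 0, p = 1). Group-level sequence statistics are means over
subjects of per-subject statistics.

## Synthetic data

`generate_timecourses` emulates the pipeline's raw input: N = 7 networks ×
120 volumes at TR = 3 s by default. The timeline is segmented into regimes
with geometric durations (memoryless, matching the Markov assumption the
model will fit; mean 15 volumes by default). Within a regime a ±1 sign
pattern over network pairs is drawn (P(+1) = 0.5 baseline; one designated
pair's probability differs by group, 0.85 vs 0.15 by default) and scaled
by the correlation magnitude ρ = 0.6. Arbitrary sign patterns need not be
valid correlation matrices, so each target is repaired by eigenvalue
clipping (floor 1e-4) and rescaling to unit diagonal; a repair that flips
a requested sign or shrinks a magnitude below 0.1ρ is rejected and the
pattern resampled (20 attempts, then an error). The repaired matrix and
its maximum entrywise delta are recorded in the per-subject truth sidecar.
White observation noise (sd 0.2) is added on top of the unit-variance
signals. Everything is deterministic given (seed, subject index).

The generator makes no attempt at hemodynamic-response convolution,
scanner drift, physiological noise or spatial structure. Passing tests on
these data therefore demonstrate the *statistical machinery* — recovery of
known dynamics, correctness of the distance and test pipeline — not
robustness to real fMRI artefacts.

**Two-group power scenario.** The built-in scenario draws controls from a
stable, sharply separated generator (μ = ±0.45, σ = 0.15, loopback 0.85)
and patients from a weaker, noisier one (μ = ±0.20, σ = 0.30, loopback
0.60), K = 6 channels and T = 103 windows per subject, 20 controls and 16
patients, distances at T_gen = 150. These conditions were fixed once as a
deliberately well-separated regime: the study they emulate reports
decisive p-values for its affected networks, and the scenario is meant to
verify that the full chain detects a true model difference, not to probe
the detection threshold. Per-subject EM is capped at 50 iterations in this
study (fits are effectively converged well before that on these data).

## Problem sizes and determinism

The test suite's exhaustive oracles enumerate all joint-state paths for
K = 2 and T ≤ 4; parameter recovery uses T = 2000; the law-of-large-numbers
check T = 50 000; the power study runs 20 replicate master seeds of the
full 36-subject protocol (a few minutes on one CPU). All randomness flows
through explicit seeds or `SeedSequence` derivations; repeated runs are
bit-identical, and `run-all` reports are byte-identical across invocations
with the same config and master seed.

## Known limitations

* The 64-state transition matrix is estimated from 103 windows; estimates
  are heavily regularized toward the initialization in sparsely visited
  regions of the state space. This mirrors the protocol's regime rather
  than a resolvable defect.
* Emissions are fixed at their sign-split initialization; channels whose
  correlation distribution is strongly skewed to one sign get a fallback
  component from grand moments.
* No "0"/decorrelated sub-state, no coupled-HMM sparsification, no
  hierarchical structure, no NIfTI ingestion — inputs are extracted
  time-courses in delimited text.
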