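# Methods

This note documents the models and procedures implemented in `ephys_batch`,
the defaults chosen where the design was open, and what validation on
synthetic data does and does not establish.

## Pipeline execution model

A pipeline is a YAML document with an optional `meta` section (event-name →
integer code) and an ordered list of steps, each a name plus keyword
arguments.  Step names resolve in a fixed order — user-supplied custom
functions, then toolbox steps, then generic backend (Recording-method)
steps — so a user function can shadow a built-in without renaming it.  A
step is a pure function `(dataset, userargs) -> dataset` over a keyed state
dict; every executed step appends one provenance record, and new keys are
persisted under the session's output subdirectory.

Reproducibility contract: session *i* of a batch always runs with seed
`seed + i`, independent of the worker count, and derivative files contain
no wall-clock timestamps (timestamps live in the log files), so serial and
parallel runs of the same batch are byte-identical.  Signal derivatives are
stored as a `.json` header plus `.npy` payload — a deliberately simple,
deterministic container; FIF input is supported for interoperability, but
FIF embeds creation times and is therefore not used for derivatives.

## Artifact screening (GESD)

Both bad-channel and bad-segment detection reduce to the two-sided
generalized extreme studentized deviate test with significance level α
(default 0.05) and candidate bound r = ⌈0.1 n⌉.  For i = 1..r the point
maximizing |x − x̄|/s among the remaining points is removed and its deviate
R_i compared against

    λ_i = (n − i) t_{p, n−i−1} / sqrt((n − i − 1 + t²)(n − i + 1)),
    p = 1 − α/(2(n − i + 1));

the declared outlier count is the largest i with R_i > λ_i, which keeps the
test sensitive when several outliers mask one another.  If the remaining
points become numerically constant the remaining deviates are defined as 0
rather than raising.  The implementation is validated against an
independently coded repeated-Grubbs oracle on randomized instances
(n ≤ 50, up to 5 planted outliers).

Channel screening applies GESD to a per-channel summary metric (std by
default; var and kurtosis available) computed over good samples only, per
channel type (MEG and EEG units differ by orders of magnitude), capped at
`max_frac` (default 0.1) of the channels.  Segment screening tiles the
recording into non-overlapping windows (default 1 s), aggregates the metric
over good channels, and merges contiguous flagged windows into annotations
aligned to window boundaries.  Metrics deliberately exclude
already-annotated samples and already-bad channels, so detection is stable
under re-running.

## IC artifact handling

ICA unmixing is delegated to FastICA; this package owns what is layered on
top: estimation on artifact-free samples only (so a large bad segment
cannot dominate the whitening), unmixing of the full timeline, labelling of
components whose absolute Pearson correlation with any recorded ECG/EOG
channel (computed over good samples) reaches the threshold (default
|r| ≥ 0.8; an ECG match wins an exact tie), and subtraction of the rejected
subspace.  Rejection recomputes the rejected source time courses from the
data being cleaned via the stored unmixing (s = W(x − μ)); since WA = I,
cleaning an already-cleaned recording subtracts zero, making the operation
idempotent.

## Spherical forward model and LCMV beamformer

The forward operator is the Sarvas closed form for a current dipole in a
homogeneous conducting sphere, projected onto sensor orientations, with
three columns (x, y, z unit moments) per grid point.  Grid: axis-aligned
lattice at a given spacing (default scale 8 mm) keeping points strictly
inside the sphere, ordered x-fastest; coordinates are meters in a
head-centered right-handed frame.  Two analytic properties anchor the
tests: a dipole at the sphere center is silent, and radially oriented
dipoles produce no external magnetic field (radial lead-field norms are at
float precision, ~1e-16 of tangential norms).

The sensor covariance is the sample covariance regularized as C + λI with
λ = `lam_frac` (default 0.05) times the mean eigenvalue.  The scalar LCMV
beamformer first rank-reduces each grid point's 3-column lead field
(singular values below 1e-6 of the largest are discarded — this removes the
magnetically silent radial direction), then selects the orientation
minimizing lᵀC⁻¹l within the retained space (equivalently maximizing the
unit-gain output power 1/(lᵀC⁻¹l)), and forms w = C⁻¹l/(lᵀC⁻¹l).

Localization uses the neural activity index wᵀĈw / (σ̂² wᵀw) with σ̂² the
smallest covariance eigenvalue, not the raw output variance wᵀĈw: the raw
variance grows like 1/(lᵀC⁻¹l) toward the sphere center where lead fields
vanish, a well-known depth bias that measurably degrades planted-dipole
localization (we observed 7/10 vs 10/10 hits at SNR 5).  Both maps are
exposed.

## Parcellation, leakage correction, sign alignment

Each parcel's time course is the first principal component of its member
dipole time courses, rescaled to the mean member variance, with the PC sign
fixed so the spatial weights sum positive — a deterministic convention so
that runs are reproducible before any cross-subject alignment.

Leakage correction is the symmetric closest-orthogonal-matrix procedure:
find Y = D O minimizing ‖X − D O‖_F over row-orthonormal O and positive
diagonal D by alternating the polar/SVD projection O ← UVᵀ of DX and the
per-parcel regression rescale d_i ← x_i·o_i, iterating until the relative
Frobenius change falls below 1e-10 (at most 100 iterations; convergence is
typically < 20).  Input rows are demeaned, so orthogonality equals
decorrelation.  Being symmetric and multivariate, the procedure privileges
no parcel ordering and also removes ghost interactions inherited from third
regions; it is verified to land closer to the input than rescaled
Gram-Schmidt on every tested instance.  Rank-deficient input is rejected
with the deficient rank named.  Orthogonalization may be applied before or
after epoching; the pipeline logs which order was used.

Sign alignment: per-subject flip vectors f ∈ {−1,+1}^P are sought to
maximize the mean Pearson correlation between the off-diagonal entries of
each subject's flipped covariance FCF and a template covariance (the
subject whose covariance best matches the element-wise mean).  The
objective separates per subject, so each subject is optimized independently
by greedy single-parcel flips from `n_init` (default 10) random restarts
(the first restart is all-ones), at most `n_iter` (default 50) sweeps.
Because FCF is invariant to a global sign, recovery of planted flips is
defined up to one global sign per subject.  Greedy equals exhaustive
enumeration on all tested P ≤ 4 instances, and recovers planted flips in
≥ 95% of desk-scale simulations (10 parcels, 5 subjects, 10 000 samples).

## GLM statistics

First-level designs are one-hot condition indicators with a mean contrast
(equal weights) and, for the famous/unfamiliar/scrambled paradigm, a
faces-vs-scrambled contrast with weights [0.5, 0.5, −1].  Group designs are
subject indicators over sessions with an equal-weight mean contrast; they
require more observations than subjects (≥ 2 sessions each), as the
per-subject residual degrees of freedom come from within-subject
replication.  Fitting is ordinary least squares per outcome dimension;
varcope = σ̂² cᵀ(XᵀX)⁺c with σ̂² from the residuals and dof = n − rank(X).
First-level copes enter the group level unweighted (no varcope
propagation); fixed-effects OLS only.

Permutation inference: the null distribution of max |t| over the in-scope
outcome dimensions, with the identity permutation always included (minimum
attainable p = 1/n_perms; duplicated random draws may tie it).  Group-mean
contrasts are permuted by per-subject sign flipping of copes (valid under a
symmetric null); condition contrasts by label permutation (within session
when sessions are given).  Tests are two-sided on |t| at α = 0.05,
default 1000 permutations, seed recorded.  Calibration is verified by
simulation: family-wise error 0.045 at α = 0.05 over 200 null datasets of
12 × 40 dimensions with 500 permutations.

The GLM-spectrum treats per-window periodograms (Welch conventions: hann
taper, 50% overlap, per-window constant detrend, density scaling) as
observations and fits an intercept plus demeaned per-window covariates per
frequency and channel.  The intercept-only fit equals the Welch average to
float precision (verified against an independent Welch implementation at
1e-10 relative tolerance).

## Synthetic data

The generators emulate a multi-subject, multi-session visual MEG study at
desk scale — defaults: 5 subjects × 2 sessions, 32 sensors, 10 parcels,
100 s at 250 Hz, sensor SNR 5, ~60 bpm cardiac pulses with 5% beat jitter,
~15 blinks/min as 300 ms half-sines, bad-channel gain 20, bad-segment gain
15 — sizes chosen so the full validation suite runs in minutes on one CPU.
Setting an artifact rate to 0 removes that component entirely, giving exact
null recordings for calibration tests.  Everything is a pure function of
the spec's mandatory seed.

What the generators do *not* emulate: realistic head geometry in the sensor
mixing (random mixing by default; the Sarvas forward model is used where
geometry matters), 1/f spectra, heteroscedastic sensor noise, and
inter-subject anatomical variability.  Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under the stated
models, not performance on real recordings.

## Reports

Per-session metrics (sensor count, duration, bad-channel count, percent bad
time, IC label counts, epoch counts) are pure functions of the session
state, always present (0 for skipped stages).  The subject report embeds
per-session figures, metric tables and the verbatim session log; the
summary report has one client-side-sortable row per session, the config and
custom-function sources, and error traces for failed sessions.  Reports are
single self-contained documents (no network assets) that parse as strict
XML; missing figures degrade to placeholders, never failures.

## Known limitations

- No Maxwell filtering, no interactive IC labelling GUI, no BEM/FreeSurfer
  surface pipeline, no coregistration: the forward model is the analytic
  sphere, and externally computed lead fields can be supplied through the
  `LeadField` file interface.
- No minimum-norm inverse; scalar (not vector) beamformer output only.
- No cluster-based or TFCE inference; no hierarchical variance modelling.
- Resumption of partially failed batches is not supported — re-runs start
  fresh.
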