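# Methods

`hemoconn` measures how cortical regions interact through the slow
oscillations of hemoglobin concentration recorded by multi-channel NIRS.
Two complementary quantities are computed per frequency band: wavelet phase
coherence (WPCO, undirected functional connectivity) and the coupling
strength of an inferred phase-oscillator model (CS, directed effective
connectivity).  Because the human recordings such analyses are usually run
on cannot be redistributed, the package ships a synthetic-cohort generator
with known ground truth; every claim the test suite makes is a claim about
recovering that ground truth.

## Frequency intervals

Hemodynamic oscillations are analysed in four physiological bands
(half-open, in Hz): I [0.6, 2) cardiac, II [0.145, 0.6) respiratory,
III [0.052, 0.145) myogenic and IV [0.021, 0.052) neurogenic.  The
scientific results of interest concern bands III and IV; bands I and II are
computed but secondary.

## Synthetic cohorts

Each cortical region (LPFC, RPFC, LMC, RMC, LOL, ROL) carries one latent
phase oscillator per band, following

    dφ_i/dt = ω_i + Σ_j q_{j→i}(φ_j, φ_i) + ξ_i(t),
    ⟨ξ_i(t) ξ_i(t')⟩ = 2 D_i δ(t − t'),

integrated by Euler–Maruyama at dt = 0.01 s (increment s.d. √(2 D dt)) and
decimated to the 10 Hz acquisition rate.  Every channel of a region reads
out Σ_b A_b sin(φ_{region,b}) plus a slow sinusoidal drift (0.002 Hz) and
white measurement noise (s.d. 0.3 in units of the band amplitude A = 1).

Default study conditions mirror the target experiment: 13 "hypertension"
and 16 "control" subjects, resting and standing conditions, 600 s records,
36 channels (6 per region).  Directed couplings q = a·sin(φ_src − φ_tgt)
connect homologous pairs plus prefrontal→motor and motor→occipital edges in
bands III (a = 0.15 rad/s) and IV (a = 0.08 rad/s); the hypertension-like
group's amplitudes are scaled by 0.7.  Oscillator frequencies are detuned
across regions so that every coupled pair sits near the edge of its 1:1
locking range (Δω/a ≈ 0.7–1.0).  This partial-synchronisation regime was
chosen deliberately: it produces band III/IV coherence values in the
0.4–0.7 range typical of published interregional NIRS coherence, and it is
the regime in which coupling direction is statistically identifiable —
deeply locked pairs carry almost no directional information (see
Limitations).  Phase-noise intensities are D = 0.2, 0.1, 0.05, 0.02 rad²/s
for bands I–IV.

Per-subject heterogeneity is a truncated-normal coupling multiplier
(s.d. 0.1), and cognitive scores are a linear map of each subject's
realised mean coupling amplitude plus Gaussian noise (s.d. 1.5), clipped to
the 30-point MMSE/MoCA scales — so weaker coupling implies lower scores on
average, giving the correlation analyses something real to find.  Subject
random streams are derived from (cohort seed, subject index) independent of
group, so equal-multiplier groups are equal in law.

What the generator does *not* emulate: optical physics (the modified
Beer–Lambert step), systemic/scalp physiology and Mayer waves, spatially
correlated noise across channels, and non-sinusoidal waveform asymmetries.
Passing tests therefore demonstrate correctness of the estimators under the
stated generative model, not robustness to every artifact of real NIRS.

## Artifact correction and filtering

Movement artifacts are detected by a centred moving standard deviation
(window 1 s) thresholded at 5× its median, with sub-0.5-s gaps merged.
Flagged segments are fitted by a cubic smoothing spline with roughness
weight p/(1−p), p = 0.01 — the spline tracks the artifact's shape — and the
residual after subtraction is re-levelled onto a linear bridge between the
neighbouring clean samples, so both segment boundaries are continuous and
no baseline step propagates downstream.  Segments shorter than 4 samples
are bridged linearly.  Records are then band-passed 0.005–2 Hz with a
zero-phase order-3 Butterworth filter.  W, T, the filter band and order are
configuration, not measurements; the defaults above are the package's own.

## Time–frequency analysis

The continuous wavelet transform uses the Morlet wavelet
ψ(u) = π^(−1/4) e^{i 2π f0 u} e^{−u²/2} with f0 = 1, scale s = f0/f on a
log-spaced grid (16 voices per octave), L2 normalisation (white-noise
energy flat across scale), implemented by FFT convolution with cached
Fourier-domain kernels.  A cone of influence of one e-folding time (s·√2)
per edge is excluded from every time average.  For analyses restricted to
slow bands the input is first anti-alias filtered and decimated so that the
sampling rate stays ≥ 4× the highest band edge (e.g. 1 Hz for bands
III + IV); this is an exact in-band equivalence and dominates the
pipeline's speed.

Band phases come either from the |W|-weighted sum of wavelet coefficients
across the band's grid (used for coherence diagnostics) or from the
analytic signal of the band-passed record (used for oscillator inference,
which needs a single protophase per band).

## Wavelet phase coherence

For channels with coefficients W1, W2, Δφ(t,f) = arg(W1 W2*) and
WPCO(f) = |⟨e^{iΔφ}⟩_t| over COI-free samples; band values average WPCO(f)
over the band's grid frequencies (time first, then frequency).  Region
pairs average over all inter-region channel pairs.  Significance: the
second channel of each pair is replaced by amplitude-adjusted Fourier
transform (AAFT) surrogates (default 100), and a pair is significant when
its value exceeds the surrogate mean + 2 s.d.  AAFT preserves the amplitude
distribution exactly and the spectrum approximately, which matters: the
null coherence level of narrowband signals is set by their bandwidth, so a
spectrum-matched null is the only fair one.

## Effective connectivity (dynamical Bayesian inference)

A channel pair's band phases, decimated to the inference rate (2 Hz for
band III, 1 Hz for band IV), are modelled as two coupled stochastic phase
equations whose right-hand sides are expanded in the Fourier basis
{1} ∪ {sin, cos(k1 φ1 + k2 φ2)} up to order K = 2, one representative per
±(k1,k2) pair — 25 real base functions per equation.  With h the inference
step, φ̇ the finite-difference phase velocity and the basis evaluated at
midpoint phases, the posterior of the stacked coefficient vector c is
computed by iterating

    D      = (h/N) Σ_n (φ̇_n − c·P_n)(φ̇_n − c·P_n)ᵀ
    Ξ_post = Ξ_prior + h Σ_n P_n D⁻¹ P_nᵀ
    r      = Ξ_prior c̄_prior + h Σ_n P_n D⁻¹ φ̇_n − (h/2) Σ_n ∂P/∂φ_i
    c      = Ξ_post⁻¹ r

to convergence.  Successive windows receive the previous posterior as
prior with covariance inflated by p_w²·diag(c²) (p_w = 0.2), allowing slow
parameter drift; the default treats a 10-min record as a single window,
because windowing a stationary record only adds estimator variance
(192-sample windows overestimated a 0.3 rad/s coupling more than twofold in
recovery simulations, a single 600-s window recovers it to a few percent).

Numerical choices worth stating:

* **First-window prior.** Ξ_prior = 0.25·I (prior coefficient s.d. 2 rad/s,
  an order of magnitude above physiological coupling strengths).  A fully
  flat prior leaves near-collinear basis directions unconstrained and the
  midpoint drift-correction term can then diverge through its interaction
  with the noise estimate; the weak prior removes the instability without
  measurably biasing identified directions.  `infer_window` still accepts
  `prior=None` for the exact flat recursion.
* **Inference rates.** 2 Hz (band III) / 1 Hz (band IV) balance
  finite-difference noise against sample count; both were selected by
  parameter recovery against simulated ground truth, where 2 Hz halves the
  band-III coupling error relative to 1 Hz.
* **Coupling strength.** CS(j→i) is the Euclidean norm of the coefficients
  in equation i whose base functions involve φ_j.  The raw norm of a noisy
  estimate is biased upward by tr Σ (the posterior covariance of those
  coefficients); the default estimator subtracts it under the square root,
  floored at zero.  On the recovery ladder a ∈ {0, 0.1, 0.3, 0.5} rad/s the
  debiased estimator returns medians {0, 0.10, 0.28, 0.49}.
* **Degenerate matrices.** D is floored at 1e−12×trace; a singular Ξ_post
  is ridge-regularised (1e−8×trace scale) and the window flagged.

Significance mirrors the coherence test: AAFT surrogates of the source
channel, re-extracted and re-fitted, with the mean + 2 s.d. criterion.

## Statistics

Per connection and band: a 2×2 mixed-design ANOVA (group between,
condition within), one-way ANOVA between groups within each condition, and
repeated-measures comparison of conditions within each group; independent
t-tests on MMSE/MoCA; Pearson correlation of connectivity with scores
within the designated group.  The mixed ANOVA is computed in closed form
through the two orthogonal subject-level contrasts (subject mean and
condition difference), which for a two-level within factor is exactly the
classical partition — Type III under unequal group sizes, no sphericity
issue with two levels — and is verified in the tests against both a
design-matrix oracle and pingouin.  Normality (Kolmogorov–Smirnov against
a moment-fitted normal) and variance homogeneity (mean-centred Levene) are
available as assumption checks.  No multiple-comparison correction is
applied by default, mirroring the per-connection reporting convention of
the studies this pipeline serves; Benjamini–Hochberg adjustment is a
configuration switch.

## Problem sizes used in the tests

The test suite runs on scaled-down montages: one channel per region for
cohort-level tests (the 36-channel montage is exercised for shape/count
contracts), full 600-s records wherever an estimator's calibration matters,
surrogate ensembles of 100 where thresholds are asserted and smaller where
only plumbing is exercised, and 10 cohort replicates for the end-to-end
group-effect test.  `scripts/acceptance.py` runs one full-size replicate
study through the complete pipeline plus a 20-replicate parameter-recovery
study.

## Known limitations

* Directionality from phases is ill-posed for deeply phase-locked pairs:
  the regressors decorrelate slowly, AAFT surrogates underestimate the
  reverse-direction estimator variance, and spurious bidirectionality can
  appear.  The estimators are honest in the partial-synchronisation regime;
  interpret directed results for near-locked pairs (coherence ≳ 0.9) with
  caution.
* Protophases from band-passed analytic signals are not invariant phases;
  no protophase-to-phase transformation is applied.
* The bivariate model ignores third-party oscillators; all-pairs inference
  cannot distinguish direct from mediated influence.
* AAFT surrogates preserve the spectrum only approximately for strongly
  non-Gaussian amplitude distributions.
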