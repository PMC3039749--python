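# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic benchmarks show. It is the package's own account of its
science; everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## Generative model

Sudomotor nerve activity (SNA) is parameterized as a train of Gaussian
bursts u(t) = Σᵢ aᵢ exp(−(t−μᵢ)²/2σ²) with fixed width σ = 0.3 s, variable
non-negative amplitudes, and a maximum density of 30 bursts/min. Microneuro-
graphic reports put burst durations around 0.6–2 s and rates between about
3 and 22 per minute, so the fixed-profile assumption is a deliberate
simplification: it turns deconvolution into estimation of a modest number
of (onset, amplitude) pairs instead of an unconstrained activity trace, and
that constraint is what makes the inversion robust to measurement noise.

Skin conductance is the output of a linear time-invariant third-order ODE,
x''' + c₂x'' + c₁x' + c₀x = u, y = g·x, with characteristic roots −k₁, −k₂,
−k₃ (kᵢ > 0). Equivalently, y is u convolved with a stable kernel that is a
positive mixture of decaying exponentials — a rise over a few seconds and a
biphasic decay with a fast and a slow component, the shape reported for
electrodermal impulse responses. The realization is companion
(controller-canonical) form with the input entering the highest derivative,
so the system has relative degree 3 and h(0) = h'(0) = 0.

### Amplitude convention and gain calibration

`calibrate_gain` rescales g so that one unit-amplitude burst, placed
mid-epoch, produces a trace whose maximum on the 10 Hz output grid is
exactly 1 μS. Burst amplitudes are therefore "SF-peak equivalents": a burst
of amplitude a would alone produce an SF peaking at a μS, and the 0.1 μS
counting threshold applies to burst amplitudes without conversion.

### Default kernel parameters (synthetic provenance)

No empirically fitted coefficients are shipped. The default rate set
k = (2.0, 0.8, 0.2) s⁻¹ is a package-authored synthetic canonical choice:
time-to-peak ≈ 3.0 s, decay with time constants 1/k₂ = 1.25 s and
1/k₃ = 5 s, fully decayed (<10⁻³ of peak) well before 60 s. Users fitting
their own recordings should derive a canonical response function (CRF) with
`estimate_crf_fir` and refit via `fit_ode_to_crf`.

## Numerical integration

The linear system is discretized exactly with a first-order-hold
(piecewise-linear input) step at an internal rate of ≥100 Hz and integrated
by direct recursion, then decimated to the output rate. No adaptive-solver
tolerance enters, so traces are bit-stable across runs. The impulse
response is propagated on-grid with the matrix exponential. The test suite
checks the integrator against the discrete convolution of the Gaussian
input with the sampled impulse response (agreement better than 10⁻⁴ of the
peak across random stable kernels). Gaussians are truncated at ±5σ
(relative error < 10⁻⁵).

## Pre-processing

The chain follows standard electrodermal practice: a bidirectional
(zero-phase) first-order Butterworth low-pass at 5 Hz — which squares the
magnitude response, 1/(1+(f/f_c)²) — doubling as the anti-alias stage for
integer-factor decimation to 10 Hz; segmentation into 60-s closed-open
windows; and per-epoch subtraction of the segment minimum. Edge transients
are suppressed by reflect-padding about three filter time constants at each
end. Files carry no units; μS is assumed, with a scale factor available on
read. Sample k of a series is at t₀ + k/rate (0-based).

The recording-hardware high-pass (0.015 Hz) is emulated only implicitly:
the synthetic generator adds a bounded slow drift rather than an integrated
random walk, and the per-epoch minimum subtraction stands in for the
hardware baseline removal, as in the working convention the analysis
assumes.

## CRF estimation and kernel fitting

`estimate_crf_fir` is ordinary least squares on a lagged-indicator design:
each epoch's trace is modelled as the sum over its (known) onsets of one
shared FIR kernel (30 s window at 10 Hz by default, i.e. 300 coefficients).
The FIR window default is our choice — it must cover the SF decay while
keeping the design well conditioned; rank deficiency raises an error
advising longer data or a shorter window.

`fit_ode_to_crf` is a MAP fit of the three log-rates (Gaussian prior, mean
at the log of the initial rates, SD 1 log-unit — positivity and stability
for free) with the gain profiled out in closed form; the data weight is set
by an observation SD defaulting to 1% of the CRF peak, so the prior acts
only as a regularizer. Nelder-Mead from a deterministic start plus five
seeded jittered restarts; rates are returned sorted descending since the
kernel is invariant under pole permutation. When the CRF was estimated from
burst *onsets* (so it is the response to a whole Gaussian burst rather than
to an impulse), `input_sigma` smears the model response with the burst
waveform before comparison; omitting this biases the fast rates by ~6%,
which is why the round-trip benchmark passes it explicitly.

## Variational inversion

One candidate burst is allotted per 60/max_rate seconds (30 candidates for
a 60-s epoch), initial onsets at the bin centres. The posterior over
θ = (log-amplitudes, onsets) is Gaussian (variational Laplace); the noise
precision has a Gamma(10⁻², 10⁻²) prior and a conjugate mean-field update.
Priors: log-amplitude N(ln 0.01, 2²) — the prior-median burst produces a
negligible 0.01 μS fluctuation, so unused candidates cost nothing and
sustained activity can be absorbed by many small bursts; onsets
N(grid position, 1 s²).

Each iteration alternates (i) the exact mean-field update of the Gamma
precision posterior, (ii) the closed-form optimal Gaussian covariance
S = (E[λ]JᵀJ + Π₀)⁻¹, and (iii) a Levenberg-damped Gauss-Newton step on the
posterior mean accepted only if the free energy increases. Every sub-step
maximizes or cannot decrease the bound, so the recorded free-energy trace
is non-decreasing by construction (asserted in the tests to 10⁻⁸).
Convergence: per-iteration gain below 10⁻² nats, cap 200 iterations (the
result is then flagged unconverged, no exception). The expected residual
sum of squares under q(θ) is taken to second order through the local
linearization, rᵀr + tr(JSJᵀ); the Jacobian is analytic (convolution of the
kernel with the Gaussian basis and its μ-derivative, evaluated by FFT at a
2× oversampled internal grid).

Two discrete post-passes address known failure modes of purely local
ascent:

- **Merge proposals.** Two neighbouring candidates can split one burst's
  amplitude — a genuine local optimum, since the convex log-amplitude prior
  favours sharing and noise rewards slight offsets. Each close active pair
  (< 1 s apart) is tentatively replaced by a single burst with the summed
  amplitude at the amplitude-weighted onset (the displaced candidate
  returns to its prior), polished with a few Gauss-Newton steps, and kept
  only if the free energy improves. In the cases we examined the evidence
  does favour the merged model; the proposal just lets the optimizer reach
  it.
- **Window filtering.** The epoch floor is the *noise* minimum, so the true
  signal floor sits a few noise-SD above zero; the model explains this
  offset with a burst drifting before the window start. Such bursts (and
  any beyond the window end) are retained in the fitted trace but excluded
  from the reported train, whose onsets are guaranteed to lie inside the
  epoch.

Reported amplitudes are posterior medians exp(m_z) (robust for the broad
posteriors of unused candidates); amplitude SDs use the delta method, and
merged bursts combine SDs in quadrature. The returned train is sorted by
onset, ties broken by amplitude descending.

## Counting and validity statistics

`count_bursts` counts posterior bursts with amplitude ≥ threshold
(inclusive, so a burst at exactly 0.1 μS counts). `count_sf_conventional`
is an automatic stand-in for semi-visual event scoring: local maxima whose
rise from the preceding trough reaches the threshold (0.25 μS by
convention), with a 1-s minimum peak separation as a proxy for the human
scorer's smoothing. ROC curves sweep all integer count cutoffs with
(1−specificity, sensitivity) points and trapezoid AUC — equal to the
Mann-Whitney U statistic with ties counted half, which the tests verify
pairwise. The nested F-test is the extra-sum-of-squares comparison of
state ~ conventional versus state ~ conventional + model counts, with
df = (1, n−3); collinear predictors yield F = 0 with a warning. For
between-subject designs the per-subject arousal score is the mean
anticipation-epoch count minus the baseline count. Threshold sweeps accept
either a fixed conventional count vector or a per-threshold matrix
(`conventional_count_matrix`) so both arms can sweep their detection
threshold together.

## Synthetic studies

`generate_study` emulates the structure of a two-condition anticipatory-
anxiety experiment: per subject, baseline epochs at 6 bursts/min and
anticipation epochs at 12 bursts/min (both within the 3–22/min range
reported for sudomotor bursts; chosen as plausible, not taken from any
dataset), amplitudes uniform on [0.2, 1.0] μS, white measurement noise of
SD 0.05 μS, and a half-period sinusoidal drift of 0.1 μS. Onsets are a
Poisson process thinned to ≥1 s spacing so ground truth is unambiguous for
onset matching. All randomness flows from one seed through
`SeedSequence.spawn`, making studies bit-identical across runs. Default
size is 6 subjects × 4 epochs, which keeps a 20-replicate benchmark
affordable on one core.

What the generator does *not* emulate: motion artifacts, electrode drift
with random-walk statistics, the recording chain's 0.015 Hz high-pass
transfer function, non-uniform amplitude distributions, or any dependence
of burst shape on state. Passing benchmarks on these data therefore show
that the estimator is correct *under its own assumptions* and robust to
white noise and bounded drift — not that it reproduces results on any
laboratory dataset.

## Benchmark conditions and known limitations

The recovery benchmarks run at the stated conditions only: amplitudes
0.2–1.0 μS, 6 bursts/min, noise SD 0.02 μS (recovery and count fidelity,
drift absent since the conditions name only noise), and the full study
conditions above for the validity comparison. Observed behaviour worth
knowing:

- Bursts in the last ~1 s of an epoch produce almost no in-window response
  (the kernel rises over ~3 s) and are unrecoverable in principle; they are
  the main source of count disagreement.
- With drift present, slow baseline movement is partly absorbed as extra
  low-amplitude bursts near the 0.1 μS threshold, inflating counts — the
  model treats sustained conductance as sustained SNA by design.
- At counting thresholds near twice the noise SD the conventional
  trough-to-peak detector degrades sharply on unsmoothed traces (noise
  excursions cross the rise criterion), which is precisely the regime where
  the model-based count retains validity; the two-condition benchmark
  quantifies this contrast.
- The inversion estimates SNA given a *fixed* kernel; kernel parameters and
  SNA are not estimated jointly.
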