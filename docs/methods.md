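# Methods

## The model

`fiakit` describes the polyphasic rise (OJIP) of chlorophyll-a variable
fluorescence in a dark-adapted leaf or algal sample during a saturating
light pulse, and its decay after light-off, as the sum of three kinetic
components over the F_o = 1 baseline:

**Photochemical component F^PP.** Reaction centers (RCs) of photosystem II
close reversibly as the primary quinone acceptor Q_A is photoreduced at the
excitation rate k_L and re-oxidized by Q_B in the dark at k_AB.  For the
majority pool the closed fraction follows

    q0(t) = k_L/(k_L + k_AB) * (1 - exp(-(k_L + k_AB) t)),

the solution of dq/dt = k_L (1 - q) - k_AB q from q(0) = 0.  A fraction
β of Q_B-nonreducing RCs (k_AB ≈ 0) closes as qβ(t) = 1 - exp(-k_L t), and
the heterogeneous closed fraction is q = (1-β) q0 + β qβ.  The variable
fluorescence is F^PP1 = nF_v · q, where nF_v is the normalized variable
fluorescence at 100 % Q_A reduction.  In the β-pool a second excitation can
transiently double-reduce the acceptor pair (trapping efficiency Φ,
decaying at k_2AB), adding

    F^PP2 = β nF_v qβ(t) (1 - exp(-Φ k_L t)) exp(-k_2AB t),

which starts with zero value *and* zero slope, so the initial rise of
F^PP = F^PP1 + F^PP2 is exactly nF_v·k_L — independent of k_AB.  The
steady state is F^PP_ss = nF_v [(1-β) k_L/(k_L+k_AB) + β].  The β term is
retained in the steady state because the heterogeneous closure fraction
requires it; the homogeneous (β = 0) case reduces to nF_v k_L/(k_L+k_AB),
and k_AB = 0 (DCMU-like blockage) gives the full nF_v.

**Photo-electrochemical component F^PE** (J–I phase, ~2–50 ms).  A
first-order conversion with forward rate k_qbf (attributed to lumenal
proton-transfer reactions at the Q_A–Q_B site) and reversal k_-qbf.  With
E(t) = 1 - exp(-(k_qbf+k_-qbf) t) and R = k_qbf/(k_qbf+k_-qbf),

    F^PE = nF_v · E R · (1 + (1 - q(t)) · E R).

**Photo-electric component F^CET** (I–P phase, ~50–500 ms), attributed to
the proton-motive force built by PSI-driven cyclic electron transport.
Its sigmoidal delay-then-rise is modelled as an N_IP-stage first-order
cascade (tanks-in-series): F^CET = IP_amp · P(N_IP, k_IP t), where P is
the regularized lower incomplete gamma function (the Erlang CDF).  The
integer N_IP ∈ (0, 10) controls both delay and steepness; N_IP = 1 is a
plain saturating exponential.  This functional family was chosen because a
single integer must tune sigmoidicity while every parameter keeps a rate
interpretation — unlike the Chapman-Richards sigmoid, whose shape exponent
has no kinetic meaning.  The form is isolated behind one function
(`f_cet`) so it can be swapped.

The full curve is F^FIA(t) = 1 + F^PP + F^PE + F^CET.  Each component is
an increment that vanishes at t = 0; the baseline enters exactly once.
Connectivity between photosynthetic units and donor-side quenching are
assumed negligible throughout.

**Quantum-yield expression.**  `fluor_yield` exposes the three-quenching
yield model Φ_f = 1/(1 + k_w/k_f + [θ1(k_e+k_y) + θ2 k_y + k_d]/(k_f N)
· exp(ψ0 - ψ)), with the Boltzmann factor expressing photo-electric
control by the membrane potential ψ (RT/F units).  It is provided for
qualitative reasoning (monotone in ψ; open centers gain more from a
potential rise than closed ones) and is never fitted to data.

## Units and conventions

Time in ms, rates in ms⁻¹, fluorescence normalized to F_o = 1 (the
earliest resolvable sample of a pulse, nominally 0.01 ms).  Light
intensity maps to excitation rate linearly, k_L = intensity/2000 ms⁻¹ by
default (≈1 ms⁻¹ at 2000 µmol photons m⁻² s⁻¹), user-overridable.

## Default parameters (worked example)

The package's reference parameter set describes a Kalanchoë leaf at
3000 µmol photons m⁻² s⁻¹: k_L = 1.5, k_AB = 2.8 ms⁻¹, nF_v = 2,
β = 0.15, Φ = 0.15, k_2AB = 0.2 ms⁻¹; thermal phase k_qbf = 0.1,
k_-qbf = 0.01 ms⁻¹, IP_amp = 0.45 F_o units, k_IP = 0.02 ms⁻¹, N_IP = 3,
k_-IP = 0.001 ms⁻¹.  With these values F^PP_ss ≈ 0.89 (closed fraction
0.45), the model maximum is F_m/F_o ≈ 5.1, and the OJIP ordering
F(2 ms) < F(30 ms) < F(500 ms) holds with the P level inside 4.5–5.5.
The J plateau of the model sits at ≈2.35 at 2 ms and enters the
2.5–3.5 band by 3 ms; the J inflection spans 2–3 ms.

An extra rate, `k_slow` (default 0.02 ms⁻¹), sets the dark relaxation of
the closed β-pool — the slow component of short-pulse decay tails.  It is
carried in `PhotochemParams` because the simulator and the decomposition
need it, although it is not part of the two-pulse estimator chain.

## Estimation procedures

**Multi-exponential deconvolution** (`fit_multiexp`).  Dark decays are
fitted by Σ a_j exp(-k_j t) (1–4 terms, optional constant offset, off by
default since instrument records are baseline-anchored) with non-negative
amplitudes, time restarted at light-off so amplitudes extrapolate to the
light-off instant.  The solver is variable projection: bounded nonlinear
least squares over log-rates with amplitudes solved by non-negative
linear least squares at every step, restarted from 8 deterministic
log-spaced initializations spanning 0.01–10 ms⁻¹ (seeded jitter, default
seed 0).  Rates within 5 % after fitting are merged and the fit re-run
with one fewer component, preventing spurious splitting.  Convergence:
1e-10 on the cost, ≤1e4 evaluations per start; non-convergence is flagged
in the result, never silent.

**Initial slope** (`initial_slope`).  The t = 0 tangent of the rise is
estimated by a quadratic-through-origin fit of F_rel - 1 over
0.01–0.1 ms; the quadratic term absorbs the exponential curvature already
present in that window (a straight-line fit underestimates the tangent by
~20 % at k_L + k_AB ≈ 4.3 ms⁻¹, which would propagate directly into k_L).
`degree=1` recovers the plain linear slope.  The reported reciprocal is
1/slope — the time at which the tangent through (0, F_o) reaches a unit
rise of ΔF/F_o, the classic graphical construction.

**Two-pulse analysis** (`two_pulse_analysis`, `TwoPulseModel`).  From a
short saturating pulse (default 0.25 ms + 20 ms dark tail) and a long
pulse (1 s): nF_v = (F_m - 1)/2 from the long-pulse maximum (running-mean
smoothed, plateau-checked); k_L = slope/nF_v; k_AB = k_1 of a
3-exponential tail fit; β = a_slow/(nF_v (1 - exp(-k_L t_0))), the
denominator correcting for incomplete photoreduction of the β-pool during
the pulse.  Two refinements follow:

1. *Thermal correction loop* (2 iterations): the slowly-reversing thermal
   components contribute both to the initial slope (a nF_v·k_qbf term)
   and to the slow tail amplitude (F^PE at light-off ≈ 0.05 F_o units
   under the default conditions, i.e. ~40 % of a_slow).  The SP trace is
   decomposed, the predicted contributions subtracted, and k_L and β
   re-estimated; Φ and k_2AB are then tuned at the O–J/J–I junction
   (0.5–1.5 ms), matching F^PP + F^PE against F^exp with k_AB allowed
   ±20 % of its decay-fit value.
2. *Joint polish*: a bounded least-squares fit of the full model to both
   records simultaneously (relative residuals — the measurement noise is
   multiplicative), multi-started over the weakly identified (Φ, k_2AB)
   pair.  Fitting the SP curve alone leaves a k_L·nF_v compensation
   ridge; the sSP rise and tail break it.  On noiseless synthetic data
   this pass recovers every parameter to machine precision.

**Sequential decomposition** (`decompose_ojip`, `OJIPDecomposition`).
Given photochemical parameters: F^PP is computed; (k_qbf, k_-qbf) fitted
to F^exp - 1 - F^PP over 0–50 ms; IP_amp set to
F_m - (1 + F^PP_ss + F^PE_ss); (k_IP, N_IP) fitted to the remaining
residual over 30–700 ms with N_IP searched exhaustively over 1–9.  Two
passes subtract the fitted I–P component before re-fitting the J–I rates
(their windows overlap), and a final joint fit of the four continuous
thermal parameters (N_IP fixed) against the photochemically corrected
curve removes the remaining window coupling — a self-consistent curve
then decomposes to machine precision.  Negative residual amplitudes are
clamped at zero and flagged.  All windows are configurable.

## The simulator and what it does (not) emulate

`simulate` produces instrument-style records for arbitrary light/dark
protocols: sampling steps of 0.01 ms (10 µs) to 1 s, pulses of 0.25 ms to
tens of seconds, intensities mapped to k_L.  Component states are
propagated analytically across segments (closure pools relax toward their
segment equilibria; the F^PE occupancy follows its own first-order
relaxation; the Erlang cascade advances by effective-time inversion), so
the closed forms are reproduced exactly from dark-adapted starts and
traces are continuous at every light↔dark boundary.  In the dark each
component decays with its own rate: k_AB (fast photochemical), k_slow
(closed β-pool), k_2AB (double-reduced pool), k_-qbf (F^PE), k_-IP
(F^CET).  The second-hit term restarts its clock only from a fully
relaxed state; rapid on/off cycling that re-lights a partially decayed
β-pool is treated approximately (documented in the code).  Between the
two default pulses a dark interval of a few seconds (default 5 s) is
assumed to re-open the fast components completely; residual
slow-component occupancy defaults to zero.

Noise is multiplicative Gaussian (relative sd, default 0.5 % — instrument
averages of a few samples are smooth), applied last and fully determined
by the seed.  The simulator does *not* model shot noise or detector
physics, actinic gradients within the leaf, PSMT decay beyond ~1.3 s,
connectivity, or donor-side quenching.  Passing recovery tests on these
traces therefore demonstrates correctness of the estimators under the
model's own assumptions, not robustness to real-leaf systematics
(baseline drift, reabsorption, non-exponential heterogeneity).

## Numerical choices

* Rates enter fits on a log scale with bounds 1e-4–50 ms⁻¹ (decay) and
  1e-6–10 ms⁻¹ (thermal); amplitudes are non-negative.
* Saturating exponentials use `expm1`; when a total rate underflows, the
  first-order series limit is returned instead of 0/0.
* Ties in junction tuning favour the incoming parameter values, so an
  exact fit is a fixed point.
* F_m detection widens its running mean with record length (window
  ≥ n/100 samples): the maximum of thousands of lightly smoothed noisy
  samples is otherwise biased upward by extreme-value statistics.
* The plateau check compares the means of the last two tenths of the
  pulse (trend), not the within-noise range.

## Known limitations

* **Identifiability at realistic noise.**  A Cramér–Rao analysis at the
  default study conditions (two-pulse protocol, 1 % multiplicative noise)
  gives asymptotic relative standard deviations of ≈36 % for Φ and ≈55 %
  for k_-qbf — their fluorescence signatures are small (F^PP2 peaks at
  ~0.07 F_o units) or nearly redundant (k_-qbf enters mainly through
  k_qbf + k_-qbf ≈ k_qbf).  Observed median errors of the pipeline sit at
  this bound, i.e. the estimator is essentially efficient; no estimator
  can do materially better from these two records.  All other parameters
  recover with median errors below ~6 % at 1 % noise.
* F^PE's dark reversal is a single exponential at k_-qbf, continuous at
  light-off; the in-light cross term with the closed fraction is frozen
  at its light-off value rather than allowed to relax.
* The steady state of the F^PE expression with the default parameters is
  ≈2.7 F_o units; treated as a property of the closed form as
  implemented.
* The Erlang-cascade form of F^CET is a documented modelling choice, not
  a mechanistic derivation; swap `f_cet` to explore alternatives.
* The routine reports the fast decay rate per pulse duration
  (`kab_vs_duration`) without asserting a direction of change; the
  direction depends on the light-driven pH shift at the acceptor side and
  is an empirical question.
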