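# Methods

## The model

`t5model` simulates the sub-threshold voltage of a directionally selective
visual neuron (the T5 cell of the *Drosophila* OFF motion pathway) as a
passive, single-compartment, conductance-based membrane. Membrane
integration is taken as instantaneous (τ = 0): with all conductances in
units of the leak conductance, the voltage is the algebraic balance

    V − Vb = (VE − Vb) · ΔG / ΣG

where ΔG is the *integrated conductance* (depolarizing minus weighted
hyperpolarizing drive) and ΣG the *total conductance* (the divisive
normalization). Three mechanisms for the hyperpolarizing arm are
implemented:

* **EI** (direct inhibition): stimulus-driven excitatory E(t) and
  inhibitory I(t) conductances, no tonic conductances, baseline at the
  leak reversal. ΔG = E − αI, ΣG = 1 + E + I, with
  α = (VL − VI)/(VE − VL) the relative inhibitory driving force.
* **E+E−** (removal of excitation): hyperpolarization arises by removing
  conductance E−(t) from a tonic excitatory conductance gE*, balanced by a
  tonic inhibitory conductance gI* = gE*/α chosen so the baseline voltage
  equals the leak reversal exactly. E− is rectified at gE* — a conductance
  can only be removed while it is open — and both stimulus conductances
  are normalized by 1 + gE* + gI*. ΔG = E+′ − E−′, ΣG = 1 + E+′ − E−′.
  The rectification implies a closed-form ceiling on the normalized
  removed conductance, E−′ ≤ gE*/(1 + gE* + gE*/α) < 1: hyperpolarization
  by removal is intrinsically bounded.
* **Scaled-EI**: an EI model that inherits the E+E− model's filters
  (E ← E+, I ← E−) with scaling coefficients CE = 1/(1 + gE* + gI*) and
  CI = 1/(α(1 + gE* + gI*)) chosen so its numerator ΔG equals the E+E−
  model's for *any* stimulus. The two models then differ only in the
  denominator — ΣG sums the conductances in Scaled-EI but subtracts them
  in E+E− — which isolates the normalization difference between the two
  mechanisms. By default the E− rectification is applied before the I
  channel inherits the trace, so ΔG matches the rectified E+E− numerator
  exactly; `rectify=False` gives the unrectified alternative.

Each channel's conductance k(t) is the output of two first-order low-pass
filters in series (rise constant τR, decay constant τD) driven by the
stimulus projected onto a Gaussian spatial receptive field
R(x) = A·exp(−(x − μ)²/2σ²). The stimulus S(x, t) is binary: a dark bar
of width one present/absent at integer position x along the cell's
preferred/null-direction (PD–ND) axis; position 0 is the empirically
strongest depolarizing flash location, positive positions the trailing
side. The Gaussians are not normalized to unit area — the amplitude
parameter carries the conductance scale.

Absolute reversal potentials are degenerate with channel amplitudes in
any fit, so the membrane frame is fixed at VL = −60 mV, VE = 0 mV,
VI = −75 mV (α = 0.25) and only α varies during fitting (moving VI);
the excitatory driving force VE − VL = 60 mV is never fitted.

## Numerics

The filter cascade is linear and the stimulus is piecewise constant on
the sample grid, so the exact solution is available: the zero-order-hold
discretization of the two-filter cascade reduces to a second-order IIR
filter whose coefficients we derive in closed form (equal time constants
fall back to the alpha-function limit; the switch triggers below a
relative τ difference of 1e−9). This exact path (`integrator="analytic"`)
is the default. A 4th-order Runge-Kutta integrator of the same ODE pair
is implemented independently and agrees with the exact solution to better
than 1e−6 relative error at dt = 0.1 ms over the full protocol battery;
the test suite additionally cross-checks the hand-derived IIR
coefficients against `scipy.signal.cont2discrete`'s matrix-exponential
discretization.

The two cascade filters commute, so (τR, τD) are identifiable only up to
exchange within a channel; fitted pairs are reported in ascending order
(rise ≤ decay) to make the solution unique.

Default simulation step is dt = 1 ms (fits and protocol simulations);
oracle comparisons use dt = 0.1 ms. Stimulus ON intervals are half-open
[onset, onset + duration) on the grid; movies get 200 ms pre-stimulus
padding (baseline window) and 500 ms post (conductance decay).

## Fitting

Parameters are estimated by multistart bounded nonlinear least squares on
baseline-subtracted mean flash-response traces — canonically width-2 bar
flashes only, the training set that contains no motion information. Each
restart draws a uniform initial point inside the bounds from a seed
derived from (master seed, restart index), then runs SciPy's trust-region
reflective least-squares with ftol = xtol = 1e−8 and at most 500 function
evaluations; restarts are ranked by summed squared error and the top 1%
(ceil) retained for held-out prediction. Default bounds: τR, τD ∈ [1, 500] ms,
A ∈ [0, 20] leak units, μ ∈ [−8, 8] positions, σ ∈ [0.3, 5] positions,
α ∈ [0.05, 5], gE* ∈ [0.05, 10]. The loss is the plain sum of squared
voltage errors across stimuli and samples; no per-stimulus weighting.

Problem sizes in the validation suite: recovery studies use 100 restarts
(the canonical workflow uses 1000; on noiseless synthetic data the
recovery objective is well behaved and most restarts reach the global
basin, so 100 is redundant) and the E+E− comparison uses 50.

## Response metrics

All metrics operate on uniform-grid traces and are pure functions.

* **Trial QC**: a trial is kept iff its pre-stimulus mean is within 10 mV
  of the pooled pre-stimulus mean of its stimulus group, and within 15 mV
  (25 mV for slow moving bars, whose responses are strong and long) of
  its own whole-trial mean. "Overall mean" is read as the whole-trial
  mean.
* **Robust peak**: the 0.995 quantile within the stimulus window
  (linear-interpolation estimator), used for DSI = (PDmax − NDmax)/PDmax.
  DSI is undefined (nan) when PDmax ≤ 0.
* **Flash-response detection**: depolarization is the 0.995 quantile in
  [onset, onset + duration + 75 ms], zeroed unless it exceeds
  {2.5, 2.7, 2.9}× the baseline SD for widths {1, 2, 4}; hyperpolarization
  mirrors this with the 0.005 quantile, the window extended to the trace
  end (slower time course), and thresholds {1.5, 1.7, 1.9}. Baseline SD
  comes from a Gaussian fit to pooled pre-stimulus samples (sample-SD
  fallback available); a degenerate zero-variance baseline is floored at
  1e−6 mV.
* **Timing**: rise start = onset → 10% of peak, rise time = 10% → 50%,
  decay time = 80% → 20% after the peak, all linearly interpolated;
  uncrossed levels yield nan.
* **Superposition**: the linear prediction for a composite stimulus is
  the sum of zero-padded component flash responses shifted to the times
  their positions appear in the composite.
* **Peak MAD**: per-trial maxima within a 100 ms window centred on the
  mean-trace peak (clipped at edges); MAD is the mean absolute deviation
  from the mean-trace peak.
* **Grating fits**: amplitude/phase by linear least squares on cosine and
  sine regressors at the stimulus temporal frequency (fixed, not fitted),
  after dropping the first cycle to remove the appearance transient. The
  raw phase lies in (−π, π]; a display convention in (−2π, π] is exposed
  separately.

## Synthetic data

The generator produces the study conditions the analysis assumes: the
full stimulus battery (flashes of widths 1/2/4 × 40/160 ms at 13
positions; fixed-speed width-2 bar pairs and the width-4
immediate-succession configuration; moving bars of widths 1/2/4 at
40/80/160 ms steps in both directions over 9 positions; 8 grating-flash
phases × 2 durations; drifting gratings at 2 speeds × 2 start phases × 2
directions), with 5 repeats for single-bar flashes and 3 for everything
else, a resting baseline of −58 mV, and iid per-sample Gaussian noise of
1 mV SD. Optional drift trials add a constant offset of 12–30 mV
(random sign) to a configurable fraction of trials — the minimal
structure the QC rules detect. Noise is iid Gaussian because trial
variability enters the analysis only through the peak MAD; no 1/f or
synaptic noise is modelled, so passing tests say nothing about
structured noise in real recordings.

Ground-truth archetypes draw parameters inside the fitting bounds with
the ordering constraints that define them. The trailing-inhibition
archetype encodes the measured receptive-field structure — fast, broad,
near-centered excitation (τR 8–15 ms, τD 25–45 ms, A 3–6, μ −0.5…−0.2,
σ 1.5–2.5) and slow, narrow, trailing-side inhibition (τR 30–60 ms,
τD 90–150 ms, A 4–8, μ 1–2, σ 0.8–1.4), α 0.2–0.35. Ranges keep every
parameter bounded away from zero so that *relative* recovery error is
well defined for all of them. The `epem` archetype uses the same filter
ranges with gE* 0.8–2; `symmetric_null` centres both fields at 0 with
equal widths, a mirror-symmetric construction whose moving-bar DSI is
exactly 0.

## Design choices on genuinely open points

* Preferred direction on synthetic data is the direction of the larger
  robust peak (ties toward the lower direction index), replacing the
  by-eye estimate used with real cells.
* The "overall mean" in the QC rule is the whole-trial mean (not
  post-stimulus only).
* The cosine-fit frequency is fixed to the stimulus temporal frequency.
* The Scaled-EI construction matches the *rectified* E+E− numerator by
  default (flag for the unrectified alternative).
* The moving bar is defined as the logical OR of its per-position
  flashes: each swept position is ON for width × step ms, so a width-w
  sweep of n positions lasts (n − 1 + w) × step ms.
* Wide bars are anchored at their leftmost pixel (the position index
  refers to the leading-edge-side pixel at stimulus construction time).

## Limitations

* Single compartment, passive, graded signalling only: no spikes, no
  dendritic cable, no voltage-to-calcium transformation.
* The receptive field is one-dimensional along the PD–ND axis; bar
  height and off-axis structure are not modelled, and the diagonal-axis
  angular correction is reduced to the step-count rule
  (ceil(n·√2) diagonal steps per n cardinal steps).
* Stimuli are binary OFF patterns; background and intermediate luminance
  are not represented.
* Synthetic validation demonstrates correctness of the machinery and the
  qualitative mechanism ordering; quantitative agreement with real
  recordings requires fitting the deposited data, which this package
  reads in its generic CSV layout but does not ship.
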