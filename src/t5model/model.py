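"""Single-compartment conductance models of T5 directional selectivity.

The membrane is passive (integration time constant taken as zero), so the
voltage is an instantaneous algebraic function of the stimulus-driven
conductances, each expressed in units of the leak conductance:

    V - Vb = (VE - Vb) * dG / sG

with an integrated conductance ``dG`` (depolarizing minus weighted
hyperpolarizing drive) and a total conductance ``sG`` (the divisive
normalization term). Three variants differ only in how the hyperpolarizing
drive enters:

* **EI** - direct inhibition:  dG = E - alpha*I,  sG = 1 + E + I.
* **E+E-** - removal of excitation from a tonic conductance gE*, balanced
  by a tonic inhibitory conductance gI* = gE*/alpha so the baseline stays
  at the leak reversal:  dG = E+' - E-',  sG = 1 + E+' - E-' where primes
  denote normalization by (1 + gE* + gI*) and E- is rectified at gE*.
* **Scaled-EI** - an EI model inheriting the E+E- filters, with the E and I
  conductances rescaled so its numerator dG matches the E+E- model exactly;
  only the normalizing denominator differs between the two.

Each stimulus-driven conductance ``k(t)`` is produced by a cascade of two
first-order low-pass filters (rise and decay time constants) driven by the
projection of the binary stimulus onto a Gaussian spatial receptive field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.signal import lfilter

from .stimuli import StimulusMovie

__all__ = [
    "ChannelParams",
    "MembraneFrame",
    "EIParams",
    "EpEmParams",
    "ScaledEIParams",
    "ConductanceTraces",
    "VoltageTrace",
    "spatial_rf",
    "stimulus_drive",
    "channel_conductance",
    "voltage_EI",
    "voltage_EpEm",
    "e_minus_bound",
    "scale_EI_from_EpEm",
    "simulate",
]


# ---------------------------------------------------------------------------
# parameter containers

@dataclass
class ChannelParams:
    """One conductance channel: temporal filter cascade + spatial RF.

    ``tau_rise_ms``/``tau_decay_ms`` are the time constants of the two
    first-order filters in series; ``amplitude`` (leak-conductance units),
    ``center`` and ``width`` (position units) define the Gaussian
    receptive field A*exp(-(x-mu)^2 / (2 sigma^2)).
    """

    tau_rise_ms: float
    tau_decay_ms: float
    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.tau_rise_ms <= 0 or self.tau_decay_ms <= 0:
            raise ValueError("time constants must be strictly positive")
        if self.width <= 0:
            raise ValueError("RF width sigma must be strictly positive")
        if self.amplitude < 0:
            raise ValueError("RF amplitude must be non-negative")


@dataclass
class MembraneFrame:
    """Reversal potentials of the passive membrane.

    Absolute reversal potentials are degenerate with conductance amplitudes
    in any fit, so the frame is fixed and only ``alpha`` — the relative
    inhibitory driving force (VL - VI) / (VE - VL) — varies. Defaults are
    physiological: VL = -60, VE = 0, VI = -75 mV, giving alpha = 0.25.
    """

    v_leak_mV: float = -60.0
    v_exc_mV: float = 0.0
    v_inh_mV: float = -75.0
    tau_membrane_ms: float = 0.0

    def __post_init__(self) -> None:
        if not self.v_inh_mV < self.v_leak_mV < self.v_exc_mV:
            raise ValueError("require VI < VL < VE")
        if self.tau_membrane_ms != 0.0:
            raise NotImplementedError(
                "only the instantaneous membrane (tau = 0) is implemented")

    @property
    def alpha(self) -> float:
        return (self.v_leak_mV - self.v_inh_mV) / (self.v_exc_mV - self.v_leak_mV)

    @property
    def driving_force_mV(self) -> float:
        """Excitatory driving force at baseline, VE - VL."""
        return self.v_exc_mV - self.v_leak_mV

    @classmethod
    def from_alpha(cls, alpha: float, v_leak_mV: float = -60.0,
                   v_exc_mV: float = 0.0) -> "MembraneFrame":
        """Build a frame with a given alpha by placing VI accordingly."""
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        v_inh = v_leak_mV - alpha * (v_exc_mV - v_leak_mV)
        return cls(v_leak_mV=v_leak_mV, v_exc_mV=v_exc_mV, v_inh_mV=v_inh)


@dataclass
class EIParams:
    """Direct-inhibition variant: stimulus-driven E and I, no tonic
    conductances, baseline at the leak reversal."""

    exc: ChannelParams
    inh: ChannelParams
    frame: MembraneFrame = field(default_factory=MembraneFrame)

    variant = "ei"


@dataclass
class EpEmParams:
    """Removal-of-excitation variant.

    ``g_e_star`` is the tonic excitatory conductance from which the E-
    channel removes conductance; the tonic inhibitory conductance is tied
    to it (gI* = gE*/alpha) so the baseline voltage equals the leak
    reversal exactly and alpha' = alpha.
    """

    e_plus: ChannelParams
    e_minus: ChannelParams
    g_e_star: float
    frame: MembraneFrame = field(default_factory=MembraneFrame)

    variant = "epem"

    def __post_init__(self) -> None:
        if self.g_e_star <= 0:
            raise ValueError("g_e_star must be strictly positive")

    @property
    def g_i_star(self) -> float:
        return self.g_e_star / self.frame.alpha

    @property
    def tonic_norm(self) -> float:
        """Normalizer 1 + gE* + gI* applied to the stimulus conductances."""
        return 1.0 + self.g_e_star + self.g_i_star


@dataclass
class ScaledEIParams:
    """EI model inheriting the filters of an E+E- model, with the E and I
    conductances scaled (coefficients ``c_e``, ``c_i``) so that the
    numerator conductances match the E+E- model's depolarizing and
    hyperpolarizing terms for any stimulus.

    ``rectify`` controls whether the E- rectification bound of the source
    model is re-applied inside the inherited hyperpolarizing channel
    (default: yes, matching the already-rectified numerator).
    """

    base: EpEmParams
    c_e: float
    c_i: float
    rectify: bool = True

    variant = "scaled_ei"

    @property
    def frame(self) -> MembraneFrame:
        return self.base.frame


ModelParams = EIParams | EpEmParams | ScaledEIParams


# ---------------------------------------------------------------------------
# outputs

@dataclass
class VoltageTrace:
    """Membrane potential relative to baseline, on a uniform time grid."""

    t_ms: np.ndarray
    v_mV: np.ndarray
    dt_ms: float
    baseline_mV: float | None = None

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.v_mV = np.asarray(self.v_mV, dtype=float)
        if self.t_ms.shape != self.v_mV.shape:
            raise ValueError("time and voltage arrays must have equal length")
        if not np.all(np.isfinite(self.v_mV)):
            raise ValueError("voltage trace contains non-finite values")

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.t_ms, self.v_mV]),
                   delimiter=",", header="t_ms,v_mV", comments="")


@dataclass
class ConductanceTraces:
    """Conductance decomposition of a simulation.

    ``channels`` holds the raw filter-cascade outputs per channel name;
    ``g_dep``/``g_hyp`` are the (normalized, rectified where applicable)
    depolarizing and hyperpolarizing conductances entering the voltage
    equation; ``delta_g`` and ``sigma_g`` are the integrated and total
    conductances of ``V - Vb = (VE - Vb) * delta_g / sigma_g``.
    """

    channels: dict[str, np.ndarray]
    g_dep: np.ndarray
    g_hyp: np.ndarray
    delta_g: np.ndarray
    sigma_g: np.ndarray
    alpha: float


# ---------------------------------------------------------------------------
# building blocks

def spatial_rf(channel: ChannelParams, positions: np.ndarray) -> np.ndarray:
    """Gaussian receptive-field weights A*exp(-(x-mu)^2/(2 sigma^2)).

    No normalization to unit area: the amplitude parameter carries the
    conductance scale.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("positions must be nonempty")
    z = (positions - channel.center) / channel.width
    return channel.amplitude * np.exp(-0.5 * z * z)


def stimulus_drive(channel: ChannelParams, movie: StimulusMovie) -> np.ndarray:
    """Input time series I_stim(t) = sum_x R(x) S(x, t)."""
    weights = spatial_rf(channel, movie.positions)
    return weights @ movie.values


def _cascade_coeffs(tau_r: float, tau_d: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact discrete-time (zero-order-hold) transfer function of the
    two-filter cascade for piecewise-constant input on the dt grid.

    From the per-step closed form
        h[n+1] = eR h[n] + (1-eR) I[n]
        k[n+1] = c  h[n] + eD k[n] + (1 - eD - c) I[n]
    with eR = exp(-dt/tauR), eD = exp(-dt/tauD) and the cross-coupling
    c = tauR (eR - eD) / (tauR - tauD) (limit (dt/tau) e^{-dt/tau} for
    equal time constants, the alpha-function case).
    """
    e_r = np.exp(-dt / tau_r)
    e_d = np.exp(-dt / tau_d)
    if abs(tau_r - tau_d) < 1e-9 * max(tau_r, tau_d):
        c = (dt / tau_r) * e_r
    else:
        c = tau_r * (e_r - e_d) / (tau_r - tau_d)
    b1 = 1.0 - e_d - c
    b2 = c * (1.0 - e_r) - e_r * b1
    b = np.array([0.0, b1, b2])
    a = np.array([1.0, -(e_r + e_d), e_r * e_d])
    return b, a


def _cascade_analytic(tau_r: float, tau_d: float, drive: np.ndarray,
                      dt: float) -> np.ndarray:
    """Exact solution of the filter cascade for sample-and-hold input,
    evaluated as a second-order IIR filter from zero initial conditions."""
    b, a = _cascade_coeffs(tau_r, tau_d, dt)
    return lfilter(b, a, drive)


def _cascade_rk4(tau_r: float, tau_d: float, drive: np.ndarray,
                 dt: float) -> np.ndarray:
    """4th-order Runge-Kutta integration of the cascade ODEs

        tauR dh/dt = -h + I(t),   tauD dk/dt = -k + h

    with the input held constant over each dt interval.
    """
    n = drive.size
    out = np.empty(n)
    h = 0.0
    k = 0.0
    inv_r = 1.0 / tau_r
    inv_d = 1.0 / tau_d
    out_local = out
    for i in range(n):
        out_local[i] = k
        u = drive[i]
        # k1..k4 for the coupled pair (h, k)
        dh1 = (u - h) * inv_r
        dk1 = (h - k) * inv_d
        h2 = h + 0.5 * dt * dh1
        k2 = k + 0.5 * dt * dk1
        dh2 = (u - h2) * inv_r
        dk2 = (h2 - k2) * inv_d
        h3 = h + 0.5 * dt * dh2
        k3 = k + 0.5 * dt * dk2
        dh3 = (u - h3) * inv_r
        dk3 = (h3 - k3) * inv_d
        h4 = h + dt * dh3
        k4 = k + dt * dk3
        dh4 = (u - h4) * inv_r
        dk4 = (h4 - k4) * inv_d
        h += dt * (dh1 + 2 * dh2 + 2 * dh3 + dh4) / 6.0
        k += dt * (dk1 + 2 * dk2 + 2 * dk3 + dk4) / 6.0
    return out


Integrator = Literal["analytic", "rk4"]


def channel_conductance(channel: ChannelParams, drive: np.ndarray,
                        dt_ms: float, integrator: Integrator = "analytic") -> np.ndarray:
    """Conductance time series k(t) of one channel for a given input drive.

    ``analytic`` uses the exact solution for piecewise-constant input (the
    default and the oracle); ``rk4`` integrates the ODE pair numerically
    with a 4th-order Runge-Kutta scheme, input held constant per sample.
    Both start from rest (h = k = 0); the conductance at sample n reflects
    the input up to (not including) sample n, i.e. a one-sample transport
    delay consistent with causal sample-and-hold integration.
    """
    drive = np.asarray(drive, dtype=float)
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    if integrator == "analytic":
        # lfilter's b[0] = 0 gives exactly the one-step-delayed exact update
        return _cascade_analytic(channel.tau_rise_ms, channel.tau_decay_ms, drive, dt_ms)
    if integrator == "rk4":
        return _cascade_rk4(channel.tau_rise_ms, channel.tau_decay_ms, drive, dt_ms)
    raise ValueError(f"unknown integrator {integrator!r}")


# ---------------------------------------------------------------------------
# voltage equations

def voltage_EI(params: EIParams, exc: np.ndarray, inh: np.ndarray) -> np.ndarray:
    """EI membrane equation: V - VL = (VE - VL)(E - alpha I)/(1 + E + I).

    Returns voltage relative to the leak reversal (= baseline), in mV.
    """
    exc = np.asarray(exc, dtype=float)
    inh = np.asarray(inh, dtype=float)
    alpha = params.frame.alpha
    return params.frame.driving_force_mV * (exc - alpha * inh) / (1.0 + exc + inh)


def voltage_EpEm(params: EpEmParams, e_plus: np.ndarray,
                 e_minus_raw: np.ndarray) -> np.ndarray:
    """E+E- membrane equation with the removed conductance rectified.

    E- is clipped at the tonic conductance gE* (a conductance can only be
    removed while it is open), both channels are normalized by
    1 + gE* + gI*, and V - Vb = (VE - Vb)(E+' - E-')/(1 + E+' - E-').
    The tie gI* = gE*/alpha pins the baseline at the leak reversal.
    """
    e_plus = np.asarray(e_plus, dtype=float)
    e_minus = np.minimum(np.asarray(e_minus_raw, dtype=float), params.g_e_star)
    norm = params.tonic_norm
    ep = e_plus / norm
    em = e_minus / norm
    return params.frame.driving_force_mV * (ep - em) / (1.0 + ep - em)


def e_minus_bound(g_e_star: float, alpha: float) -> float:
    """Upper bound on the normalized removed conductance E-',

        E-' <= gE* / (1 + gE* + gE*/alpha) < 1,

    the intrinsic ceiling on hyperpolarization in the E+E- mechanism.
    """
    if g_e_star <= 0 or alpha <= 0:
        raise ValueError("g_e_star and alpha must be positive")
    return g_e_star / (1.0 + g_e_star + g_e_star / alpha)


def scale_EI_from_EpEm(epem: EpEmParams, rectify: bool = True) -> ScaledEIParams:
    """Construct the Scaled-EI model from a fitted E+E- model.

    The E channel inherits the E+ filters, the I channel the E- filters.
    The scaling coefficients make the EI numerator terms equal the E+E-
    numerator terms for any stimulus: c_e = 1/(1 + gE* + gI*) maps E+ onto
    E+', and c_i = 1/(alpha (1 + gE* + gI*)) maps E- onto E-'/alpha so
    that alpha * (c_i E-) = E-'. The integrated conductance dG is then
    identical between the two models by construction, while the total
    conductance sums rather than subtracts the hyperpolarizing term.
    """
    norm = epem.tonic_norm
    alpha = epem.frame.alpha
    return ScaledEIParams(base=epem, c_e=1.0 / norm, c_i=1.0 / (alpha * norm),
                          rectify=rectify)


# ---------------------------------------------------------------------------
# full simulation

def simulate(params: ModelParams, movie: StimulusMovie,
             integrator: Integrator = "analytic") -> tuple[VoltageTrace, ConductanceTraces]:
    """Simulate the membrane response of a model variant to a stimulus.

    Composes stimulus drive -> filter cascade per channel -> variant
    voltage equation, and returns both the voltage (relative to baseline)
    and the dG/sG conductance decomposition.
    """
    dt = movie.dt_ms
    t = movie.t_ms
    frame = params.frame
    alpha = frame.alpha

    if isinstance(params, EIParams):
        e = channel_conductance(params.exc, stimulus_drive(params.exc, movie), dt, integrator)
        i = channel_conductance(params.inh, stimulus_drive(params.inh, movie), dt, integrator)
        delta_g = e - alpha * i
        sigma_g = 1.0 + e + i
        channels = {"E": e, "I": i}
        g_dep, g_hyp = e, i
    elif isinstance(params, EpEmParams):
        ep_raw = channel_conductance(params.e_plus, stimulus_drive(params.e_plus, movie),
                                     dt, integrator)
        em_raw = channel_conductance(params.e_minus, stimulus_drive(params.e_minus, movie),
                                     dt, integrator)
        norm = params.tonic_norm
        ep = ep_raw / norm
        em = np.minimum(em_raw, params.g_e_star) / norm
        delta_g = ep - em
        sigma_g = 1.0 + ep - em
        channels = {"E+": ep_raw, "E-": em_raw}
        g_dep, g_hyp = ep, em
    elif isinstance(params, ScaledEIParams):
        src = params.base
        ep_raw = channel_conductance(src.e_plus, stimulus_drive(src.e_plus, movie),
                                     dt, integrator)
        em_raw = channel_conductance(src.e_minus, stimulus_drive(src.e_minus, movie),
                                     dt, integrator)
        if params.rectify:
            em_raw = np.minimum(em_raw, src.g_e_star)
        e = params.c_e * ep_raw
        i = params.c_i * em_raw
        delta_g = e - alpha * i
        sigma_g = 1.0 + e + i
        channels = {"E": e, "I": i}
        g_dep, g_hyp = e, i
    else:  # pragma: no cover
        raise TypeError(f"unknown model parameter type {type(params).__name__}")

    v = frame.driving_force_mV * delta_g / sigma_g
    voltage = VoltageTrace(t_ms=t, v_mV=v, dt_ms=dt, baseline_mV=frame.v_leak_mV)
    traces = ConductanceTraces(channels=channels, g_dep=g_dep, g_hyp=g_hyp,
                               delta_g=delta_g, sigma_g=sigma_g, alpha=alpha)
    return voltage, traces


# ---------------------------------------------------------------------------
# serialization

def params_to_json(params: ModelParams, path: str | Path) -> None:
    """Write model parameters as a JSON object tagged with the variant."""
    if isinstance(params, ScaledEIParams):
        obj = {"variant": params.variant, "c_e": params.c_e, "c_i": params.c_i,
               "rectify": params.rectify, "base": asdict(params.base)}
    else:
        obj = {"variant": params.variant, **asdict(params)}
    Path(path).write_text(json.dumps(obj, indent=1))


def params_from_json(path: str | Path) -> ModelParams:
    obj = json.loads(Path(path).read_text())
    variant = obj.pop("variant")

    def _frame(d: dict) -> MembraneFrame:
        return MembraneFrame(**d)

    def _epem(d: dict) -> EpEmParams:
        return EpEmParams(e_plus=ChannelParams(**d["e_plus"]),
                          e_minus=ChannelParams(**d["e_minus"]),
                          g_e_star=d["g_e_star"], frame=_frame(d["frame"]))

    if variant == "ei":
        return EIParams(exc=ChannelParams(**obj["exc"]),
                        inh=ChannelParams(**obj["inh"]), frame=_frame(obj["frame"]))
    if variant == "epem":
        return _epem(obj)
    if variant == "scaled_ei":
        return ScaledEIParams(base=_epem(obj["base"]), c_e=obj["c_e"],
                              c_i=obj["c_i"], rectify=obj["rectify"])
    raise ValueError(f"unknown variant {variant!r}")
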