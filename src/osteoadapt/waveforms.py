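"""Unit loading waveforms and the Kelvin-Voigt viscoelastic strain response.

A loading bout is a periodic force history ``F(t) = F0 * u(t)`` built from a
unit-amplitude waveform ``u`` (max |u| = 1 over one period), optionally with a
rest interval inserted after every ``n_group`` cycles.  Bone tissue is treated
as a Kelvin-Voigt solid, ``eta * d(eps)/dt + E * eps = sigma(t)``, so the
strain response lags the force and the oscillation amplitude ``delta_eps_max``
can fall below the peak strain ``eps_peak``.  The ratio
``xi = delta_eps_max / eps_peak`` is the quantity that distinguishes
rest-inserted from back-to-back loading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "UnitWaveform",
    "ViscoelasticMaterial",
    "StrainResponse",
    "make_waveform",
    "kelvin_voigt_response",
    "strain_metrics",
    "unit_response_metrics",
    "ConvergenceError",
]

WAVEFORM_KINDS = ("trapezoid", "haversine", "triangle", "rect_pulse", "sine")

#: default number of samples per waveform period used by the ODE integrator
DEFAULT_SAMPLES_PER_PERIOD = 2000

#: hard cap on settle cycles before the integrator gives up
MAX_SETTLE_CYCLES = 200


class ConvergenceError(RuntimeError):
    """Raised when the periodic steady state is not reached within the cycle cap."""


@dataclass(frozen=True)
class UnitWaveform:
    """A unit-amplitude periodic waveform with optional grouped rest insertion.

    ``shape_params`` is kind-specific:

    - ``trapezoid``: (rise_s, hold_s, fall_s)
    - ``haversine``: (frequency_hz,) -> u = sin^2(pi f t), period 1/f
    - ``triangle``: (frequency_hz,) -> symmetric 0-1-0 ramp, period 1/f
    - ``rect_pulse``: (duration_s,) -> u = 1 for the duration
    - ``sine``: (frequency_hz,) -> u = sin(2 pi f t), full wave in [-1, 1]
    """

    kind: str
    period_s: float
    rest_s: float = 0.0
    n_group: int = 1
    shape_params: tuple = ()

    @property
    def repeat_s(self) -> float:
        """Length of one repeat unit: ``n_group`` cycles plus the rest interval."""
        return self.n_group * self.period_s + self.rest_s

    def sample(self, t):
        """Evaluate u(t) (vectorized); t is taken modulo the repeat unit."""
        t = np.asarray(t, dtype=float)
        tc = np.mod(t, self.repeat_s)
        u = np.zeros_like(tc)
        active = tc < self.n_group * self.period_s
        phase = np.mod(tc[active], self.period_s)
        u[active] = self._shape(phase)
        return u

    def _shape(self, s):
        k = self.kind
        if k == "trapezoid":
            rise, hold, fall = self.shape_params
            u = np.zeros_like(s)
            m = s < rise
            u[m] = s[m] / rise
            m = (s >= rise) & (s < rise + hold)
            u[m] = 1.0
            m = (s >= rise + hold) & (s < rise + hold + fall)
            u[m] = 1.0 - (s[m] - rise - hold) / fall
            return u
        if k == "haversine":
            return np.sin(np.pi * s / self.period_s) ** 2
        if k == "triangle":
            half = self.period_s / 2.0
            return np.where(s < half, s / half, 2.0 - s / half)
        if k == "rect_pulse":
            return np.where(s < self.shape_params[0], 1.0, 0.0)
        if k == "sine":
            return np.sin(2.0 * np.pi * s / self.period_s)
        raise ValueError(f"unknown waveform kind: {k!r}")


@dataclass(frozen=True)
class ViscoelasticMaterial:
    """Kelvin-Voigt material: spring E (GPa) in parallel with dashpot eta (GPa s)."""

    E_gpa: float = 20.0
    eta_gpa_s: float = 0.0

    def __post_init__(self):
        if self.E_gpa <= 0:
            raise ValueError("Young's modulus must be positive")
        if self.eta_gpa_s < 0:
            raise ValueError("viscosity must be non-negative")

    @property
    def r_s(self) -> float:
        """Characteristic time r = 2*pi*eta/E (seconds)."""
        return 2.0 * math.pi * self.eta_gpa_s / self.E_gpa

    @property
    def tau_s(self) -> float:
        """Relaxation time eta/E = r/(2*pi)."""
        return self.eta_gpa_s / self.E_gpa

    @classmethod
    def from_r(cls, r_s: float, E_gpa: float = 20.0) -> "ViscoelasticMaterial":
        return cls(E_gpa=E_gpa, eta_gpa_s=r_s * E_gpa / (2.0 * math.pi))


@dataclass
class StrainResponse:
    """Steady-state strain trace over one repeat unit plus its scalar metrics."""

    time_s: np.ndarray
    strain_ue: np.ndarray
    eps_peak: float
    delta_eps_max: float
    xi: float
    degenerate: bool = False
    n_cycles_to_settle: int = 1
    waveform: UnitWaveform | None = field(default=None, repr=False)


def make_waveform(kind, shape_params, rest_s=0.0, n_group=1) -> UnitWaveform:
    """Construct a validated :class:`UnitWaveform`.

    ``shape_params`` may be a dict (e.g. ``{"rise_s": .1, "hold_s": .8,
    "fall_s": .1}`` or ``{"frequency_hz": 2}``) or a bare tuple in the order
    documented on :class:`UnitWaveform`.
    """
    if kind not in WAVEFORM_KINDS:
        raise ValueError(f"unknown waveform kind {kind!r}; expected one of {WAVEFORM_KINDS}")
    if rest_s < 0:
        raise ValueError("rest_s must be non-negative")
    n_group = int(n_group)
    if n_group < 1:
        raise ValueError("n_group must be a positive integer")

    if isinstance(shape_params, dict):
        if kind == "trapezoid":
            params = (shape_params["rise_s"], shape_params["hold_s"], shape_params["fall_s"])
        elif kind == "rect_pulse":
            params = (shape_params["duration_s"],)
        else:
            params = (shape_params["frequency_hz"],)
    else:
        params = tuple(float(v) for v in shape_params)

    if kind == "trapezoid":
        rise, hold, fall = params
        if rise <= 0 or fall <= 0 or hold < 0:
            raise ValueError("trapezoid rise/fall must be positive and hold non-negative")
        period = rise + hold + fall
    elif kind == "rect_pulse":
        (duration,) = params
        if duration <= 0:
            raise ValueError("rect_pulse duration must be positive")
        period = duration
    else:
        (freq,) = params
        if freq <= 0:
            raise ValueError(f"{kind} requires a positive frequency_hz")
        period = 1.0 / freq

    if period <= 0:
        raise ValueError("waveform period must be positive")
    return UnitWaveform(kind=kind, period_s=period, rest_s=float(rest_s),
                        n_group=n_group, shape_params=params)


@lru_cache(maxsize=512)
def _unit_samples(waveform: UnitWaveform, n_steps: int):
    t = np.linspace(0.0, waveform.repeat_s, n_steps + 1)
    return t, waveform.sample(t)


def _settle_to_periodic(u, dt, tau, rtol=1e-6, max_cycles=MAX_SETTLE_CYCLES):
    """March the linear ODE tau*eps' = u - eps cycle by cycle until the peak
    strain drift per repeat unit falls below ``rtol`` (relative).

    Uses the exact one-step update for piecewise-linear forcing, so the only
    discretization error is the piecewise-linear sampling of ``u``.
    Returns (trace over final repeat unit, number of cycles marched).
    """
    if tau == 0.0:
        return u.copy(), 1
    alpha = math.exp(-dt / tau)
    b = np.diff(u) / dt
    # exact step: eps_{n+1} = alpha*eps_n + u_n*(1-alpha) + b_n*(dt - tau*(1-alpha))
    gamma = u[:-1] * (1.0 - alpha) + b * (dt - tau * (1.0 - alpha))
    eps0 = 0.0
    zi = np.array([alpha * eps0])
    prev_peak = None
    scale = max(np.max(np.abs(u)), 1e-30)
    for cycle in range(1, max_cycles + 1):
        y, zi = lfilter([1.0], [1.0, -alpha], gamma, zi=zi)
        trace = np.concatenate(([eps0], y))
        peak = float(np.max(np.abs(trace)))
        if prev_peak is not None and abs(peak - prev_peak) <= rtol * max(peak, 1e-12 * scale):
            return trace, cycle
        prev_peak = peak
        eps0 = trace[-1]
        zi = np.array([alpha * eps0])
    raise ConvergenceError(
        f"periodic steady state not reached within {max_cycles} repeat units "
        f"(tau={tau:.4g} s, repeat={len(u) * dt:.4g} s)"
    )


def kelvin_voigt_response(waveform: UnitWaveform, amplitude_ue: float,
                          material: ViscoelasticMaterial,
                          n_settle_cycles: int = 1, dt: float | None = None,
                          max_cycles: int = MAX_SETTLE_CYCLES) -> StrainResponse:
    """Steady-state strain response of a Kelvin-Voigt solid to periodic loading.

    Parameters
    ----------
    waveform
        The unit force waveform (including rest insertion).
    amplitude_ue
        Elastic strain scale sigma0/E in microstrain: the strain an elastic
        bone (eta = 0) would see at the waveform peak.
    material
        Kelvin-Voigt constants; only the ratio tau = eta/E enters.
    n_settle_cycles
        Minimum number of repeat units to march before accepting steady state.
    dt
        Integration step; must satisfy ``dt <= period/200``.  Defaults to
        ``period / 2000``.
    """
    period = waveform.period_s
    if dt is None:
        dt = period / DEFAULT_SAMPLES_PER_PERIOD
    if dt > period / 200.0 + 1e-15:
        raise ValueError(f"dt={dt:g} too coarse: require dt <= period/200 = {period / 200:g}")
    if n_settle_cycles < 1:
        raise ValueError("n_settle_cycles must be >= 1")

    n_steps = max(int(round(waveform.repeat_s / dt)), 200)
    t, u = _unit_samples(waveform, n_steps)
    dt_actual = waveform.repeat_s / n_steps

    tau = material.tau_s
    if tau == 0.0:
        trace, n_cycles = u.copy(), 1
    else:
        trace, n_cycles = _settle_to_periodic(u, dt_actual, tau, max_cycles=max_cycles)
        n_cycles = max(n_cycles, n_settle_cycles)

    strain = amplitude_ue * trace
    resp = StrainResponse(time_s=t, strain_ue=strain, eps_peak=0.0,
                          delta_eps_max=0.0, xi=0.0, waveform=waveform,
                          n_cycles_to_settle=n_cycles)
    resp.eps_peak, resp.delta_eps_max, resp.xi = strain_metrics(resp)
    resp.degenerate = resp.eps_peak == 0.0
    return resp


def strain_metrics(response: StrainResponse):
    """(eps_peak, delta_eps_max, xi) from a steady-state repeat-unit trace.

    eps_peak is max |eps|; delta_eps_max the global crest-to-trough excursion;
    xi their ratio (0 when the trace is identically zero, flagged degenerate).
    """
    strain = np.asarray(response.strain_ue, dtype=float)
    eps_peak = float(np.max(np.abs(strain)))
    delta = float(np.max(strain) - np.min(strain))
    xi = delta / eps_peak if eps_peak > 0 else 0.0
    return eps_peak, delta, xi


@lru_cache(maxsize=8192)
def unit_response_metrics(waveform: UnitWaveform, r_s: float,
                          dt: float | None = None):
    """(peak, delta, xi) of the unit-amplitude viscoelastic response.

    Cached: repeated calls with the same (waveform, r) — e.g. inside a
    least-squares jacobian — are free.  By linearity the actual response is
    the unit response scaled by the elastic strain amplitude.
    """
    material = ViscoelasticMaterial.from_r(r_s)
    resp = kelvin_voigt_response(waveform, 1.0, material, dt=dt)
    return resp.eps_peak, resp.delta_eps_max, resp.xi
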