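"""Mineral apposition from stimulus flux, and the constant-of-proportionality
calibrations.

MAR at an osteoblast is proportional to the stimulus inflow: m_i = k * q_i,
with k a negative constant (osteoblast flow rates are negative, being sinks).
k is calibrated in closed form three ways: against per-site MAR data, against
a single section-average BFR, or against BFR observations from several
protocols at once.  Two auxiliary derivations recover the days exponent beta
from two lumped calibration constants obtained at different d, and audit the
unit conversions by extracting |k| from a lumped constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np

from .network import NM_TO_NMOL_PER_UM3, cm2_s_to_um2_day

__all__ = [
    "MarResult",
    "CalibrationResult",
    "WorkedGain",
    "mar_from_flux",
    "calibrate_k",
    "worked_h",
    "derive_beta",
    "derive_k_value",
]


@dataclass
class MarResult:
    """Per-osteoblast apposition rates and surface aggregates.

    BFR/BS for a surface is identified numerically with the mean MAR over that
    surface's osteoblasts (both um/day ~ um^3/um^2/day).
    """

    mar_um_day: dict
    bfr_by_surface: dict
    n_osteoblasts: int

    @property
    def bfr_overall(self) -> float:
        vals = list(self.mar_um_day.values())
        return float(np.mean(vals)) if vals else 0.0


@dataclass
class CalibrationResult:
    k_um_per_nmol: float           # signed (negative for sink flow rates)
    mode: str
    objective: float
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def k_magnitude(self) -> float:
        return abs(self.k_um_per_nmol)


@dataclass(frozen=True)
class WorkedGain:
    spike_nM: float
    h_nm_per_ue: float


def mar_from_flux(q_by_id: dict, k_um_per_nmol: float,
                  network=None) -> MarResult:
    """m_i = k * q_i per osteoblast, aggregated to BFR/BS per surface.

    ``q_by_id`` maps osteoblast id -> flow rate (nmol/day).  If ``network`` is
    given, surfaces are read from it; otherwise everything is pooled under
    'all'.
    """
    mar = {ob: k_um_per_nmol * q for ob, q in q_by_id.items()}
    by_surface = {}
    if network is not None:
        for surface in ("periosteal", "endocortical"):
            ids = [i for i in network.osteoblast_ids_on(surface) if i in mar]
            if ids:
                by_surface[surface] = float(np.mean([mar[i] for i in ids]))
    else:
        by_surface["all"] = float(np.mean(list(mar.values()))) if mar else 0.0
    return MarResult(mar_um_day=mar, bfr_by_surface=by_surface,
                     n_osteoblasts=len(mar))


def calibrate_k(mode: str, observed, q_data) -> CalibrationResult:
    """Closed-form least-squares calibration of k.

    mode='site_mar':   observed = per-osteoblast MAR array m0, q_data = array q
                       -> k = sum(m0*q)/sum(q^2)
    mode='single_avg': observed = one section BFR B0, q_data = array q
                       -> k = B0*n_b/sum(q)
    mode='multi_avg':  observed = array of per-protocol B0_l,
                       q_data = list of per-protocol q arrays (same osteoblasts)
                       -> k = n_b * sum_l(B0_l*S_l) / sum_l(S_l^2), S_l = sum_i q_i^l
    """
    if mode == "site_mar":
        m0 = np.asarray(observed, dtype=float)
        q = np.asarray(q_data, dtype=float)
        if m0.shape != q.shape:
            raise ValueError("observed MAR and flux arrays must align")
        denom = float(np.sum(q**2))
        if denom == 0.0:
            raise ValueError("all flow rates are zero: k undefined")
        k = float(np.sum(m0 * q)) / denom
        resid = m0 - k * q
        return CalibrationResult(k, mode, float(np.sum(resid**2)), resid)

    if mode == "single_avg":
        b0 = float(observed)
        q = np.asarray(q_data, dtype=float)
        s = float(np.sum(q))
        if s == 0.0:
            raise ValueError("all flow rates are zero: k undefined")
        k = b0 * len(q) / s
        resid = np.array([b0 - k * s / len(q)])
        return CalibrationResult(k, mode, float(np.sum(resid**2)), resid)

    if mode == "multi_avg":
        b0 = np.asarray(observed, dtype=float)
        q_sets = [np.asarray(q, dtype=float) for q in q_data]
        if len(b0) != len(q_sets):
            raise ValueError("need one BFR observation per protocol")
        n_b = {len(q) for q in q_sets}
        if len(n_b) != 1:
            raise ValueError("protocols must share the same osteoblast set")
        n_b = n_b.pop()
        s = np.array([q.sum() for q in q_sets])
        denom = float(np.sum(s**2))
        if denom == 0.0:
            raise ValueError("all flow rates are zero: k undefined")
        k = n_b * float(np.sum(b0 * s)) / denom
        resid = b0 - k * s / n_b
        return CalibrationResult(k, mode, float(np.sum(resid**2)), resid)

    raise ValueError(f"unknown calibration mode {mode!r}")


def worked_h(baseline_nM: float, fold_increase: float,
             applied_strain_ue: float, eps_thres_ue: float) -> WorkedGain:
    """Signaling gain h from a single-pulse calcium-spike observation.

    The spike amplitude is fold_increase * baseline; with xi ~ 1 for a single
    rest-inserted pulse, h is the spike divided by the strain excess over
    threshold.
    """
    if applied_strain_ue <= eps_thres_ue:
        raise ValueError("applied strain must exceed the threshold")
    if baseline_nM < 0 or fold_increase < 0:
        raise ValueError("baseline and fold increase must be non-negative")
    spike = fold_increase * baseline_nM
    return WorkedGain(spike_nM=spike,
                      h_nm_per_ue=spike / (applied_strain_ue - eps_thres_ue))


def derive_beta(lump_a: float, d_a: float, lump_b: float, d_b: float) -> float:
    """Days exponent from two lumped constants c*d^beta at distinct d:
    beta = ln(lump_b/lump_a) / ln(d_b/d_a)."""
    if d_a <= 0 or d_b <= 0 or d_a == d_b:
        raise ValueError("need two distinct positive d values")
    if lump_a * lump_b <= 0:
        raise ValueError("lumped constants must be nonzero with the same sign")
    return log(lump_b / lump_a) / log(d_b / d_a)


def derive_k_value(lump_with_d, d: float, beta: float, h_nm_per_ue: float,
                   D_cm2_s: float, A0_um2: float) -> float:
    """|k| (um/nmol) from a lumped constant k*h*D*A0*d^beta (um^2/day/ue).

    Audits the unit layer: h converts nM/ue -> nmol/um^3/ue, D cm^2/s ->
    um^2/day; the remaining factor is k in um/nmol.
    """
    if h_nm_per_ue <= 0 or D_cm2_s <= 0 or A0_um2 <= 0:
        raise ValueError("h, D and A0 must be positive")
    h_internal = h_nm_per_ue * NM_TO_NMOL_PER_UM3
    denom = h_internal * cm2_s_to_um2_day(D_cm2_s) * A0_um2
    if denom == 0.0:
        raise ValueError("zero denominator in k derivation")
    return abs(lump_with_d / d ** beta) / denom
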