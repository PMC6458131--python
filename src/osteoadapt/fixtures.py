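"""Deterministic synthetic fixtures: sections, cell networks, protocol presets
and noisy observations.

No public dataset carries the section geometry and cell coordinates the model
was originally calibrated on, so these generators produce structurally
equivalent stand-ins: an elliptical-annulus mid-diaphyseal section,
intracortical osteocytes on a jittered lattice wired by short processes to
surface osteoblasts, and the loading protocols with the published timing
parameters.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .bfr import BfrObservation, LoadingProtocol, ModelParameters, bfr_forward
from .network import A0_UM2, Cell, CellNetwork, Process
from .section import CrossSection, section_properties
from .waveforms import make_waveform

__all__ = [
    "FixtureSpec",
    "make_section",
    "make_cells_and_network",
    "make_observations",
    "protocol_presets",
    "cantilever_protocol_grid",
    "TRAPEZOID_TIMINGS",
]

#: published trapezoid timings: 0.1 s rise, 0.8 s hold, 0.1 s fall
TRAPEZOID_TIMINGS = {"rise_s": 0.1, "hold_s": 0.8, "fall_s": 0.1}

NETWORK_RULES = ("nearest_osteoblast", "k_nearest", "delaunay_pruned")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic section + cell-network generator."""

    outer_a_um: float = 600.0
    outer_b_um: float = 450.0
    thickness_um: float = 200.0
    n_vertices: int = 128
    n_osteocytes: int = 200
    n_osteoblasts_periosteal: int = 40
    n_osteoblasts_endocortical: int = 20
    network_rule: str = "nearest_osteoblast"
    k_nearest: int = 2
    A0_um2: float = A0_UM2
    seed: int = 0

    def __post_init__(self):
        if self.thickness_um >= min(self.outer_a_um, self.outer_b_um):
            raise ValueError("cortical thickness must be less than the smaller semi-axis")
        if min(self.n_osteocytes, self.n_osteoblasts_periosteal,
               self.n_osteoblasts_endocortical) < 1:
            raise ValueError("cell counts must be >= 1")
        if self.network_rule not in NETWORK_RULES:
            raise ValueError(f"unknown network rule {self.network_rule!r}")


def _ellipse(a, b, n, phase=0.0):
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False) + phase
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


def make_section(spec: FixtureSpec) -> CrossSection:
    """Elliptical-annulus cross-section with properties from the section module."""
    outer = _ellipse(spec.outer_a_um, spec.outer_b_um, spec.n_vertices)
    inner = _ellipse(spec.outer_a_um - spec.thickness_um,
                     spec.outer_b_um - spec.thickness_um, spec.n_vertices)
    return section_properties(outer, inner)


def _in_annulus(xy, spec, margin=0.08):
    """Strictly inside the cortex with a small relative margin off both walls."""
    ao, bo = spec.outer_a_um, spec.outer_b_um
    ai, bi = ao - spec.thickness_um, bo - spec.thickness_um
    m = 1.0 - margin
    outer_ok = (xy[:, 0] / (ao * m)) ** 2 + (xy[:, 1] / (bo * m)) ** 2 <= 1.0
    inner_ok = (xy[:, 0] / (ai / m)) ** 2 + (xy[:, 1] / (bi / m)) ** 2 >= 1.0
    return outer_ok & inner_ok


def make_cells_and_network(section: CrossSection, spec: FixtureSpec):
    """(cells, edges) -> a :class:`CellNetwork` over the synthetic section.

    Osteocytes sit on a seeded, jittered lattice inside the cortex;
    osteoblasts are equally spaced along the periosteal and endocortical
    boundaries.  Edges follow ``spec.network_rule``; every edge length is the
    Euclidean distance and every area is A0.
    """
    rng = np.random.default_rng(spec.seed)

    # lattice of candidate osteocyte sites, jittered, filtered to the cortex
    target = spec.n_osteocytes
    side = int(np.ceil(np.sqrt(target * 4)))
    gx = np.linspace(-spec.outer_a_um, spec.outer_a_um, side)
    gy = np.linspace(-spec.outer_b_um, spec.outer_b_um, side)
    xx, yy = np.meshgrid(gx, gy)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pitch = min(gx[1] - gx[0], gy[1] - gy[0])
    pts = pts + rng.normal(scale=0.18 * pitch, size=pts.shape)
    pts = pts[_in_annulus(pts, spec)]
    if len(pts) < target:
        raise ValueError(f"only {len(pts)} lattice sites fit the cortex; "
                         f"reduce n_osteocytes or thicken the section")
    keep = rng.choice(len(pts), size=target, replace=False)
    ocy_xy = pts[np.sort(keep)]

    cells = [Cell(id=f"ocy{i:04d}", kind="osteocyte", x_um=float(p[0]),
                  y_um=float(p[1])) for i, p in enumerate(ocy_xy)]

    for surface, n_ob in (("periosteal", spec.n_osteoblasts_periosteal),
                          ("endocortical", spec.n_osteoblasts_endocortical)):
        if surface == "periosteal":
            a, b = spec.outer_a_um, spec.outer_b_um
        else:
            a, b = spec.outer_a_um - spec.thickness_um, spec.outer_b_um - spec.thickness_um
        xy = _ellipse(a, b, n_ob, phase=np.pi / n_ob)
        tag = "pob" if surface == "periosteal" else "eob"
        cells += [Cell(id=f"{tag}{i:03d}", kind="osteoblast", x_um=float(p[0]),
                       y_um=float(p[1]), surface=surface) for i, p in enumerate(xy)]

    net_tmp = CellNetwork(cells, [])
    ob_ids = net_tmp.osteoblast_ids
    ob_pos = net_tmp.positions(ob_ids)
    tree = cKDTree(ob_pos)

    edges = []
    seen = set()

    def add_edge(ida, idb, pa, pb):
        key = (ida, idb) if ida < idb else (idb, ida)
        if key in seen:
            return
        seen.add(key)
        edges.append(Process(a=ida, b=idb,
                             length_um=float(np.hypot(*(np.asarray(pa) - pb))),
                             area_um2=spec.A0_um2))

    if spec.network_rule in ("nearest_osteoblast", "k_nearest"):
        k = 1 if spec.network_rule == "nearest_osteoblast" else spec.k_nearest
        _, nearest = tree.query(ocy_xy, k=k)
        nearest = np.atleast_2d(nearest.T).T
        for i, row in enumerate(nearest):
            for j in np.atleast_1d(row):
                add_edge(cells[i].id, ob_ids[int(j)], ocy_xy[i], ob_pos[int(j)])
    else:  # delaunay_pruned
        all_ids = [c.id for c in cells]
        all_xy = net_tmp.positions(all_ids)
        tri = Delaunay(all_xy)
        kinds = {c.id: c.kind for c in cells}
        pairs = set()
        for simplex in tri.simplices:
            for u in range(3):
                i, j = sorted((simplex[u], simplex[(u + 1) % 3]))
                pairs.add((i, j))
        lengths = np.array([np.hypot(*(all_xy[i] - all_xy[j])) for i, j in pairs])
        cutoff = np.percentile(lengths, 90)
        for (i, j), L in zip(pairs, lengths):
            if kinds[all_ids[i]] == "osteoblast" and kinds[all_ids[j]] == "osteoblast":
                continue
            if L > cutoff:
                continue
            add_edge(all_ids[i], all_ids[j], all_xy[i], all_xy[j])
        # guarantee every osteocyte can reach a sink
        net_try = CellNetwork(cells, edges)
        for comp in net_try.components_without_sink():
            for cid in comp:
                if kinds[cid] == "osteocyte":
                    i = net_try.index[cid]
                    _, j = tree.query(all_xy[i])
                    add_edge(cid, ob_ids[int(j)], all_xy[i], ob_pos[int(j)])
                    break

    network = CellNetwork(cells, edges)
    stranded = network.components_without_sink()
    if stranded:
        raise ValueError(f"disconnected osteocytes under rule {spec.network_rule}: "
                         f"{[c for comp in stranded for c in comp]}")
    return network


def protocol_presets() -> dict:
    """Named loading protocols with published timing parameters."""
    trap_rest = make_waveform("trapezoid", TRAPEZOID_TIMINGS, rest_s=10.0)
    presets = {
        "cantilever_trapezoid_rest10": LoadingProtocol(
            "cantilever_trapezoid_rest10", trap_rest, 1600.0, 50, 3, weeks=3),
        "axial_haversine_2hz_360": LoadingProtocol(
            "axial_haversine_2hz_360",
            make_waveform("haversine", {"frequency_hz": 2.0}), 1833.0, 360, 3, weeks=4),
        "axial_haversine_2hz_60": LoadingProtocol(
            "axial_haversine_2hz_60",
            make_waveform("haversine", {"frequency_hz": 2.0}), 1200.0, 60, 3, weeks=2),
        "axial_triangle_4hz_216_grouped_rest": LoadingProtocol(
            "axial_triangle_4hz_216_grouped_rest",
            make_waveform("triangle", {"frequency_hz": 4.0}, rest_s=5.0, n_group=4),
            1080.0, 216, 5, weeks=2),
        "fourpoint_haversine_2hz_36": LoadingProtocol(
            "fourpoint_haversine_2hz_36",
            make_waveform("haversine", {"frequency_hz": 2.0}), 1404.0, 36, 7, weeks=2),
        "fourpoint_haversine_2hz_99": LoadingProtocol(
            "fourpoint_haversine_2hz_99",
            make_waveform("haversine", {"frequency_hz": 2.0}), 2000.0, 99, 3, weeks=3),
        "threepoint_rect_pulse_rest39.5": LoadingProtocol(
            "threepoint_rect_pulse_rest39.5",
            make_waveform("rect_pulse", {"duration_s": 0.5}, rest_s=39.5),
            2100.0, 36, 3, weeks=1),
    }
    return presets


def cantilever_protocol_grid(d: float = 3.0) -> list:
    """Ten cantilever-style trapezoid protocols: the published strain levels
    (1000/1250/1600 ue) crossed with cycle counts (10/50/250), half with the
    10 s rest insertion and half back-to-back, plus one extra no-rest arm."""
    strains = (1000.0, 1250.0, 1600.0)
    cycles = (10, 50, 250)
    protocols = []
    i = 0
    for eps in strains:
        for n in cycles:
            rest = 10.0 if (i % 2 == 0) else 0.0
            wf = make_waveform("trapezoid", TRAPEZOID_TIMINGS, rest_s=rest)
            protocols.append(LoadingProtocol(
                f"p{i + 1:02d}_s{int(eps)}_n{n}_rest{int(rest)}", wf, eps, n, d))
            i += 1
    wf = make_waveform("trapezoid", TRAPEZOID_TIMINGS, rest_s=0.0)
    protocols.append(LoadingProtocol("p10_s1600_n50_rest0", wf, 1600.0, 50, d))
    return protocols


def make_observations(ground_truth: ModelParameters, protocols,
                      noise_sd: float = 0.0, seed: int = 0,
                      dt_fraction: int = 500):
    """Forward-model BFR observations, optionally with Gaussian noise.

    Negative noisy values are clipped to zero and flagged.  Returns
    (observations, clipped_labels).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    obs, clipped = [], []
    for p in protocols:
        b = bfr_forward(ground_truth, p, dt=p.waveform.period_s / dt_fraction)
        if noise_sd > 0:
            b_noisy = b + rng.normal(scale=noise_sd)
            if b_noisy < 0:
                clipped.append(p.label)
                b_noisy = 0.0
        else:
            b_noisy = b
        obs.append(BfrObservation(label=p.label, B0=float(b_noisy)))
    return obs, clipped


def spec_to_dict(spec: FixtureSpec) -> dict:
    return asdict(spec)
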