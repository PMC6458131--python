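"""Osteocyte-osteoblast network and the steady-state stimulus diffusion solve.

Osteocytes above the strain threshold release a biochemical stimulus whose
concentration is pinned at each osteocyte node; osteoblasts are perfect sinks
(concentration zero).  The stimulus diffuses along 1-D cell processes; each
process of length L and cross-section A contributes an edge conductance
D*A/L, assembled into a symmetric graph Laplacian K.  Solving Q = K*Psi gives
the stimulus flow rate at every node; osteoblast inflow (q_i <= 0) drives
bone apposition downstream.

Unit regime (documented once, audited by the k-value test):
  lengths um, areas um^2, D supplied in cm^2/s and converted to um^2/day,
  concentrations supplied in nM and converted to nmol/um^3, so flow rates
  come out in nmol/day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

__all__ = [
    "Cell",
    "Process",
    "CellNetwork",
    "StimulusField",
    "DiffusionSolution",
    "osteocyte_stimulus",
    "assemble_stiffness",
    "solve_fluxes",
    "D_CA_CM2_S",
    "A0_UM2",
    "cm2_s_to_um2_day",
    "NM_TO_NMOL_PER_UM3",
]

#: default Ca2+ diffusivity, cm^2/s
D_CA_CM2_S = 5.3e-6
#: default cell-process cross-sectional area, um^2
A0_UM2 = 0.025
#: 1 nM = 1e-9 mol/L = 1e-15 nmol/um^3
NM_TO_NMOL_PER_UM3 = 1e-15

_CM2_PER_S_TO_UM2_PER_DAY = 1e8 * 86400.0


def cm2_s_to_um2_day(d_cm2_s: float) -> float:
    return d_cm2_s * _CM2_PER_S_TO_UM2_PER_DAY


CELL_KINDS = ("osteocyte", "osteoblast", "junction")
SURFACE_TAGS = ("periosteal", "endocortical", "intracortical")


@dataclass(frozen=True)
class Cell:
    id: str
    kind: str
    x_um: float
    y_um: float
    surface: str = "intracortical"

    def __post_init__(self):
        if self.kind not in CELL_KINDS:
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.surface not in SURFACE_TAGS:
            raise ValueError(f"unknown surface tag {self.surface!r}")
        if self.kind == "osteoblast" and self.surface == "intracortical":
            raise ValueError(f"osteoblast {self.id} must carry a surface tag")
        if self.kind == "osteocyte" and self.surface != "intracortical":
            raise ValueError(f"osteocyte {self.id} must be intracortical")


@dataclass(frozen=True)
class Process:
    """A 1-D cell process (edge) between two cells."""

    a: str
    b: str
    length_um: float
    area_um2: float = A0_UM2

    def __post_init__(self):
        if self.a == self.b:
            raise ValueError("process endpoints must be distinct")
        if self.length_um <= 0:
            raise ValueError("process length must be positive")
        if self.area_um2 <= 0:
            raise ValueError("process area must be positive")


class CellNetwork:
    """Typed cells plus process edges, with index bookkeeping for the solve."""

    def __init__(self, cells, processes):
        self.cells = list(cells)
        self.processes = list(processes)
        self.index = {c.id: i for i, c in enumerate(self.cells)}
        if len(self.index) != len(self.cells):
            raise ValueError("duplicate cell ids")
        for e in self.processes:
            if e.a not in self.index or e.b not in self.index:
                raise ValueError(f"process references unknown cell: {e.a}-{e.b}")

    def __len__(self):
        return len(self.cells)

    @property
    def osteocyte_ids(self):
        return [c.id for c in self.cells if c.kind == "osteocyte"]

    @property
    def osteoblast_ids(self):
        return [c.id for c in self.cells if c.kind == "osteoblast"]

    def osteoblast_ids_on(self, surface):
        return [c.id for c in self.cells if c.kind == "osteoblast" and c.surface == surface]

    def positions(self, ids=None):
        if ids is None:
            ids = [c.id for c in self.cells]
        return np.array([[self.cells[self.index[i]].x_um,
                          self.cells[self.index[i]].y_um] for i in ids])

    def components_without_sink(self):
        """Connected components (as id lists) that contain no osteoblast:
        stimulus generated there has nowhere to flow."""
        n = len(self.cells)
        adj = self._adjacency()
        n_comp, labels = connected_components(adj, directed=False)
        bad = []
        for comp in range(n_comp):
            ids = [self.cells[i].id for i in range(n) if labels[i] == comp]
            if not any(self.cells[self.index[i]].kind == "osteoblast" for i in ids):
                bad.append(ids)
        return bad

    def _adjacency(self):
        n = len(self.cells)
        rows = [self.index[e.a] for e in self.processes]
        cols = [self.index[e.b] for e in self.processes]
        data = np.ones(len(self.processes))
        return sp.coo_matrix((data, (rows, cols)), shape=(n, n))


@dataclass
class StimulusField:
    """Per-osteocyte stimulus concentrations (nM) and the constants behind them."""

    s_nM: dict
    h_nm_per_ue: float
    D_cm2_s: float = D_CA_CM2_S


@dataclass
class DiffusionSolution:
    K: sp.csr_matrix
    psi_nmol_um3: np.ndarray
    Q_nmol_day: np.ndarray
    q_osteoblasts_nmol_day: dict
    ids: list
    conservation_residual: float = 0.0
    flags: list = field(default_factory=list)


def osteocyte_stimulus(eps_peak_ue, xi, h_nm_per_ue, eps_thres_ue,
                       N, d, q_exp, beta, is_osteocyte=True):
    """Stimulus concentration (nM) released by a cell under local peak strain.

    s = h * (eps_peak - eps_thres) * xi * N^q * d^beta above threshold;
    exactly zero below threshold and always zero for non-osteocytes.
    Vectorized over ``eps_peak_ue`` (with matching ``is_osteocyte`` mask).
    """
    eps = np.asarray(eps_peak_ue, dtype=float)
    mask = np.logical_and(np.asarray(is_osteocyte, dtype=bool), eps >= eps_thres_ue)
    s = np.where(mask,
                 h_nm_per_ue * (eps - eps_thres_ue) * xi * N ** q_exp * d ** beta,
                 0.0)
    if np.ndim(eps_peak_ue) == 0:
        return float(s)
    return s


def assemble_stiffness(network: CellNetwork, D_cm2_s: float = D_CA_CM2_S):
    """Assemble the global conductance (diffusion stiffness) matrix.

    Each process contributes c * [[1, -1], [-1, 1]] with c = D*A/L in
    um^3/day; duplicate edges merge with summed conductance.  Returns a CSR
    matrix ordered like ``network.cells``.
    """
    d_um2_day = cm2_s_to_um2_day(D_cm2_s)
    n = len(network)
    rows, cols, data = [], [], []
    for e in network.processes:
        i, j = network.index[e.a], network.index[e.b]
        c = d_um2_day * e.area_um2 / e.length_um
        rows += [i, j, i, j]
        cols += [i, j, j, i]
        data += [c, c, -c, -c]
    K = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    K.sum_duplicates()
    return K


def solve_fluxes(K, stimulus: StimulusField, network: CellNetwork,
                 dense_threshold: int = 500) -> DiffusionSolution:
    """Solve the steady-state diffusion system for nodal flow rates.

    Osteocyte concentrations are prescribed to the stimulus values and
    osteoblasts to zero; junction nodes are free unknowns determined by
    zero net flow.  With no free nodes Q = K*Psi is a direct product; both
    paths agree by construction.  Flow rates are in nmol/day.
    """
    n = len(network)
    ids = [c.id for c in network.cells]
    psi = np.zeros(n)
    prescribed = np.zeros(n, dtype=bool)
    for i, cell in enumerate(network.cells):
        if cell.kind == "osteocyte":
            s = stimulus.s_nM.get(cell.id, 0.0)
            if s < 0:
                raise ValueError(f"negative stimulus at {cell.id}")
            psi[i] = s * NM_TO_NMOL_PER_UM3
            prescribed[i] = True
        elif cell.kind == "osteoblast":
            psi[i] = 0.0
            prescribed[i] = True

    flags = []
    sinkless = network.components_without_sink()
    if sinkless:
        flags.append(f"{len(sinkless)} component(s) contain no osteoblast sink")

    free = ~prescribed
    if free.any():
        Kff = K[free][:, free]
        rhs = -K[free][:, prescribed] @ psi[prescribed]
        diag = Kff.diagonal()
        if np.any(diag == 0):
            loose = [ids[i] for i in np.flatnonzero(free)[diag == 0]]
            raise ValueError(f"singular system: isolated free node(s) {loose}")
        if free.sum() < dense_threshold:
            psi[free] = np.linalg.solve(Kff.toarray(), rhs)
        else:
            psi[free] = spsolve(Kff.tocsc(), rhs)

    Q = np.asarray(K @ psi).ravel()
    conservation = float(abs(Q.sum()) / max(np.abs(Q).max(), 1e-300))
    q_ob = {c.id: float(Q[network.index[c.id]])
            for c in network.cells if c.kind == "osteoblast"}
    return DiffusionSolution(K=K, psi_nmol_um3=psi, Q_nmol_day=Q,
                             q_osteoblasts_nmol_day=q_ob, ids=ids,
                             conservation_residual=conservation, flags=flags)
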