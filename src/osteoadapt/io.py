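"""Plain-text I/O for sections, cell networks, protocols, parameters and MAR
tables, plus run manifests.

All tabular formats are CSV with unit-suffixed headers; structured inputs are
JSON (YAML accepted for configs).  Every pipeline run can emit a manifest
recording input hashes, options and the package version so outputs are
traceable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bfr import BfrObservation, LoadingProtocol, ModelParameters
from .network import Cell, CellNetwork, Process
from .section import CrossSection, section_properties
from .waveforms import make_waveform

__all__ = [
    "read_config",
    "read_section",
    "write_section",
    "read_network",
    "write_network",
    "read_protocols",
    "write_protocols",
    "read_params",
    "write_params",
    "write_mar_table",
    "read_mar_table",
    "write_manifest",
]


class ConfigError(ValueError):
    pass


def read_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ConfigError(f"missing required field {key!r} in {where}")
    return d[key]


# -- section ---------------------------------------------------------------

def write_section(section: CrossSection, path) -> None:
    payload = {
        "periosteal_um": np.asarray(section.periosteal_um).tolist(),
        "endocortical_um": np.asarray(section.endocortical_um).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_section(path) -> CrossSection:
    data = read_config(path)
    peri = _require(data, "periosteal_um", str(path))
    endo = _require(data, "endocortical_um", str(path))
    return section_properties(np.asarray(peri), np.asarray(endo))


# -- cell network ----------------------------------------------------------

def write_network(network: CellNetwork, cells_path, edges_path) -> None:
    cells = pd.DataFrame(
        [{"id": c.id, "kind": c.kind, "x_um": c.x_um, "y_um": c.y_um,
          "surface": c.surface} for c in network.cells])
    edges = pd.DataFrame(
        [{"id_a": e.a, "id_b": e.b, "length_um": e.length_um,
          "area_um2": e.area_um2} for e in network.processes])
    cells.to_csv(cells_path, index=False)
    edges.to_csv(edges_path, index=False)


def read_network(cells_path, edges_path) -> CellNetwork:
    try:
        cells_df = pd.read_csv(cells_path)
    except FileNotFoundError:
        raise ConfigError(f"cells file not found: {cells_path}")
    try:
        edges_df = pd.read_csv(edges_path)
    except FileNotFoundError:
        raise ConfigError(f"edges file not found: {edges_path}")
    for col in ("id", "kind", "x_um", "y_um"):
        if col not in cells_df.columns:
            raise ConfigError(f"cells CSV lacks column {col!r}")
    cells = []
    for row_no, row in enumerate(cells_df.itertuples(index=False), start=2):
        try:
            cells.append(Cell(id=str(row.id), kind=row.kind, x_um=float(row.x_um),
                              y_um=float(row.y_um),
                              surface=getattr(row, "surface", "intracortical")))
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"malformed cells CSV at row {row_no}: {exc}")
    pos = {c.id: (c.x_um, c.y_um) for c in cells}
    edges = []
    for row_no, row in enumerate(edges_df.itertuples(index=False), start=2):
        a, b = str(row.id_a), str(row.id_b)
        length = getattr(row, "length_um", float("nan"))
        if pd.isna(length):  # default to Euclidean distance between endpoints
            if a not in pos or b not in pos:
                raise ConfigError(f"edges CSV row {row_no}: unknown endpoint")
            pa, pb = np.array(pos[a]), np.array(pos[b])
            length = float(np.hypot(*(pa - pb)))
        try:
            edges.append(Process(a=a, b=b, length_um=float(length),
                                 area_um2=float(getattr(row, "area_um2", 0.025))))
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"malformed edges CSV at row {row_no}: {exc}")
    return CellNetwork(cells, edges)


# -- protocols & observations ---------------------------------------------

def _protocol_to_dict(p: LoadingProtocol) -> dict:
    wf = p.waveform
    return {"label": p.label,
            "waveform": {"kind": wf.kind, "shape_params": list(wf.shape_params),
                         "rest_s": wf.rest_s, "n_group": wf.n_group},
            "peak_strain_ue": p.peak_strain_ue, "n_cycles": p.n_cycles,
            "days_per_week": p.days_per_week, "weeks": p.weeks}


def write_protocols(protocols, path, observations=None) -> None:
    payload = {"protocols": [_protocol_to_dict(p) for p in protocols]}
    if observations is not None:
        payload["observations"] = [
            {"label": o.label, "B0": o.B0, "se": o.se, "n": o.n} for o in observations]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_protocols(path):
    data = read_config(path)
    protocols = []
    for entry in _require(data, "protocols", str(path)):
        wf_spec = _require(entry, "waveform", "protocol entry")
        wf = make_waveform(_require(wf_spec, "kind", "waveform"),
                           tuple(wf_spec.get("shape_params", ())),
                           rest_s=wf_spec.get("rest_s", 0.0),
                           n_group=wf_spec.get("n_group", 1))
        protocols.append(LoadingProtocol(
            label=_require(entry, "label", "protocol entry"), waveform=wf,
            peak_strain_ue=float(_require(entry, "peak_strain_ue", "protocol entry")),
            n_cycles=int(_require(entry, "n_cycles", "protocol entry")),
            days_per_week=float(_require(entry, "days_per_week", "protocol entry")),
            weeks=float(entry.get("weeks", 1.0))))
    observations = None
    if "observations" in data:
        observations = [BfrObservation(label=o["label"], B0=float(o["B0"]),
                                       se=o.get("se"), n=o.get("n"))
                        for o in data["observations"]]
    return protocols, observations


# -- parameters ------------------------------------------------------------

def write_params(params: ModelParameters, path, extra=None) -> None:
    payload = {"q": params.q, "eps_thres_ue": params.eps_thres_ue, "r_s": params.r_s,
               "p": params.p, "beta": params.beta, "p_d_beta": params.p_d_beta,
               "h_nm_per_ue": params.h_nm_per_ue}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_params(path) -> ModelParameters:
    data = read_config(path)
    return ModelParameters(
        q=float(_require(data, "q", str(path))),
        eps_thres_ue=float(_require(data, "eps_thres_ue", str(path))),
        r_s=float(_require(data, "r_s", str(path))),
        p=data.get("p"), beta=data.get("beta"), p_d_beta=data.get("p_d_beta"),
        h_nm_per_ue=data.get("h_nm_per_ue"))


# -- MAR tables ------------------------------------------------------------

def write_mar_table(mar_result, network, path) -> None:
    rows = []
    for ob_id, mar in mar_result.mar_um_day.items():
        cell = network.cells[network.index[ob_id]]
        rows.append({"osteoblast_id": ob_id, "x_um": cell.x_um, "y_um": cell.y_um,
                     "surface": cell.surface, "mar_um_per_day": mar})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mar_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"osteoblast_id", "x_um", "y_um", "mar_um_per_day"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(f"MAR table lacks columns: {sorted(missing)}")
    return df


# -- manifests -------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, command: str, inputs: dict, options: dict) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "osteoadapt",
        "version": __version__,
        "command": command,
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in inputs.items() if p is not None},
        "options": options,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
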