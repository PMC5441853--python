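"""Standard-format writers and configuration handling.

Covers RSML (Root System Markup Language) XML export of simulated systems,
per-axis and per-segment CSV summaries, YAML/JSON run configuration and a
run manifest that makes every output traceable to its inputs and seeds.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from lxml import etree

from .simulator import (
    AxisParameters,
    BranchScaling,
    RootAxis,
    RootSystem,
    SEGMENT_BOUNDS,
    SefSchedule,
    lateral_count_by_segment,
    length_distribution_along_tap,
)

__all__ = [
    "write_rsml",
    "write_axis_csv",
    "write_segment_csv",
    "load_config",
    "save_config",
    "system_from_config",
    "write_manifest",
]


# --------------------------------------------------------------------------
# RSML
# --------------------------------------------------------------------------

def _axis_element(axis: RootAxis, axis_id: list[int]) -> etree._Element:
    root = etree.Element("root")
    root.set("id", str(axis_id[0]))
    root.set("label", f"order{axis.order}")
    axis_id[0] += 1
    props = etree.SubElement(root, "properties")
    for key, value in (
        ("order", axis.order),
        ("emergence-day", round(axis.emergence_time, 6)),
        ("parent-position", round(axis.branch_arc, 6)),
        ("length", round(axis.length, 6)),
    ):
        prop = etree.SubElement(props, "property")
        prop.set("name", str(key))
        prop.set("value", str(value))
    geometry = etree.SubElement(root, "geometry")
    polyline = etree.SubElement(geometry, "polyline")
    for node in axis.nodes:
        pt = etree.SubElement(polyline, "point")
        pt.set("x", f"{node.position[0]:.6f}")
        pt.set("y", f"{node.position[1]:.6f}")
        pt.set("z", f"{node.position[2]:.6f}")
    functions = etree.SubElement(root, "functions")
    for name, values in (
        ("diameter", [2.0 * axis.params.radius] * len(axis.nodes)),
        ("age", [node.creation_time for node in axis.nodes]),
    ):
        fn = etree.SubElement(functions, "function")
        fn.set("name", name)
        fn.set("domain", "polyline")
        for v in values:
            sample = etree.SubElement(fn, "sample")
            sample.set("value", f"{v:.6f}")
    for child in axis.children:
        root.append(_axis_element(child, axis_id))
    return root


def write_rsml(system: RootSystem, path: str | Path, label: str = "plant") -> Path:
    """Export one simulated root system as a minimal conforming RSML scene."""
    path = Path(path)
    rsml = etree.Element("rsml")
    meta = etree.SubElement(rsml, "metadata")
    for key, value in (
        ("version", "1"),
        ("unit", "cm"),
        ("resolution", "1"),
        ("last-modified", _dt.datetime.now().isoformat(timespec="seconds")),
        ("software", "rootscale"),
    ):
        etree.SubElement(meta, key).text = value
    scene = etree.SubElement(rsml, "scene")
    plant = etree.SubElement(scene, "plant")
    plant.set("id", "1")
    plant.set("label", label)
    plant.append(_axis_element(system.tap, [1]))
    path.write_bytes(
        etree.tostring(rsml, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )
    return path


# --------------------------------------------------------------------------
# CSV summaries
# --------------------------------------------------------------------------

def write_axis_csv(system: RootSystem, path: str | Path) -> Path:
    """Per-axis summary: order, parent, branch position, emergence, length."""
    ids = {id(a): i for i, a in enumerate(system.axes)}
    rows = [
        {
            "axis_id": ids[id(a)],
            "order": a.order,
            "parent_id": ids[id(a.parent)] if a.parent is not None else -1,
            "branch_arc_cm": round(a.branch_arc, 6),
            "emergence_day": round(a.emergence_time, 6),
            "length_cm": round(a.length, 6),
            "n_nodes": len(a.nodes),
        }
        for a in system.axes
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_segment_csv(system: RootSystem, path: str | Path) -> Path:
    """Per-tap-segment lateral counts and root-length fractions."""
    counts = lateral_count_by_segment(system, SEGMENT_BOUNDS)
    fractions = length_distribution_along_tap(system, SEGMENT_BOUNDS)
    rows = [
        {
            "segment_top_cm": SEGMENT_BOUNDS[i],
            "segment_bottom_cm": SEGMENT_BOUNDS[i + 1],
            "lateral_count": counts[i],
            "length_fraction": fractions[i],
        }
        for i in range(len(counts))
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def plot_projection(system: RootSystem, path: str | Path, plane: str = "xz") -> Path:
    """Static 2-D projection of a root system for visual debugging.

    ``plane`` picks the projection axes; depth (z) is drawn downward.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = {"x": 0, "y": 1, "z": 2}
    try:
        i, j = idx[plane[0]], idx[plane[1]]
    except (KeyError, IndexError):
        raise ValueError("plane must combine two of x, y, z") from None
    fig, ax = plt.subplots(figsize=(4, 6))
    for axis in system.axes:
        pts = [n.position for n in axis.nodes]
        ax.plot(
            [p[i] for p in pts],
            [p[j] for p in pts],
            linewidth=max(0.3, 6.0 * axis.params.radius),
            color=["#5b3a1e", "#2d7d3a", "#76b041"][min(axis.order, 2)],
        )
    if plane[1] == "z":
        ax.invert_yaxis()
    ax.set_xlabel(f"{plane[0]} (cm)")
    ax.set_ylabel(f"{plane[1]} (cm)")
    ax.set_aspect("equal")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def _params_to_dict(p: AxisParameters) -> dict:
    return {
        "order": p.order,
        "r": p.r,
        "gf": p.gf,
        "apical_zone": p.apical_zone,
        "basal_zone": p.basal_zone,
        "interbranch": p.interbranch,
        "nob": p.nob,
        "theta": p.theta,
        "tropism_type": p.tropism_type,
        "tropism_N": p.tropism_N,
        "sigma_flex": p.sigma_flex,
        "radius": p.radius,
    }


def save_config(
    path: str | Path,
    params_by_order: dict[int, AxisParameters],
    sef: SefSchedule | None = None,
    sbf: BranchScaling | None = None,
    duration: float = 82.0,
    dt: float = 0.1,
    seed: int = 0,
) -> Path:
    doc = {
        "axes": [_params_to_dict(p) for p in params_by_order.values()],
        "duration": duration,
        "dt": dt,
        "seed": seed,
    }
    if sef is not None:
        doc["sef"] = {"onset_day": sef.onset_day, "peak_day": sef.peak_day}
    if sbf is not None:
        doc["sbf"] = {
            "segment_bounds": list(sbf.segment_bounds),
            "probabilities": list(sbf.probabilities),
        }
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON simulation config into constructor-ready pieces."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict) or "axes" not in doc:
        raise ValueError("config must be a mapping with an 'axes' list")
    params = {}
    for entry in doc["axes"]:
        try:
            p = AxisParameters(**entry)
        except (TypeError, ValueError) as err:
            raise ValueError(f"invalid axis entry {entry!r}: {err}") from err
        params[p.order] = p
    out = {
        "params_by_order": params,
        "sef": None,
        "sbf": None,
        "duration": float(doc.get("duration", 82.0)),
        "dt": float(doc.get("dt", 0.1)),
        "seed": int(doc.get("seed", 0)),
    }
    if "sef" in doc and doc["sef"]:
        out["sef"] = SefSchedule(**doc["sef"])
    if "sbf" in doc and doc["sbf"]:
        out["sbf"] = BranchScaling(
            tuple(doc["sbf"]["segment_bounds"]),
            tuple(doc["sbf"]["probabilities"]),
        )
    return out


def system_from_config(config: dict) -> RootSystem:
    return RootSystem(
        config["params_by_order"],
        sef=config["sef"],
        sbf=config["sbf"],
        seed=config["seed"],
    )


# --------------------------------------------------------------------------
# manifest
# --------------------------------------------------------------------------

def _fixture_checksums() -> dict[str, str]:
    out = {}
    data_dir = resources.files("rootscale").joinpath("data")
    for entry in sorted(data_dir.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".csv"):
            out[entry.name] = hashlib.sha256(entry.read_bytes()).hexdigest()
    return out


def write_manifest(
    path: str | Path, config_snapshot: dict, seeds: dict[str, int], notes: list[str] | None = None
) -> Path:
    """Record what produced a set of outputs: config, seeds, fixture
    checksums, package version and timestamp."""
    from . import __version__

    doc = {
        "package": "rootscale",
        "version": __version__,
        "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
        "seeds": seeds,
        "config": config_snapshot,
        "fixture_sha256": _fixture_checksums(),
        "notes": notes or [],
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, default=str), encoding="utf-8")
    return path
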