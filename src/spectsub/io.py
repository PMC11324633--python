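"""Config and data I/O: YAML experiment specs, HDF5 projection sets.

Volumes read/write themselves as NIfTI or raw+JSON (see
:mod:`spectsub.volumes`); this module covers the experiment configuration
round-trip and projection storage.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import yaml

from .experiments import ExperimentSpec, SweepSpec
from .phantom import PhantomConfig, TumorSpec
from .system import ProjectionSet, SystemGeometry

__all__ = ["load_experiment", "dump_experiment", "save_projections", "load_projections"]


def _phantom_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    tumors = [TumorSpec(**{**t, "center_mm": tuple(t["center_mm"])}) for t in d.pop("tumors", [])]
    for key in ("grid_shape", "liver_center_mm", "liver_semi_axes_mm",
                "body_center_mm", "body_semi_axes_mm"):
        if key in d:
            d[key] = tuple(d[key])
    return PhantomConfig(tumors=tumors, **d)


def load_experiment(path: str | Path) -> ExperimentSpec:
    """Build an :class:`ExperimentSpec` from a YAML file.

    Sections: ``phantom``, ``geometry``, ``sweep`` and top-level experiment
    fields (``n_iterations``, ``methods``, ``n_realizations``, ``base_seed``,
    ``erosion_voxels``...).  Missing fields fall back to package defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    phantom = _phantom_from_dict(raw.get("phantom", {}))
    geom_raw = dict(raw.get("geometry", {}))
    if "detector_shape" in geom_raw and geom_raw["detector_shape"] is not None:
        geom_raw["detector_shape"] = tuple(geom_raw["detector_shape"])
    geometry = SystemGeometry(**geom_raw)
    sweep = None
    if raw.get("sweep"):
        sweep = SweepSpec(parameter=raw["sweep"]["parameter"], values=raw["sweep"]["values"])
    exp_fields = {
        k: raw[k]
        for k in ("n_iterations", "n_subsets", "methods", "n_realizations",
                  "base_seed", "erosion_voxels")
        if k in raw
    }
    return ExperimentSpec(phantom=phantom, geometry=geometry, sweep=sweep, **exp_fields)


def dump_experiment(spec: ExperimentSpec, path: str | Path) -> None:
    """Write an experiment spec back to YAML (round-trips with
    :func:`load_experiment`)."""
    phantom = dataclasses.asdict(spec.phantom)
    phantom["tumors"] = [dataclasses.asdict(t) for t in spec.phantom.tumors]
    doc = {
        "phantom": _listify(phantom),
        "geometry": _listify(dataclasses.asdict(spec.geometry)),
        "n_iterations": spec.n_iterations,
        "n_subsets": spec.n_subsets,
        "methods": list(spec.methods),
        "n_realizations": spec.n_realizations,
        "base_seed": spec.base_seed,
        "erosion_voxels": spec.erosion_voxels,
    }
    if spec.sweep is not None:
        doc["sweep"] = {"parameter": spec.sweep.parameter, "values": list(spec.sweep.values)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj


def save_projections(proj: ProjectionSet, path: str | Path) -> None:
    """HDF5 with per-view angles and flags in attributes."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("counts", data=proj.counts, compression="gzip")
        f.create_dataset("angles_deg", data=proj.angles_deg)
        ds.attrs["noisy"] = proj.noisy
        ds.attrs["clipped"] = proj.clipped


def load_projections(path: str | Path) -> ProjectionSet:
    with h5py.File(path, "r") as f:
        ds = f["counts"]
        return ProjectionSet(
            counts=np.asarray(ds),
            angles_deg=np.asarray(f["angles_deg"]),
            noisy=bool(ds.attrs.get("noisy", False)),
            clipped=bool(ds.attrs.get("clipped", False)),
        )
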