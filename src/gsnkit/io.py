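"""File I/O: response arrays, fit results, and scenario containers.

HDF5 is the canonical container for 3-D response arrays and fit results;
NPY and CSV are conveniences.  The axis order of response arrays is always
``(unit, condition, trial)`` and is recorded in the file so it can be
checked on read rather than silently assumed.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .data import GaussianMoments, ResponseData
from .gsn import GSNResult
from .simulate import Scenario

__all__ = [
    "read_response_data",
    "write_response_data",
    "write_gsn_result",
    "read_gsn_result",
    "write_scenario",
    "read_scenario",
]

AXIS_ORDER = "unit,condition,trial"
_VERSION = "gsnkit-0.1.0"


class FileFormatError(ValueError):
    """File exists but does not match the expected layout."""


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix == ".npy":
        return "npy"
    if suffix == ".csv":
        return "csv"
    raise FileFormatError(
        f"cannot infer format from suffix {suffix!r} of {path}; pass format="
    )


def read_response_data(path, format: str | None = None, trial_paths=None) -> ResponseData:
    """Read a response array from HDF5, NPY, or CSV.

    HDF5 files hold a 3-D dataset ``responses`` with axis order
    ``(unit, condition, trial)`` plus optional label datasets.  NPY files
    hold the bare 3-D array.  A single CSV is a 2-D (condition x unit)
    slice and is rejected (the model needs t > 1 trials); pass
    ``trial_paths`` with one CSV per trial to assemble a 3-D array.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "responses" not in f:
                raise FileFormatError(f"{path}: no 'responses' dataset")
            ds = f["responses"]
            if ds.ndim != 3:
                raise FileFormatError(
                    f"{path}: 'responses' must be 3-D (unit, condition, trial), "
                    f"got rank {ds.ndim}"
                )
            order = ds.attrs.get("axis_order", AXIS_ORDER)
            if isinstance(order, bytes):
                order = order.decode()
            if order != AXIS_ORDER:
                raise FileFormatError(
                    f"{path}: axis_order is {order!r}, expected {AXIS_ORDER!r}; "
                    "refusing to transpose silently"
                )
            values = ds[()]
            units = (
                [s.decode() if isinstance(s, bytes) else str(s) for s in f["unit_labels"][()]]
                if "unit_labels" in f
                else None
            )
            conds = (
                [s.decode() if isinstance(s, bytes) else str(s) for s in f["condition_labels"][()]]
                if "condition_labels" in f
                else None
            )
        return ResponseData(values, units, conds)
    if fmt == "npy":
        values = np.load(path)
        if values.ndim != 3:
            raise FileFormatError(
                f"{path}: expected a 3-D (unit, condition, trial) array, got "
                f"rank {values.ndim}"
            )
        return ResponseData(values)
    if fmt == "csv":
        if not trial_paths:
            raise FileFormatError(
                f"{path}: a single 2-D CSV has no trial structure; the model "
                "requires t > 1 trials per condition — pass trial_paths with "
                "one CSV (condition x unit) per trial"
            )
        slices = [np.loadtxt(p, delimiter=",", ndmin=2) for p in trial_paths]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise FileFormatError(f"trial CSVs have differing shapes: {shapes}")
        return ResponseData(np.stack(slices, axis=2).transpose(1, 0, 2))
    raise FileFormatError(f"unknown format {fmt!r}")


def write_response_data(data: ResponseData, path) -> None:
    """Write a response array to HDF5 (with axis-order metadata)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("responses", data=data.values)
        ds.attrs["axis_order"] = AXIS_ORDER
        f.attrs["version"] = _VERSION
        if data.unit_labels is not None:
            f.create_dataset("unit_labels", data=[str(s) for s in data.unit_labels])
        if data.condition_labels is not None:
            f.create_dataset(
                "condition_labels", data=[str(s) for s in data.condition_labels]
            )


def write_gsn_result(fit: GSNResult, path, seed=None) -> None:
    """Serialize a fit result to HDF5, including shrinkage fractions,
    iteration count, library version, and the master seed."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal_mean", data=fit.signal.mean)
        f.create_dataset("signal_cov", data=fit.signal.covariance)
        f.create_dataset("noise_mean", data=fit.noise.mean)
        f.create_dataset("noise_cov", data=fit.noise.covariance)
        f.create_dataset("data_mean", data=fit.data_trialavg.mean)
        f.create_dataset("data_cov", data=fit.data_trialavg.covariance)
        f.create_dataset("noise_orig_cov", data=fit.noise_orig_cov)
        f.attrs["shrinkage_noise"] = float(fit.shrinkage_noise)
        f.attrs["shrinkage_data"] = float(fit.shrinkage_data)
        f.attrs["iterations"] = int(fit.iterations)
        f.attrs["converged"] = bool(fit.converged)
        f.attrs["n_conditions"] = int(fit.n_conditions)
        f.attrs["n_trials"] = int(fit.n_trials)
        f.attrs["version"] = _VERSION
        f.attrs["master_seed"] = "unset" if seed is None else int(seed)


def read_gsn_result(path) -> GSNResult:
    path = Path(path)
    with h5py.File(path, "r") as f:
        return GSNResult(
            signal=GaussianMoments(f["signal_mean"][()], f["signal_cov"][()]),
            noise=GaussianMoments(f["noise_mean"][()], f["noise_cov"][()]),
            data_trialavg=GaussianMoments(f["data_mean"][()], f["data_cov"][()]),
            noise_orig_cov=f["noise_orig_cov"][()],
            shrinkage_noise=float(f.attrs["shrinkage_noise"]),
            shrinkage_data=float(f.attrs["shrinkage_data"]),
            iterations=int(f.attrs["iterations"]),
            converged=bool(f.attrs["converged"]),
            n_conditions=int(f.attrs["n_conditions"]),
            n_trials=int(f.attrs["n_trials"]),
        )


def write_scenario(scenario: Scenario, path) -> None:
    """Write a ground-truth covariance-pair container (HDF5)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal_mean", data=scenario.signal.mean)
        f.create_dataset("signal_cov", data=scenario.signal.covariance)
        f.create_dataset("noise_mean", data=scenario.noise.mean)
        f.create_dataset("noise_cov", data=scenario.noise.covariance)
        f.attrs["name"] = scenario.name
        f.attrs["metadata"] = json.dumps(scenario.metadata)
        f.attrs["version"] = _VERSION


def read_scenario(path) -> Scenario:
    """Read a ground-truth scenario; supports user-supplied covariance
    pairs (e.g. empirically derived ground truths)."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        name = f.attrs.get("name", path.stem)
        if isinstance(name, bytes):
            name = name.decode()
        meta = f.attrs.get("metadata", "{}")
        if isinstance(meta, bytes):
            meta = meta.decode()
        return Scenario(
            str(name),
            GaussianMoments(f["signal_mean"][()], f["signal_cov"][()]),
            GaussianMoments(f["noise_mean"][()], f["noise_cov"][()]),
            json.loads(meta),
        )
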