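"""Serialization: HDF5 containers for datasets / forward models / source
timeseries, JSON for ground truth and reports, NIfTI volumes for voxel maps
on the source grid, plain text for melodies."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .beamform import ForwardModel, SourceTimeseries
from .synthetic import GroundTruth, SensorDataset, SourceGrid, SyntheticLeadfield

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_forward",
    "load_forward",
    "save_source",
    "load_source",
    "save_ground_truth",
    "grid_to_nifti",
]


def save_dataset(path, ds: SensorDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ds.data)
        f.attrs["sfreq"] = ds.sfreq
        f.attrs["is_epoched"] = ds.is_epoched
        f.attrs["meta"] = json.dumps({
            "ch_names": list(ds.ch_names),
            "ch_roles": list(ds.ch_roles),
            "grad_pairs": [list(p) for p in ds.grad_pairs],
            "condition_labels": list(ds.condition_labels),
        })
        if ds.times is not None:
            f.create_dataset("times", data=ds.times)
        if ds.onsets is not None:
            f.create_dataset("onsets", data=np.asarray(ds.onsets))


def load_dataset(path) -> SensorDataset:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        return SensorDataset(
            data=f["data"][()],
            sfreq=float(f.attrs["sfreq"]),
            ch_names=tuple(meta["ch_names"]),
            ch_roles=tuple(meta["ch_roles"]),
            grad_pairs=tuple(tuple(p) for p in meta["grad_pairs"]),
            times=f["times"][()] if "times" in f else None,
            onsets=f["onsets"][()] if "onsets" in f else None,
            condition_labels=tuple(meta["condition_labels"]),
            is_epoched=bool(f.attrs["is_epoched"]),
        )


def save_forward(path, fm: ForwardModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coordinates", data=fm.grid.coordinates)
        f.attrs["spacing"] = fm.grid.spacing
        f.create_dataset("leadfield3", data=fm.leadfield3)
        if fm.leadfield1 is not None:
            f.create_dataset("leadfield1", data=fm.leadfield1)
        if fm.orientations is not None:
            f.create_dataset("orientations", data=fm.orientations)


def load_forward(path) -> ForwardModel:
    with h5py.File(path, "r") as f:
        grid = SourceGrid(coordinates=f["coordinates"][()],
                          spacing=float(f.attrs["spacing"]))
        return ForwardModel(
            grid=grid,
            leadfield3=f["leadfield3"][()],
            leadfield1=f["leadfield1"][()] if "leadfield1" in f else None,
            orientations=f["orientations"][()] if "orientations" in f else None,
        )


def save_source(path, src: SourceTimeseries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("q", data=src.q)
        f.attrs["sfreq"] = src.sfreq
        f.attrs["absolute_applied"] = src.absolute_applied
        f.attrs["condition_labels"] = json.dumps(list(src.condition_labels))
        if src.times is not None:
            f.create_dataset("times", data=src.times)


def load_source(path) -> SourceTimeseries:
    with h5py.File(path, "r") as f:
        return SourceTimeseries(
            q=f["q"][()],
            sfreq=float(f.attrs["sfreq"]),
            times=f["times"][()] if "times" in f else None,
            condition_labels=tuple(json.loads(f.attrs["condition_labels"])),
            absolute_applied=bool(f.attrs["absolute_applied"]),
        )


def save_ground_truth(path, truth: GroundTruth) -> None:
    d = {
        "slow_voxels": [list(v) for v in truth.slow_voxels],
        "slow_peak_times": list(truth.slow_peak_times),
        "fast_voxels": list(truth.fast_voxels),
        "orientations": {str(k): list(map(float, v))
                         for k, v in truth.orientations.items()},
        "active_voxels": list(truth.active_voxels),
        "amplitude_ratio": truth.amplitude_ratio,
    }
    with open(path, "w") as f:
        json.dump(d, f, indent=1)


def grid_to_nifti(values: np.ndarray, grid: SourceGrid):
    """Rasterize per-voxel values to a NIfTI volume by nearest lattice cell.

    The affine maps volume index (i, j, k) to mm as
    ``coord = origin + spacing * index`` with origin the minimum grid corner.
    """
    import nibabel as nib

    coords = grid.coordinates
    origin = coords.min(axis=0)
    idx = np.round((coords - origin) / grid.spacing).astype(int)
    shape = idx.max(axis=0) + 1
    vol = np.zeros(shape, dtype=float)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = values
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * grid.spacing
    affine[:3, 3] = origin
    return nib.Nifti1Image(vol, affine)
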