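"""HDF5 / NIfTI persistence for k-space data, dictionaries and maps.

k-space container layout (version ``aquamap-kspace-1``)::

    /profiles/data        complex64 (n_profiles, n_echoes, n_coils, n_readout)
    /profiles/coords      int32 (n_profiles-aligned shot table below)
    /profiles/times       float64 ms
    /profiles/motion      float64 surrogate amplitude
    /profiles/weights     float64 soft-gating weights (optional)
    /calibration          complex (2, n_coils, n_readout)
    /noise_cov            complex (n_coils, n_coils)
    /sampling/*           shot-table arrays of the CASPR schedule
    attrs: layout, timing fields, grid metadata

Dictionaries and bases share one container (version ``aquamap-dict-1``) with
``/atoms`` (float32 real-valued timelines), ``/params`` and optional
``/basis/*``.  Parameter maps go to NIfTI (one volume per map, voxel size in
the header) plus a JSON sidecar with grid and provenance metadata.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .matching import ParameterMaps
from .phantom import KSpaceData
from .sequence import BlochDictionary, DictionaryGrid, SequenceTiming
from .subspace import SubspaceBasis
from .trajectory import CASPRSampling

__all__ = [
    "write_kspace", "read_kspace",
    "save_dictionary", "load_dictionary",
    "save_basis", "load_basis",
    "write_maps", "read_map",
    "config_hash",
]

KSPACE_LAYOUT = "aquamap-kspace-1"
DICT_LAYOUT = "aquamap-dict-1"

_TIMING_FIELDS = [
    "n_blocks", "block_duration", "prep_durations", "prep_angles", "td1",
    "prep_to_readout_gap", "shots_per_block", "profiles_per_shot", "tr", "te",
    "flip_deg", "n_repetitions",
]


def _write_timing(grp, timing: SequenceTiming):
    for f in _TIMING_FIELDS:
        grp.attrs[f"timing_{f}"] = getattr(timing, f)


def _read_timing(grp) -> SequenceTiming:
    kw = {}
    for f in _TIMING_FIELDS:
        v = grp.attrs[f"timing_{f}"]
        if isinstance(v, np.ndarray):
            v = tuple(v.tolist())
        elif isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        kw[f] = v
    return SequenceTiming(**kw)


def write_kspace(kdata: KSpaceData, path):
    """Persist a KSpaceData container (byte-faithful round trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["layout"] = KSPACE_LAYOUT
        p = f.create_group("profiles")
        p.create_dataset("data", data=kdata.data)
        p.create_dataset("coords", data=kdata.sampling.profile_coords)
        p.create_dataset("times", data=kdata.times)
        p.create_dataset("motion", data=kdata.motion_amplitude)
        if kdata.weights is not None:
            p.create_dataset("weights", data=kdata.weights)
        f.create_dataset("calibration", data=kdata.calibration)
        f.create_dataset("noise_cov", data=kdata.noise_covariance)
        s = f.create_group("sampling")
        sp = kdata.sampling
        s.create_dataset("coords", data=sp.coords)
        s.create_dataset("block_index", data=sp.block_index)
        s.create_dataset("shot_index", data=sp.shot_index)
        s.create_dataset("repetition", data=sp.repetition)
        s.create_dataset("golden_index", data=sp.golden_index)
        s.attrs["grid_shape"] = sp.grid_shape
        s.attrs["acceleration"] = sp.acceleration
        s.attrs["n_repetitions"] = sp.n_repetitions
        s.attrs["shots_per_block"] = sp.shots_per_block
        f.attrs["readout_oversampling"] = kdata.readout_oversampling
        f.attrs["nx"] = kdata.nx
        f.attrs["voxel_size"] = kdata.voxel_size
        _write_timing(f, kdata.timing)


def read_kspace(path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        if f.attrs.get("layout") != KSPACE_LAYOUT:
            raise ValueError(
                f"not a {KSPACE_LAYOUT} container: {f.attrs.get('layout')!r}"
            )
        if "profiles/coords" not in f:
            raise ValueError("malformed container: missing /profiles/coords")
        s = f["sampling"]
        sampling = CASPRSampling(
            coords=s["coords"][()],
            block_index=s["block_index"][()],
            shot_index=s["shot_index"][()],
            repetition=s["repetition"][()],
            golden_index=s["golden_index"][()],
            grid_shape=tuple(int(v) for v in s.attrs["grid_shape"]),
            acceleration=float(s.attrs["acceleration"]),
            n_repetitions=int(s.attrs["n_repetitions"]),
            shots_per_block=int(s.attrs["shots_per_block"]),
        )
        p = f["profiles"]
        return KSpaceData(
            data=p["data"][()],
            sampling=sampling,
            timing=_read_timing(f),
            calibration=f["calibration"][()],
            noise_covariance=f["noise_cov"][()],
            motion_amplitude=p["motion"][()],
            times=p["times"][()],
            readout_oversampling=int(f.attrs["readout_oversampling"]),
            nx=int(f.attrs["nx"]),
            voxel_size=float(f.attrs["voxel_size"]),
            weights=p["weights"][()] if "weights" in p else None,
        )


def save_dictionary(dictionary: BlochDictionary, path, basis: SubspaceBasis | None = None):
    with h5py.File(path, "w") as f:
        f.attrs["layout"] = DICT_LAYOUT
        f.create_dataset("atoms", data=dictionary.atoms)
        f.create_dataset("params", data=dictionary.params)
        g = f.create_group("grid")
        g.create_dataset("t1_values", data=dictionary.grid.t1_values)
        g.create_dataset("t2_values", data=dictionary.grid.t2_values)
        g.create_dataset("b0_values", data=dictionary.grid.b0_values)
        g.attrs["b1_scale"] = dictionary.grid.b1_scale
        _write_timing(f, dictionary.timing)
        if basis is not None:
            _save_basis_group(f, basis)


def load_dictionary(path):
    with h5py.File(path, "r") as f:
        if f.attrs.get("layout") != DICT_LAYOUT:
            raise ValueError(f"not a {DICT_LAYOUT} container")
        g = f["grid"]
        grid = DictionaryGrid(
            t1_values=g["t1_values"][()],
            t2_values=g["t2_values"][()],
            b0_values=g["b0_values"][()],
            b1_scale=float(g.attrs["b1_scale"]),
        )
        d = BlochDictionary(
            atoms=f["atoms"][()],
            params=f["params"][()],
            grid=grid,
            timing=_read_timing(f),
        )
        basis = _load_basis_group(f) if "basis" in f else None
    return d, basis


def _save_basis_group(f, basis: SubspaceBasis):
    b = f.require_group("basis")
    for name in ("phi", "singular_values"):
        if name in b:
            del b[name]
        b.create_dataset(name, data=getattr(basis, name))
    b.attrs["k"] = basis.k


def _load_basis_group(f) -> SubspaceBasis:
    b = f["basis"]
    return SubspaceBasis(
        phi=b["phi"][()], singular_values=b["singular_values"][()],
        k=int(b.attrs["k"]),
    )


def save_basis(basis: SubspaceBasis, path):
    """Store a basis into an existing (or new) dictionary container."""
    with h5py.File(path, "a") as f:
        f.attrs.setdefault("layout", DICT_LAYOUT)
        _save_basis_group(f, basis)


def load_basis(path) -> SubspaceBasis:
    with h5py.File(path, "r") as f:
        return _load_basis_group(f)


# ---------------------------------------------------------------------------
# NIfTI maps
# ---------------------------------------------------------------------------

def write_maps(maps: ParameterMaps, out_dir, voxel_size: float = 3.0,
               metadata: dict | None = None, prefix: str = "aquamap"):
    """Write wT1/wT2/PD/mask NIfTI volumes plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    files = {}
    for name, vol, dtype in (
        ("wt1", maps.wt1, np.float32),
        ("wt2", maps.wt2, np.float32),
        ("pd_water", np.abs(maps.pd_water), np.float32),
        ("mask", maps.mask, np.uint8),
    ):
        img = nib.Nifti1Image(np.asarray(vol, dtype), affine)
        img.header.set_zooms((voxel_size,) * 3)
        fn = out_dir / f"{prefix}_{name}.nii.gz"
        nib.save(img, fn)
        files[name] = fn.name
    side = dict(metadata or {})
    side["files"] = files
    side["voxel_size_mm"] = voxel_size
    side["clamped_voxels"] = int(maps.clamped_voxels)
    with open(out_dir / f"{prefix}_maps.json", "w") as fh:
        json.dump(side, fh, indent=2, default=str)
    return files


def read_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def config_hash(config: dict) -> str:
    """Short content hash of a configuration mapping (provenance tag)."""
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
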