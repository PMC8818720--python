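"""File formats: flatmaps and velocity grids as HDF5, surfaces as PLY/OBJ,
velocity volumes alternatively as per-component NIfTI.

Every HDF5 artifact records the seed and a config hash so that workflow
outputs are traceable and reruns comparable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .flatmap import Flatmap, GridSource
from .geometry import QuadSurface


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_provenance(g: h5py.Group, seed: int | None, config: dict | None) -> None:
    if seed is not None:
        g.attrs["seed"] = int(seed)
    if config is not None:
        g.attrs["config_hash"] = config_hash(config)
        g.attrs["config_json"] = json.dumps(config, sort_keys=True, default=str)


def save_flatmap(path, fm: Flatmap, seed: int | None = None, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=fm.values)
        f.create_dataset("mask", data=fm.mask)
        f.attrs["channel_names"] = list(fm.channel_names)
        _write_provenance(f, seed, config)


def load_flatmap(path) -> Flatmap:
    with h5py.File(path, "r") as f:
        return Flatmap(
            f["values"][...],
            f["mask"][...].astype(bool),
            tuple(str(c) for c in f.attrs.get("channel_names", [])),
        )


def save_velocity_grid(path, src: GridSource, seed: int | None = None,
                       config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        for i, name in enumerate(("vx", "vy", "vz")):
            f.create_dataset(name, data=src.values[..., i])
        f.attrs["dx"] = src.spacing
        f.attrs["origin"] = src.origin
        f.attrs["venc"] = src.venc
        _write_provenance(f, seed, config)


def read_velocity_volume(path) -> GridSource:
    """Load a uniform-grid velocity source.

    Accepts an HDF5 file (datasets vx, vy, vz; attrs dx, origin, venc) or a
    NIfTI file holding one velocity component, in which case the two sibling
    components are found by substituting vx/vy/vz in the name. Missing
    spacing metadata fails loudly naming the field.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            for name in ("vx", "vy", "vz"):
                if name not in f:
                    raise KeyError(f"velocity grid missing dataset {name!r}")
            if "dx" not in f.attrs:
                raise KeyError("velocity grid missing attribute 'dx'")
            values = np.stack([f[n][...] for n in ("vx", "vy", "vz")], axis=-1)
            spacing = np.atleast_1d(np.asarray(f.attrs["dx"], dtype=float))
            if spacing.size == 1:
                spacing = np.repeat(spacing, 3)
            origin = np.asarray(f.attrs.get("origin", (0.0, 0.0, 0.0)), dtype=float)
            venc = float(f.attrs.get("venc", 1.5))
        return GridSource(values, spacing=spacing, origin=origin, venc=venc)
    if ".nii" in path.suffixes or path.suffix == ".nii":
        return _read_nifti_components(path)
    raise ValueError(f"unsupported velocity volume format: {path.name}")


def _read_nifti_components(path: Path) -> GridSource:
    import nibabel as nib

    name = path.name
    comp = next((c for c in ("vx", "vy", "vz") if c in name), None)
    if comp is None:
        raise ValueError("NIfTI velocity files must be named with vx/vy/vz components")
    arrays = []
    spacing = None
    origin = (0.0, 0.0, 0.0)
    for c in ("vx", "vy", "vz"):
        p = path.with_name(name.replace(comp, c))
        if not p.exists():
            raise FileNotFoundError(f"missing component file {p.name}")
        img = nib.load(str(p))
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise ValueError("NIfTI header missing voxel spacing ('pixdim')")
        spacing = np.asarray(zooms, dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        arrays.append(np.asarray(img.dataobj, dtype=float))
    return GridSource(np.stack(arrays, axis=-1), spacing=spacing, origin=origin)


def save_surface(path, surface: QuadSurface) -> None:
    """Write a quad surface as PLY/OBJ (triangulated faces, grid preserved by
    row-major vertex order)."""
    import trimesh

    quads = surface.quad_faces()
    tris = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]], axis=0)
    mesh = trimesh.Trimesh(vertices=surface.points(), faces=tris, process=False)
    mesh.export(str(path))


def load_surface_points(path) -> np.ndarray:
    """Vertices of a PLY/OBJ mesh as an (N, 3) point cloud (mm)."""
    import trimesh

    mesh = trimesh.load(str(path), process=False)
    return np.asarray(mesh.vertices, dtype=float)


def load_surface_grid(path, n_u: int = 48, n_v: int = 93) -> QuadSurface:
    """Rebuild a QuadSurface from a mesh written by :func:`save_surface`."""
    pts = load_surface_points(path)
    if len(pts) != n_u * n_v:
        raise ValueError(f"expected {n_u * n_v} vertices, found {len(pts)}")
    return QuadSurface(pts.reshape(n_u, n_v, 3))


def save_point_cloud(path, points: np.ndarray, velocities: np.ndarray | None = None,
                     wss: np.ndarray | None = None) -> None:
    """HDF5 table of scattered samples (x,y,z[,vx,vy,vz][,wssx,wssy,wssz])."""
    with h5py.File(path, "w") as f:
        f.create_dataset("points", data=np.asarray(points, dtype=float))
        if velocities is not None:
            f.create_dataset("velocities", data=np.asarray(velocities, dtype=float))
        if wss is not None:
            f.create_dataset("wss", data=np.asarray(wss, dtype=float))


def load_point_cloud(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        for k in ("points", "velocities", "wss"):
            if k in f:
                out[k] = f[k][...]
    return out


def save_weights(path, model, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        for k, v in model.state_dict().items():
            f.create_dataset(k, data=v)
        f.attrs["filters"] = list(model.config.filters)
        f.attrs["in_channels"] = model.config.in_channels
        f.attrs["out_channels"] = model.config.out_channels
        if config is not None:
            f.attrs["config_json"] = json.dumps(config, sort_keys=True, default=str)
            f.attrs["config_hash"] = config_hash(config)


def load_weights(path):
    from .nn.unet import NetConfig, WSSNet

    with h5py.File(path, "r") as f:
        cfg = NetConfig(
            in_channels=int(f.attrs["in_channels"]),
            out_channels=int(f.attrs["out_channels"]),
            filters=tuple(int(x) for x in f.attrs["filters"]),
        )
        state = {k: f[k][...] for k in f.keys()}
    model = WSSNet(cfg)
    model.load_state_dict(state)
    return model
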