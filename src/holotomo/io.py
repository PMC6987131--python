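"""Readers/writers: hologram stacks (HDF5/TIFF + YAML sidecar), RI volumes,
CTF models, calibration tables, and the run configuration.

HDF5 is the lossless interchange format (group layout documented in the
README: /holograms, /scan, /calibration, /reconstruction, /truth); TIFF is
the microscopy-ecosystem export (uint16 scaled stacks with an ImageJ-style
resolution tag, float32 volumes).  All files carry a schema tag; readers
reject newer major versions.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile
import yaml

from .forward import HologramFrame, HologramStack, JitterModel, NoiseModel
from .optics import CTFModel, OpticsConfig, ScanPattern
from .tomography import ReconParams

SCHEMA_VERSION = "1.0"


def _check_schema(tag: str, where: str) -> None:
    major = str(tag).split(".")[0]
    if int(major) > int(SCHEMA_VERSION.split(".")[0]):
        raise ValueError(
            f"{where}: schema version {tag} is newer than supported "
            f"({SCHEMA_VERSION})")


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a run: optics, scan, noise/jitter,
    reconstruction parameters, seeds and output paths."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    n_angles: int = 240
    scan_scheme: str = "ring"
    ring_fraction: float = 0.95
    q_ref: list | None = None             # rad/nm; None -> package default
    jitter_sigma_bins: float = 0.0        # sd in detector frequency bins
    photons: float | None = None          # None -> noiseless
    seed: int = 0
    recon: ReconParams = field(default_factory=ReconParams)
    phantom: str = "organelles"           # named phantom for `simulate`
    output: str = "stack.h5"

    _KEYS = ("optics", "n_angles", "scan_scheme", "ring_fraction", "q_ref",
             "jitter_sigma_bins", "photons", "seed", "recon", "phantom",
             "output")

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "optics": self.optics.to_dict(),
            "n_angles": self.n_angles,
            "scan_scheme": self.scan_scheme,
            "ring_fraction": self.ring_fraction,
            "q_ref": self.q_ref,
            "jitter_sigma_bins": self.jitter_sigma_bins,
            "photons": self.photons,
            "seed": self.seed,
            "recon": self.recon.to_dict(),
            "phantom": self.phantom,
            "output": self.output,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        _check_schema(d.pop("schema", SCHEMA_VERSION), "run config")
        unknown = set(d) - set(cls._KEYS)
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        if "optics" in d:
            d["optics"] = OpticsConfig.from_dict(d["optics"])
        if "recon" in d:
            d["recon"] = ReconParams(**d["recon"])
        return cls(**d)


def read_run_config(path: str) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def write_run_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# --------------------------------------------------------------------------
# Hologram stacks
# --------------------------------------------------------------------------

def write_stack(stack: HologramStack, path: str, truth=None) -> None:
    """Write a hologram stack.

    ``.h5``: lossless float64 intensities plus scan/config metadata and an
    optional /truth group (never read by the reconstruction path).
    ``.tif``: uint16-scaled multipage TIFF with a ``<path>.yaml`` sidecar.
    """
    frames = np.stack([f.intensity for f in stack.frames])
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as fh:
            fh.attrs["schema"] = SCHEMA_VERSION
            fh.create_dataset("holograms/intensity", data=frames)
            fh.create_dataset("scan/vectors", data=stack.scan.vectors)
            fh["scan"].attrs["scheme"] = stack.scan.scheme
            fh.create_dataset("q_ref", data=np.asarray(stack.q_ref))
            fh.attrs["config"] = yaml.safe_dump(stack.config.to_dict())
            if truth is not None:
                fh.create_dataset("truth/true_vectors", data=truth.true_vectors)
                fh["truth"].attrs["jitter_sigma"] = truth.jitter.sigma
                fh["truth"].attrs["jitter_seed"] = truth.jitter.seed
    elif path.endswith((".tif", ".tiff")):
        lo, hi = float(frames.min()), float(frames.max())
        scale = (65535.0 / (hi - lo)) if hi > lo else 1.0
        data16 = np.round((frames - lo) * scale).astype(np.uint16)
        tifffile.imwrite(path, data16, photometric="minisblack")
        sidecar = {
            "schema": SCHEMA_VERSION,
            "intensity_offset": lo,
            "intensity_scale": scale,
            "q_ref": np.asarray(stack.q_ref).tolist(),
            "scan": stack.scan.to_dict(),
            "config": stack.config.to_dict(),
        }
        with open(path + ".yaml", "w") as fh:
            yaml.safe_dump(sidecar, fh, sort_keys=False)
    else:
        raise ValueError(f"unsupported stack extension: {path}")


def read_stack(path: str) -> HologramStack:
    """Read a hologram stack written by :func:`write_stack`."""
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as fh:
            _check_schema(fh.attrs.get("schema", "0"), path)
            for key in ("holograms/intensity", "scan/vectors", "q_ref"):
                if key not in fh:
                    raise ValueError(f"{path}: missing required dataset {key}")
            if "config" not in fh.attrs:
                raise ValueError(f"{path}: missing required attribute 'config'")
            frames = fh["holograms/intensity"][()]
            vectors = fh["scan/vectors"][()]
            scheme = fh["scan"].attrs.get("scheme", "ring")
            q_ref = fh["q_ref"][()]
            config = OpticsConfig.from_dict(yaml.safe_load(fh.attrs["config"]))
    elif path.endswith((".tif", ".tiff")):
        sidecar_path = path + ".yaml"
        if not os.path.exists(sidecar_path):
            raise ValueError(
                f"{path}: missing sidecar {sidecar_path} (required keys: "
                "schema, intensity_offset, intensity_scale, q_ref, scan, config)")
        with open(sidecar_path) as fh:
            meta = yaml.safe_load(fh)
        required = {"intensity_offset", "intensity_scale", "q_ref", "scan", "config"}
        missing = required - set(meta)
        if missing:
            raise ValueError(f"{sidecar_path}: missing keys {sorted(missing)}")
        _check_schema(meta.get("schema", SCHEMA_VERSION), path)
        data16 = tifffile.imread(path)
        frames = data16.astype(np.float64) / meta["intensity_scale"] \
            + meta["intensity_offset"]
        vectors = np.asarray(meta["scan"]["vectors"], dtype=float)
        scheme = meta["scan"].get("scheme", "ring")
        q_ref = np.asarray(meta["q_ref"], dtype=float)
        config = OpticsConfig.from_dict(meta["config"])
    else:
        raise ValueError(f"unsupported stack extension: {path}")
    if len(frames) != len(vectors):
        raise ValueError(
            f"{path}: {len(frames)} frames but scan declares {len(vectors)}")
    scan = ScanPattern(vectors=vectors, scheme=scheme)
    frame_objs = [HologramFrame(intensity=np.asarray(frames[i], dtype=np.float64),
                                index=i, k_designated=vectors[i])
                  for i in range(len(frames))]
    return HologramStack(frames=frame_objs, scan=scan,
                         q_ref=np.asarray(q_ref, dtype=float), config=config)


# --------------------------------------------------------------------------
# Volumes, CTF, calibration tables
# --------------------------------------------------------------------------

def write_volume(volume, path: str, diagnostics: dict | None = None) -> None:
    """RI (or any scalar) volume to float32 multipage TIFF (Z pages, with
    resolution metadata) or HDF5 (with a diagnostics group)."""
    data = np.asarray(getattr(volume, "data", volume), dtype=np.float32)
    voxel = getattr(volume, "voxel_size", (65.0, 65.0, 150.0))
    if path.endswith((".tif", ".tiff")):
        pages = np.transpose(data, (2, 1, 0))    # (z, y, x) pages for ImageJ
        tifffile.imwrite(
            path, pages, photometric="minisblack", imagej=True,
            resolution=(1e3 / voxel[0], 1e3 / voxel[1]),
            metadata={"spacing": voxel[2] / 1e3, "unit": "um", "axes": "ZYX"})
    elif path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as fh:
            fh.attrs["schema"] = SCHEMA_VERSION
            ds = fh.create_dataset("reconstruction/ri", data=data)
            ds.attrs["voxel_size_nm"] = np.asarray(voxel, dtype=float)
            if diagnostics:
                grp = fh.create_group("reconstruction/diagnostics")
                for key, val in diagnostics.items():
                    if np.isscalar(val):
                        grp.attrs[key] = val
    else:
        raise ValueError(f"unsupported volume extension: {path}")


def read_volume(path: str) -> np.ndarray:
    if path.endswith((".tif", ".tiff")):
        return np.transpose(tifffile.imread(path), (2, 1, 0))
    with h5py.File(path, "r") as fh:
        _check_schema(fh.attrs.get("schema", "0"), path)
        return fh["reconstruction/ri"][()]


def write_ctf(ctf: CTFModel, path: str, grid_spacing) -> None:
    """CTF weights to HDF5 with frequency-grid spacing attributes."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema"] = SCHEMA_VERSION
        ds = fh.create_dataset("ctf/weights", data=ctf.weights)
        ds.attrs["provenance"] = ctf.provenance
        ds.attrs["grid_spacing_rad_per_nm"] = np.asarray(grid_spacing, dtype=float)


def read_ctf(path: str) -> CTFModel:
    with h5py.File(path, "r") as fh:
        _check_schema(fh.attrs.get("schema", "0"), path)
        weights = fh["ctf/weights"][()]
    return CTFModel(weights=weights, provenance="loaded")


CALIBRATION_HEADER = ("frame", "designated_x", "designated_y",
                      "refined_x", "refined_y", "residual", "converged")


def write_calibration_csv(calib, path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CALIBRATION_HEADER)
        for e in calib.entries:
            writer.writerow([e.frame_index,
                             e.k_designated[0], e.k_designated[1],
                             e.k_refined[0], e.k_refined[1],
                             e.residual, int(e.converged)])


def read_tracks_csv(path: str) -> dict:
    """Object tracks from CSV with columns t, x, y[, z], id -> dict id -> array."""
    tracks: dict = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            tid = row.get("id", "0")
            point = [float(row["t"]), float(row["x"]), float(row["y"])]
            if "z" in row and row["z"] not in (None, ""):
                point.append(float(row["z"]))
            tracks.setdefault(tid, []).append(point)
    return {k: np.asarray(sorted(v), dtype=float) for k, v in tracks.items()}


def read_fluorescence_mask(path: str) -> np.ndarray:
    """Single-page TIFF fluorescence mask -> boolean array."""
    return np.asarray(tifffile.imread(path)) > 0
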