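"""Raw-data HDF5 schema, NIfTI output, and run manifests.

Raw k-space schema (version 1.0), one file per run:

    /data         complex64 (shot, coil, pe_line, readout_sample)
    /navigators   complex64 (shot, coil, nav_line, readout_sample)
    /traj         float32   (shot, pe_line, readout_sample, 3)  kx,ky,kz cycles/FOV
    /pe_indices   int32     (shot, pe_line)
    /angles_deg   float64   (shot,)
    /protocol     group, protocol fields as attributes
    /truth        complex64 (x, y, z, t), optional ground-truth series
    /meta/k0_truth_rad  optional injected k0 series

Root attributes: ``schema_version``, ``noise_sd``.  Reads are validated and
failures name the offending dataset; version mismatches are refused rather
than reinterpreted.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field

import h5py
import nibabel as nib
import numpy as np

from . import __version__
from .errors import SchemaError
from .simulator import ImageSeries, RawKspace
from .trajectory import BladeSampling, TurbineProtocol

SCHEMA_VERSION = "1.0"


def write_raw(path, raw: RawKspace) -> None:
    """Persist a :class:`RawKspace` to the HDF5 raw-data schema."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["noise_sd"] = float(raw.noise_sd)
        fh.create_dataset("data", data=raw.data.astype(np.complex64))
        fh.create_dataset("navigators", data=raw.navigators.astype(np.complex64))
        traj = np.stack([b.readout_coords for b in raw.blades]).astype(np.float32)
        fh.create_dataset("traj", data=traj)
        fh.create_dataset("pe_indices",
                          data=np.stack([b.pe_indices for b in raw.blades]).astype(np.int32))
        fh.create_dataset("angles_deg",
                          data=np.array([b.angle_deg for b in raw.blades]))
        grp = fh.create_group("protocol")
        for k, v in raw.protocol.to_dict().items():
            grp.attrs[k] = v
        if raw.truth is not None:
            ds = fh.create_dataset("truth", data=raw.truth.data.astype(np.complex64))
            ds.attrs["tr_vol_s"] = raw.truth.tr_vol_s
            ds.attrs["voxel_size_mm"] = list(raw.truth.voxel_size_mm)
        meta = fh.create_group("meta")
        if "k0_truth_rad" in raw.meta:
            meta.create_dataset("k0_truth_rad", data=np.asarray(raw.meta["k0_truth_rad"]))
        if "corrections" in raw.meta:
            meta.attrs["corrections"] = json.dumps(raw.meta["corrections"])


def read_raw(path) -> RawKspace:
    """Load a raw-data file, validating the schema (lossless round-trip)."""
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("schema_version")
        if version is None:
            raise SchemaError("missing root attribute 'schema_version'")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"schema version {version!r} not supported (expected {SCHEMA_VERSION!r})")
        for name in ("data", "navigators", "traj", "pe_indices", "angles_deg"):
            if name not in fh:
                raise SchemaError(f"missing dataset '/{name}'")
        if "protocol" not in fh:
            raise SchemaError("missing group '/protocol'")
        protocol = TurbineProtocol.from_dict(dict(fh["protocol"].attrs))
        data = fh["data"][...].astype(complex)
        navs = fh["navigators"][...].astype(complex)
        traj = fh["traj"][...].astype(float)
        pe = fh["pe_indices"][...]
        angles = fh["angles_deg"][...]
        blades = [
            BladeSampling(shot_index=s, angle_deg=float(angles[s]), pe_indices=pe[s],
                          readout_coords=traj[s],
                          navigator_coords=np.repeat(traj[s][:1] * [1.0, 1.0, 0.0],
                                                     protocol.n_navigators, axis=0))
            for s in range(data.shape[0])
        ]
        truth = None
        if "truth" in fh:
            ds = fh["truth"]
            truth = ImageSeries(ds[...].astype(complex),
                                tuple(ds.attrs.get("voxel_size_mm", (1.0, 1.0, 1.0))),
                                tr_vol_s=float(ds.attrs.get("tr_vol_s", 1.0)))
        meta = {}
        if "meta" in fh:
            if "k0_truth_rad" in fh["meta"]:
                meta["k0_truth_rad"] = fh["meta"]["k0_truth_rad"][...]
            if "corrections" in fh["meta"].attrs:
                meta["corrections"] = json.loads(fh["meta"].attrs["corrections"])
        return RawKspace(data=data, navigators=navs, blades=blades, protocol=protocol,
                         noise_sd=float(fh.attrs.get("noise_sd", 0.0)),
                         truth=truth, meta=meta)


def write_nifti(path, series_or_volume, voxel_size_mm=(1.0, 1.0, 1.0),
                tr_s: float = 1.0) -> None:
    """Write a magnitude image/time-series as NIfTI-1, RAS, float32."""
    if isinstance(series_or_volume, ImageSeries):
        data = series_or_volume.magnitude()
        voxel_size_mm = series_or_volume.voxel_size_mm
        tr_s = series_or_volume.tr_vol_s
    else:
        data = np.abs(np.asarray(series_or_volume))
    affine = np.diag(list(voxel_size_mm[:3]) + [1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    zooms = tuple(voxel_size_mm)[:min(data.ndim, 3)]
    if data.ndim == 4:
        zooms = zooms + (tr_s,)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.header.get_zooms()


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI output."""

    command: str
    config: dict
    seeds: dict
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    status: str = "ok"

    def write(self, path) -> None:
        payload = {
            "command": self.command,
            "config": self.config,
            "seeds": self.seeds,
            "inputs": [str(p) for p in self.inputs],
            "outputs": [str(p) for p in self.outputs],
            "status": self.status,
            "software_version": __version__,
            "python": sys.version.split()[0],
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
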