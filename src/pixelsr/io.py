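"""Record/image formats and the reproducibility manifest.

Records travel as HDF5 (sample array + config attributes + optional
ground-truth group in one file) or as a flat binary sample dump with a JSON
sidecar for interoperability with digitizer streaming dumps.  Reconstructed
images are 16-bit TIFF with the pixel pitch and the linear intensity scaling
recorded in the image description, so a round trip recovers physical values
to 16-bit quantization.  Every CLI run serializes a RunManifest alongside
its outputs; deterministic stages re-run bit-identically from the same
manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .synth import GroundTruth, RawRecord, SceneSpec
from .reconstruct import HRImage
from .warpgeom import AcquisitionConfig


class RecordFormatError(ValueError):
    pass


def write_record(record: RawRecord, path: str | Path) -> None:
    """Write a record as HDF5 (.h5/.hdf5) or flat binary + JSON sidecar."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=record.samples)
            for k, v in record.config.to_sidecar().items():
                f.attrs[k] = v
            gt = record.ground_truth
            if gt is not None:
                g = f.create_group("ground_truth")
                g.attrs["ratio"] = gt.ratio
                g.attrs["hr_pitch"] = gt.hr_pitch
                g.attrs["x_offset"] = gt.x_offset
                if gt.label is not None:
                    g.attrs["label"] = gt.label
                g.create_dataset("envelope", data=gt.envelope)
                g.create_dataset("envelope_x", data=gt.envelope_x)
                if gt.hr_image is not None:
                    g.create_dataset("hr_image", data=gt.hr_image)
    else:
        record.samples.astype("<f8").tofile(path)
        sidecar = dict(record.config.to_sidecar())
        sidecar["dtype"] = "<f8"
        if record.ground_truth is not None:
            sidecar["true_ratio"] = record.ground_truth.ratio
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))


def read_record(path: str | Path) -> RawRecord:
    """Read a record written by :func:`write_record`; units are validated."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            samples = np.asarray(f["samples"], dtype=float)
            config = AcquisitionConfig.from_sidecar(dict(f.attrs))
            gt = None
            if "ground_truth" in f:
                g = f["ground_truth"]
                gt = GroundTruth(
                    ratio=float(g.attrs["ratio"]),
                    envelope_x=np.asarray(g["envelope_x"]),
                    envelope=np.asarray(g["envelope"]),
                    hr_image=np.asarray(g["hr_image"]) if "hr_image" in g else None,
                    hr_pitch=float(g.attrs.get("hr_pitch", 0.0)),
                    x_offset=float(g.attrs.get("x_offset", 0.0)),
                    label=(g.attrs["label"] if "label" in g.attrs else None),
                )
        return RawRecord(samples=samples, config=config, ground_truth=gt)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise RecordFormatError(f"missing metadata sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    config = AcquisitionConfig.from_sidecar(sidecar)
    samples = np.fromfile(path, dtype=sidecar.get("dtype", "<f8")).astype(float)
    gt = None
    if "true_ratio" in sidecar:
        gt = GroundTruth(ratio=float(sidecar["true_ratio"]),
                         envelope_x=np.empty(0), envelope=np.empty(0),
                         hr_image=None)
    return RawRecord(samples=samples, config=config, ground_truth=gt)


def write_image(image: HRImage, path: str | Path) -> dict:
    """Write a 16-bit TIFF with pitch + intensity-scaling metadata.

    Returns the scaling record {'offset', 'scale'} that maps stored counts
    back to physical values: value = offset + counts * scale.
    """
    if not np.all(np.isfinite(image.grid)):
        raise ValueError("image contains non-finite values")
    lo = float(image.grid.min())
    hi = float(image.grid.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    counts = np.round((image.grid - lo) / scale).astype(np.uint16)
    meta = {"pitch_x_um": image.pitch_x, "pitch_y_um": image.pitch_y,
            "origin_um": list(image.origin), "offset": lo, "scale": scale}
    tifffile.imwrite(str(path), counts, description=json.dumps(meta),
                     resolution=(1e4 / image.pitch_x, 1e4 / image.pitch_y))
    return {"offset": lo, "scale": scale}


def read_image(path: str | Path) -> HRImage:
    """Read a TIFF written by :func:`write_image` back to physical values."""
    with tifffile.TiffFile(str(path)) as tf:
        counts = tf.asarray().astype(float)
        desc = tf.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    grid = meta.get("offset", 0.0) + counts * meta.get("scale", 1.0)
    return HRImage(grid=grid, pitch_x=meta.get("pitch_x_um", 1.0),
                   pitch_y=meta.get("pitch_y_um", 1.0),
                   origin=tuple(meta.get("origin_um", (0.0, 0.0))))


@dataclass
class RunManifest:
    """Snapshot of everything needed to reproduce a run."""

    command: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    estimates: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.versions:
            import scipy
            import skimage
            from . import __version__
            self.versions = {"pixelsr": __version__, "numpy": np.__version__,
                             "scipy": scipy.__version__,
                             "scikit-image": skimage.__version__}
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def content_hash(self) -> str:
        """Hash of the deterministic fields (timestamp excluded)."""
        d = dataclasses.asdict(self)
        d.pop("timestamp")
        blob = json.dumps(d, sort_keys=True, default=_round6).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["content_hash"] = self.content_hash()
        Path(path).write_text(json.dumps(d, indent=2, default=_round6))


def _round6(obj):
    """Fix floating text output to 6 significant digits (diff-able manifests)."""
    if isinstance(obj, float):
        return float(f"{obj:.6g}")
    if isinstance(obj, np.floating):
        return float(f"{float(obj):.6g}")
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
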