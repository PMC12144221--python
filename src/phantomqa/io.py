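"""Readers and writers: PNG stacks, DICOM RGB series, manifests, configs.

The reference on-disk layout for a study is a directory tree
``<dose>/<reconstruction>/<repetition>/slice_<k>.png`` of per-slice 8-bit
RGB PNGs, accompanied by a JSON study manifest (design, per-scan entries,
provenance) and a CSV truth table. A DICOM RGB secondary-capture dialect
is also supported for both reading and writing.

Provenance carried by every manifest is deliberately stable: seed, tool
version and a config hash — so identical configurations reproduce
byte-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .design import AcquisitionCondition, Geometry, StudyDesign
from .errors import FormatError, ValidationError
from .quantify import HeatmapSeries

_SLICE_RE = re.compile(r"slice_(\d+)\.png$")


# ---------------------------------------------------------------------------
# PNG stack dialect
# ---------------------------------------------------------------------------

def write_png_stack(series: HeatmapSeries, directory: str | Path) -> list[Path]:
    """Write one heatmap series as slice_<k>.png files (k from 0)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(series.pixels.shape[0]):
        path = directory / f"slice_{k:03d}.png"
        Image.fromarray(series.pixels[k], mode="RGB").save(path)
        paths.append(path)
    return paths


def _read_png_stack(
    directory: Path,
    pixel_size_mm: float,
    slice_thickness_mm: float,
    acquisition: AcquisitionCondition | None,
) -> HeatmapSeries:
    files = sorted(directory.glob("slice_*.png"))
    if not files:
        raise FormatError(f"no slice_*.png files in {directory}")
    indexed = {}
    for f in files:
        m = _SLICE_RE.search(f.name)
        if m:
            indexed[int(m.group(1))] = f
    expected = range(min(indexed), max(indexed) + 1)
    gaps = [k for k in expected if k not in indexed]
    if gaps:
        raise FormatError(f"missing slice indices {gaps} in {directory}")
    slices = []
    shape = None
    for k in expected:
        with Image.open(indexed[k]) as img:
            if img.mode != "RGB":
                raise FormatError(f"{indexed[k]} is {img.mode}, expected RGB")
            arr = np.asarray(img, dtype=np.uint8)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise FormatError(
                f"mixed slice dimensions in {directory}: {shape} vs {arr.shape}"
            )
        slices.append(arr)
    return HeatmapSeries(
        pixels=np.stack(slices),
        pixel_size_mm=pixel_size_mm,
        slice_thickness_mm=slice_thickness_mm,
        acquisition=acquisition,
    )


# ---------------------------------------------------------------------------
# DICOM RGB secondary-capture dialect
# ---------------------------------------------------------------------------

def write_dicom_rgb(series: HeatmapSeries, directory: str | Path) -> list[Path]:
    """Write a series as DICOM RGB secondary-capture files, one per slice."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(series.pixels.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid(
            entropy_srcs=[f"phantomqa-{k}"]
        )
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "OT"
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = series.pixels.shape[1:3]
        ds.SamplesPerPixel = 3
        ds.PhotometricInterpretation = "RGB"
        ds.PlanarConfiguration = 0
        ds.BitsAllocated = 8
        ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        ds.PixelSpacing = [series.pixel_size_mm, series.pixel_size_mm]
        ds.SliceThickness = series.slice_thickness_mm
        ds.PixelData = series.pixels[k].tobytes()
        path = directory / f"slice_{k:03d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def _read_dicom_rgb(
    directory: Path, acquisition: AcquisitionCondition | None
) -> HeatmapSeries:
    import pydicom

    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise FormatError(f"no .dcm files in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    slices = []
    shape = None
    for ds in datasets:
        if getattr(ds, "PhotometricInterpretation", None) != "RGB":
            raise FormatError(
                f"non-RGB DICOM (PhotometricInterpretation="
                f"{getattr(ds, 'PhotometricInterpretation', None)!r})"
            )
        arr = ds.pixel_array.astype(np.uint8)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise FormatError("mixed slice dimensions in DICOM series")
        slices.append(arr)
    first = datasets[0]
    spacing = [float(v) for v in first.PixelSpacing]
    return HeatmapSeries(
        pixels=np.stack(slices),
        pixel_size_mm=spacing[0],
        slice_thickness_mm=float(getattr(first, "SliceThickness", 1.0)),
        acquisition=acquisition,
    )


def read_heatmap_series(
    path: str | Path,
    dialect: str = "png-stack",
    pixel_size_mm: float | None = None,
    slice_thickness_mm: float | None = None,
    acquisition: AcquisitionCondition | None = None,
) -> HeatmapSeries:
    """Load one scan's RGB stack.

    ``png-stack`` requires geometry (from the manifest or arguments);
    ``dicom-rgb`` reads PixelSpacing/SliceThickness from the files.
    """
    path = Path(path)
    if dialect == "png-stack":
        if pixel_size_mm is None or slice_thickness_mm is None:
            raise ValidationError(
                "png-stack dialect needs pixel_size_mm and slice_thickness_mm"
            )
        return _read_png_stack(path, pixel_size_mm, slice_thickness_mm, acquisition)
    if dialect == "dicom-rgb":
        return _read_dicom_rgb(path, acquisition)
    raise ValidationError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Study tree, manifest, config
# ---------------------------------------------------------------------------

def scan_directory(root: Path, cond: AcquisitionCondition) -> Path:
    return (
        Path(root)
        / f"{cond.dose_mGy:06.2f}mGy"
        / cond.reconstruction
        / f"rep{cond.repetition}"
    )


def config_hash(config: dict) -> str:
    """Stable SHA-256 over the canonical JSON form of a config dict."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def write_manifest(
    path: str | Path,
    design: StudyDesign,
    scans: list[dict],
    seed: int,
    cfg_hash: str | None = None,
) -> None:
    manifest = {
        "provenance": {
            "tool": "phantomqa",
            "version": __version__,
            "seed": seed,
            "config_hash": cfg_hash,
        },
        "design": design.to_dict(),
        "scans": scans,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_manifest(path: str | Path) -> dict:
    manifest = json.loads(Path(path).read_text())
    ids = [s["scan_id"] for s in manifest["scans"]]
    if len(ids) != len(set(ids)):
        raise FormatError("duplicate scan ids in manifest")
    root = Path(path).parent
    for s in manifest["scans"]:
        if "path" in s and not (root / s["path"]).exists():
            raise FormatError(f"manifest path missing on disk: {s['path']}")
    return manifest


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def jsonable(obj):
    """Recursively convert numpy scalars and NaN to JSON-safe values."""
    if isinstance(obj, dict):
        return {k: jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(jsonable(payload), indent=2, sort_keys=True))


def write_csv(path: str | Path, frame: pd.DataFrame) -> None:
    """Deterministic CSV writer (fixed float format, no index)."""
    frame.to_csv(path, index=False, float_format="%.10g")
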