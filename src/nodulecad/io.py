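"""Format I/O and pipeline orchestration.

Volumes travel as numbered PNG slice stacks or as a minimal single-frame
CT DICOM series; masks as 0/255 PNG stacks; reports as JSON; meshes as
STL/PLY.  :func:`run_pipeline` chains segmentation, detection, surface
reconstruction and path planning and writes a manifest recording the
config hash, seed, versions and per-stage wall-clock timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from . import __version__
from .features import candidate_regions, refine_region, compute_features
from .parenchyma import SegmentConfig, dice_coefficient, segment_slice
from .phantom import PhantomSpec, default_spec, generate_phantom
from .prediagnosis import (DEFAULT_THRESHOLDS, ThresholdSet, classify_all,
                           evaluate_detection)
from .preprocess import (DEFAULT_GAUSS_SIGMA, DEFAULT_WINDOW,
                         preprocess_slice, window_to_uint8)
from .pathplan import plan_insertion
from .volume3d import GrayVolume, extract_surface

__all__ = ["IOError_", "SeriesMetadata", "read_png", "write_png",
           "write_png_stack", "write_dicom_series", "read_dicom_series",
           "detect_slice", "run_pipeline"]

CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
_UID_ROOT = "1.2.826.0.1.3680043.10.1543."


class IOError_(ValueError):
    pass


@dataclass
class SeriesMetadata:
    paths: list[str]
    z_positions_mm: list[float]
    pixel_spacing_mm: tuple[float, float]   # (row, col)
    rows: int
    cols: int
    rescale_slope: float
    rescale_intercept: float


def read_png(path) -> np.ndarray:
    return np.asarray(iio.imread(path))


def write_png(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image).astype(np.uint8))


def write_png_stack(directory, volume: np.ndarray, prefix: str = "slice",
                    binary: bool = False) -> list[Path]:
    """Write a (z, y, x) volume or mask stack as numbered PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sl in enumerate(np.asarray(volume)):
        img = (sl.astype(bool) * 255).astype(np.uint8) if binary else sl
        p = directory / f"{prefix}_{i:04d}.png"
        write_png(p, img)
        paths.append(p)
    return paths


def write_dicom_series(directory, volume: GrayVolume,
                       window=DEFAULT_WINDOW, series_tag: str = "phantom"
                       ) -> list[Path]:
    """Write the 8-bit volume as a minimal CT DICOM series.

    Stored pixel values are the 8-bit grays; RescaleSlope/Intercept are set
    to the inverse of the given display window, so re-reading with the same
    window reproduces the volume bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lo, hi = window
    slope = (hi - lo) / 255.0
    series_uid = generate_uid(prefix=_UID_ROOT, entropy_srcs=[series_tag])
    study_uid = generate_uid(prefix=_UID_ROOT, entropy_srcs=[series_tag, "study"])
    paths = []
    sz, sy, sx = volume.spacing
    for i, sl in enumerate(volume.data):
        ds = Dataset()
        ds.SOPClassUID = CT_SOP_CLASS
        ds.SOPInstanceUID = generate_uid(prefix=_UID_ROOT,
                                         entropy_srcs=[series_tag, str(i)])
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "PHANTOM"
        ds.PatientID = series_tag
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(volume.origin[0] + i * sz)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceThickness = sz
        ds.PixelSpacing = [sy, sx]
        ds.Rows, ds.Columns = sl.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = float(lo)
        ds.PixelData = sl.astype(np.uint16).tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CT_SOP_CLASS
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        p = directory / f"ct_{i:04d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        paths.append(p)
    return paths


def read_dicom_series(directory, window=DEFAULT_WINDOW
                      ) -> tuple[GrayVolume, SeriesMetadata]:
    """Read a single-frame CT series: sort by z, rescale to HU, window to 8-bit."""
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if len(files) < 2:
        raise IOError_(f"need >= 2 DICOM slices in {directory}")
    datasets = []
    for f in files:
        try:
            datasets.append((f, pydicom.dcmread(f)))
        except Exception as e:  # pragma: no cover - corrupt input
            raise IOError_(f"unreadable DICOM file {f}: {e}") from e
    ref = datasets[0][1]
    geom = (int(ref.Rows), int(ref.Columns),
            tuple(float(v) for v in ref.PixelSpacing))
    bad = [str(f) for f, ds in datasets
           if (int(ds.Rows), int(ds.Columns),
               tuple(float(v) for v in ds.PixelSpacing)) != geom]
    if bad:
        raise IOError_("mixed slice geometry in series: " + ", ".join(bad))
    zs = [float(ds.ImagePositionPatient[2]) for _, ds in datasets]
    order = np.argsort(zs)
    zs = [zs[i] for i in order]
    datasets = [datasets[i] for i in order]
    dz = np.diff(zs)
    if np.any(dz <= 0):
        raise IOError_("duplicate or non-monotone slice positions")
    slices = []
    for _, ds in datasets:
        hu = ds.pixel_array.astype(float) * float(ds.RescaleSlope) \
            + float(ds.RescaleIntercept)
        slices.append(window_to_uint8(hu, window=window))
    sy, sx = geom[2]
    vol = GrayVolume(data=np.stack(slices), spacing=(float(dz[0]), sy, sx),
                     origin=(zs[0], 0.0, 0.0))
    meta = SeriesMetadata(
        paths=[str(f) for f, _ in datasets], z_positions_mm=zs,
        pixel_spacing_mm=(sy, sx), rows=geom[0], cols=geom[1],
        rescale_slope=float(ref.RescaleSlope),
        rescale_intercept=float(ref.RescaleIntercept))
    return vol, meta


# ---------------------------------------------------------------------------
# detection on one slice, and the full pipeline

def detect_slice(slice_gray: np.ndarray, *, seg_config: SegmentConfig | None = None,
                 thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
                 tau: float = 0.5, gauss_sigma: float = DEFAULT_GAUSS_SIGMA,
                 slice_index: int | None = None):
    """Preprocess, segment and classify one axial slice.

    Returns (detections, segmentation_result, features).  Raises the
    segmentation stage's error if no lung is found.
    """
    pre = preprocess_slice(slice_gray, gauss_sigma=gauss_sigma)
    seg = segment_slice(pre, seg_config)
    regions = candidate_regions(seg.masked_image, slice_index=slice_index)
    regions = [refine_region(r, seg.masked_image, tau=tau) for r in regions]
    regions = [r for r in regions if r.area > 0]
    feats = [compute_features(r, seg.masked_image) for r in regions]
    detections = classify_all(feats, thresholds)
    return detections, seg, feats


def _config_volume(config: dict, seed: int):
    inp = config.get("input")
    if not isinstance(inp, dict) or not ({"phantom", "dicom_dir"} & set(inp)):
        raise IOError_("config must contain input.phantom or input.dicom_dir")
    if "phantom" in inp:
        pconf = inp["phantom"] or {}
        if isinstance(pconf, PhantomSpec):
            spec = pconf
        else:
            spec = default_spec(seed=pconf.get("seed", seed),
                                noise_sigma=pconf.get("noise_sigma", 3.0))
        vol_data, truth = generate_phantom(spec)
        vol = GrayVolume(vol_data, spec.spacing_mm)
        return vol, truth, spec
    window = tuple(config.get("window", DEFAULT_WINDOW))
    vol, _ = read_dicom_series(inp["dicom_dir"], window=window)
    return vol, None, None


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """segment -> detect -> reconstruct -> plan, writing all artifacts.

    Returns the manifest dict (also written to ``manifest.json``).
    Partial outputs are kept on stage failure; the failing stage's name is
    prefixed to the raised error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": seed,
        "versions": {"nodulecad": __version__, "numpy": np.__version__},
        "timings_s": timings,
    }

    t0 = time.perf_counter()
    vol, truth, spec = _config_volume(config, seed)
    timings["load"] = time.perf_counter() - t0

    slices = config.get("slices", "mid")
    if slices == "mid":
        slice_ids = [vol.shape[0] // 2]
    else:
        slice_ids = [int(s) for s in slices]

    t0 = time.perf_counter()
    seg_results = {}
    seg_report = {}
    for si in slice_ids:
        try:
            dets, seg, feats = detect_slice(vol.data[si], slice_index=si)
        except Exception as e:
            raise type(e)(f"segment/detect slice {si}: {e}") from e
        seg_results[si] = (dets, seg, feats)
        entry = {
            "threshold": seg.threshold,
            "component_areas": seg.components.sorted_areas.tolist()
            if seg.components else [],
        }
        if truth is not None:
            entry["dice_vs_truth"] = dice_coefficient(
                seg.mask, truth.parenchyma[si])
        seg_report[si] = entry
        write_png(out / f"parenchyma_mask_{si:04d}.png",
                  seg.mask.astype(np.uint8) * 255)
        write_png(out / f"parenchyma_gray_{si:04d}.png", seg.masked_image)
    (out / "segmentation.json").write_text(json.dumps(seg_report, indent=2))
    timings["segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    detections_json = []
    all_dets = []
    for si, (dets, seg, feats) in seg_results.items():
        for d in dets:
            r, c = d.centroid
            d.centroid_mm = (float(si * vol.spacing[0] + vol.origin[0]),
                             float(r * vol.spacing[1]),
                             float(c * vol.spacing[2]))
            all_dets.append((si, d))
            detections_json.append({
                "slice": si,
                "centroid_rc": [float(r), float(c)],
                "centroid_mm_zyx": list(d.centroid_mm),
                "label": "suspected-nodule" if d.suspected else "rejected",
                "rejection_reason": d.rejection_reason,
                "large": d.large,
                "features": {k: float(getattr(d.features, k)) for k in
                             ("s_r", "p_r", "c_r", "mbr", "mbm",
                              "gm", "gv", "ge")},
            })
    report = {"detections": detections_json}
    if truth is not None:
        truth_cent = [c for si in slice_ids
                      for c in _truth_centroids_on_slice(truth, si)]
        preds = [d for si, d in all_dets if d.suspected]
        if truth_cent or preds:
            m = evaluate_detection([d.centroid for d in preds], truth_cent)
            report["metrics"] = {
                "TP": m.tp, "FP": m.fp, "FN": m.fn, "TN": m.tn,
                "F_se": m.f_se, "F_sp": m.f_sp, "F_a": m.f_a,
            }
    (out / "detection.json").write_text(json.dumps(report, indent=2))
    timings["detect"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    iso = float(config.get("iso", 90.0))
    mesh = extract_surface(vol, iso=iso,
                           smooth_iters=int(config.get("smooth_iters", 10)))
    if not mesh.is_empty:
        tm = mesh.to_trimesh()
        tm.export(out / "surface.stl")
        tm.export(out / "surface.ply")
    timings["reconstruct"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    plan_entry = None
    suspected = [(si, d) for si, d in all_dets if d.suspected]
    if suspected and truth is not None:
        si, d = max(suspected, key=lambda x: x[1].features.s_r)
        obstacles = {"bone": truth.bone, "vessel": truth.vessels}
        try:
            path = plan_insertion(vol, d.centroid_mm, truth.body,
                                  k=int(config.get("k", 4)),
                                  obstacle_masks=obstacles)
            plan_entry = {
                "nodule_centroid_mm_zyx": list(d.centroid_mm),
                "entry_mm_zyx": list(path.entry_mm),
                "length_mm": path.length_mm,
                "gray_sum": path.gray_sum,
                "feasible": path.feasible,
                "slice_index": path.slice_index,
            }
        except Exception as e:
            plan_entry = {"error": f"plan: {e}"}
    (out / "plan.json").write_text(json.dumps(plan_entry, indent=2))
    timings["plan"] = time.perf_counter() - t0

    n_img = max(len(slice_ids), 1)
    manifest["F_ce_seconds_per_image"] = (
        timings["segment"] + timings["detect"]) / n_img
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _truth_centroids_on_slice(truth, si: int) -> list[tuple[float, float]]:
    """In-plane centroids of truth nodules visible on slice ``si``."""
    out = []
    for m in truth.nodules:
        sl = m[si]
        if sl.any():
            rows, cols = np.nonzero(sl)
            out.append((float(rows.mean()), float(cols.mean())))
    return out
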