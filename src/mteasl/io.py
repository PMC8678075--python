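"""NIfTI/JSON dataset bundles, masked Gaussian smoothing and provenance.

Volumes are NIfTI-1, 32-bit float; frame timing lives in a JSON sidecar
(``ti_ms``/``te_ms`` or ``row``/``te_ms`` lists, milliseconds, plus the
frame ordering), so files are never interpreted by position alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import __version__
from .inference import SENTINEL
from .types import DecodedSeries, EncodedSeries

__all__ = ["DatasetBundle", "read_bundle", "write_bundle", "smooth_map",
           "write_provenance"]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass
class DatasetBundle:
    """Paths of one dataset: 4-D data, JSON sidecar, optional M0/masks."""

    data: Path
    sidecar: Path
    m0: Optional[Path] = None
    mask: Optional[Path] = None


def write_bundle(series: Union[DecodedSeries, EncodedSeries], path,
                 affine: Optional[np.ndarray] = None, extra: Optional[dict] = None):
    """Write a series as ``<path>.nii.gz`` + ``<path>.json``.

    The sidecar records per-frame timing (ms), the frame ordering convention
    and any ``extra`` metadata (e.g. ground-truth provenance).
    """
    path = Path(path)
    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(series.volumes.astype(np.float32), affine)
    nii_path = path.with_suffix(".nii.gz")
    nib.save(img, str(nii_path))
    meta: dict = {"frame_order": "te_fastest", "units": "ms"}
    if isinstance(series, DecodedSeries):
        meta["kind"] = "decoded"
        meta["ti_ms"] = [float(v) for v in series.frame_meta["ti"]]
        meta["te_ms"] = [float(v) for v in series.frame_meta["te"]]
    else:
        meta["kind"] = "encoded"
        meta["row"] = [int(v) for v in series.frame_meta["row"]]
        meta["te_ms"] = [float(v) for v in series.frame_meta["te"]]
    if extra:
        meta.update(extra)
    side_path = path.with_suffix(".json")
    side_path.write_text(json.dumps(meta, indent=2))
    return DatasetBundle(data=nii_path, sidecar=side_path)


def read_bundle(paths: Union[DatasetBundle, str, Path]):
    """Load a bundle back into a series; validation errors are aggregated.

    Returns ``(series, metadata_dict)``.
    """
    if isinstance(paths, (str, Path)):
        p = Path(paths)
        paths = DatasetBundle(data=p.with_suffix(".nii.gz"),
                              sidecar=p.with_suffix(".json"))
    problems = []
    if not Path(paths.data).exists():
        problems.append(f"data file missing: {paths.data}")
    if not Path(paths.sidecar).exists():
        problems.append(f"sidecar missing: {paths.sidecar}")
    if problems:
        raise FileNotFoundError("; ".join(problems))

    meta = json.loads(Path(paths.sidecar).read_text())
    vols = np.asarray(nib.load(str(paths.data)).get_fdata(), dtype=float)
    if vols.ndim == 3:
        vols = vols[..., None]
    n_frames = vols.shape[3]
    kind = meta.get("kind", "decoded")

    if "te_ms" not in meta:
        problems.append("sidecar missing key 'te_ms'")
    if kind == "decoded" and "ti_ms" not in meta:
        problems.append("sidecar missing key 'ti_ms'")
    if kind == "encoded" and "row" not in meta:
        problems.append("sidecar missing key 'row'")
    if problems:
        raise KeyError("; ".join(problems))

    te = meta["te_ms"]
    if kind == "decoded":
        ti = meta["ti_ms"]
        if len(ti) == n_frames and len(te) == n_frames:
            ti_col, te_col = np.asarray(ti, float), np.asarray(te, float)
        elif len(ti) * len(te) == n_frames:
            # compact sidecar: unique TI and TE lists, TE fastest-varying
            ti_col = np.repeat(np.asarray(ti, float), len(te))
            te_col = np.tile(np.asarray(te, float), len(ti))
        else:
            raise ValueError(
                f"sidecar lists {len(ti)} TI / {len(te)} TE entries but the "
                f"4-D file has {n_frames} frames "
                f"({len(ti)} x {len(te)} = {len(ti) * len(te)})"
            )
        series = DecodedSeries(
            volumes=vols,
            frame_meta=pd.DataFrame({"ti": ti_col, "te": te_col}),
        )
    else:
        rows = meta["row"]
        if len(rows) != n_frames or len(te) != n_frames:
            raise ValueError(
                f"sidecar lists {len(rows)} rows / {len(te)} TE entries but "
                f"the 4-D file has {n_frames} frames"
            )
        series = EncodedSeries(
            volumes=vols,
            frame_meta=pd.DataFrame({"row": np.asarray(rows, int),
                                     "te": np.asarray(te, float)}),
        )
    return series, meta


def smooth_map(param_map: np.ndarray, fwhm_factor: float = 2.0,
               voxel_size=(1.0, 1.0, 1.0),
               mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Masked Gaussian smoothing with per-axis FWHM = factor x voxel size.

    Sentinel/out-of-mask voxels are excluded by normalised masked
    convolution (smooth(map * w) / smooth(w)); they stay sentinel in the
    output.  Mean-preserving on constant fields.
    """
    if fwhm_factor <= 0:
        raise ValueError("fwhm_factor must be positive")
    m = np.asarray(param_map, dtype=float)
    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (m.ndim,))
    sigma_vox = fwhm_factor / FWHM_TO_SIGMA  # kernel scales with voxel size,
    # so in voxel units sigma is the same on every axis
    sigmas = np.full(m.ndim, sigma_vox)
    valid = np.isfinite(m) & (m != SENTINEL)
    if mask is not None:
        valid &= np.asarray(mask).astype(bool)
    w = valid.astype(float)
    num = gaussian_filter(np.where(valid, m, 0.0), sigmas)
    den = gaussian_filter(w, sigmas)
    out = np.full(m.shape, SENTINEL)
    ok = valid & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return out


def write_provenance(out_dir, config: dict, seed: Optional[int] = None):
    """Drop a machine-readable provenance record alongside outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "package": "mteasl",
        "version": __version__,
        "seed": seed,
        "config": config,
    }
    p = out_dir / "provenance.json"
    p.write_text(json.dumps(record, indent=2, default=str))
    return p
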