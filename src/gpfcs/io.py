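"""File formats: CSV for traces/curves/tables, multi-page TIFF for image
stacks, YAML sidecars for metadata.

Every writer produces a ``<file>.yaml`` sidecar next to the data file;
readers look for it and fall back to sensible defaults when absent.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import ChannelStack, CorrelationCurve, DiffusionFit, GPImage, PhotonTrace

__all__ = [
    "save_trace",
    "load_trace",
    "save_curve",
    "load_curve",
    "save_stack",
    "load_stack",
    "save_frames",
    "load_frames",
    "save_gp_image",
    "load_mask",
    "parse_roi",
    "fit_record",
    "fits_to_csv",
]

PathLike = Union[str, Path]


def _pyify(obj):
    """Make metadata YAML-safe (plain Python scalars/lists)."""
    if isinstance(obj, dict):
        return {str(k): _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_pyify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _sidecar(path: PathLike) -> Path:
    return Path(str(path) + ".yaml")


def _write_sidecar(path: PathLike, payload: dict) -> None:
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(_pyify(payload), fh, sort_keys=True)


def _read_sidecar(path: PathLike) -> dict:
    p = _sidecar(path)
    if not p.exists():
        return {}
    with open(p) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"malformed YAML sidecar {p}: expected a mapping")
    return data


# -- photon traces ----------------------------------------------------------


def save_trace(trace: PhotonTrace, path: PathLike) -> None:
    """Two-column CSV (blue, red counts per bin) plus YAML sidecar."""
    df = pd.DataFrame(
        {"counts_blue": trace.counts_blue, "counts_red": trace.counts_red}
    )
    df.to_csv(path, index=False)
    _write_sidecar(
        path,
        {"bin_width_s": trace.bin_width, "n_bins": trace.n_bins, "meta": trace.meta},
    )


def load_trace(path: PathLike, bin_width: Optional[float] = None) -> PhotonTrace:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"malformed trace CSV {path}: {exc}") from exc
    for col in ("counts_blue", "counts_red"):
        if col not in df.columns:
            raise ValueError(f"malformed trace CSV {path}: missing column {col!r}")
    side = _read_sidecar(path)
    bw = bin_width if bin_width is not None else side.get("bin_width_s")
    if bw is None:
        raise ValueError(f"no bin width: pass bin_width or provide {_sidecar(path)}")
    return PhotonTrace(
        df["counts_blue"].to_numpy(),
        df["counts_red"].to_numpy(),
        float(bw),
        meta=side.get("meta", {}),
    )


# -- correlation curves -----------------------------------------------------


def save_curve(curve: CorrelationCurve, path: PathLike) -> None:
    pd.DataFrame({"lag_s": curve.lags, "g": curve.g}).to_csv(path, index=False)
    _write_sidecar(
        path,
        {
            "mean_count_rate_blue_khz": curve.mean_count_rate_blue,
            "mean_count_rate_red_khz": curve.mean_count_rate_red,
            "acquisition_time_s": curve.acquisition_time,
            "channel": curve.channel,
            "meta": curve.meta,
        },
    )


def load_curve(path: PathLike) -> CorrelationCurve:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"malformed curve CSV {path}: {exc}") from exc
    for col in ("lag_s", "g"):
        if col not in df.columns:
            raise ValueError(f"malformed curve CSV {path}: missing column {col!r}")
    side = _read_sidecar(path)
    return CorrelationCurve(
        df["lag_s"].to_numpy(),
        df["g"].to_numpy(),
        mean_count_rate_blue=float(side.get("mean_count_rate_blue_khz", np.nan)),
        mean_count_rate_red=float(side.get("mean_count_rate_red_khz", np.nan)),
        acquisition_time=float(side.get("acquisition_time_s", np.nan)),
        channel=side.get("channel", "sum"),
        meta=side.get("meta", {}),
    )


# -- image stacks -----------------------------------------------------------


def _stack_sidecar(stack: ChannelStack) -> dict:
    return {
        "kind": stack.kind,
        "channel_centers_nm": stack.channel_centers,
        "band_edges_nm": stack.band_edges,
        "pixel_size_nm": stack.pixel_size,
        "frame_index": stack.frame_index,
        "meta": stack.meta,
    }


def save_stack(stack: ChannelStack, path: PathLike) -> None:
    """Multi-page TIFF, one page per channel, with a YAML sidecar."""
    tifffile.imwrite(path, np.moveaxis(stack.pixels, 2, 0).astype(np.float32))
    _write_sidecar(path, _stack_sidecar(stack))


def _stack_from(pages: np.ndarray, side: dict) -> ChannelStack:
    kind = side.get("kind", "spectral")
    centers = side.get("channel_centers_nm")
    edges = side.get("band_edges_nm")
    return ChannelStack(
        np.moveaxis(pages, 0, 2),
        kind=kind,
        channel_centers=np.asarray(centers, float) if centers is not None else None,
        band_edges=[tuple(e) for e in edges] if edges else None,
        pixel_size=float(side.get("pixel_size_nm") or np.nan),
        frame_index=side.get("frame_index"),
        meta=side.get("meta", {}),
    )


def load_stack(path: PathLike) -> ChannelStack:
    try:
        pages = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"malformed TIFF {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    return _stack_from(pages, _read_sidecar(path))


def save_frames(frames: Sequence[ChannelStack], path: PathLike) -> None:
    """Time-lapse: pages ordered frame-major (frame0/ch0, frame0/ch1, ...)."""
    arr = np.stack([np.moveaxis(f.pixels, 2, 0) for f in frames])
    tifffile.imwrite(path, arr.astype(np.float32))
    side = _stack_sidecar(frames[0])
    side["n_frames"] = len(frames)
    side["frame_meta"] = [f.meta for f in frames]
    _write_sidecar(path, side)


def load_frames(path: PathLike) -> list[ChannelStack]:
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"malformed TIFF {path}: {exc}") from exc
    side = _read_sidecar(path)
    if arr.ndim == 3:  # single frame
        arr = arr[None]
    frame_meta = side.get("frame_meta") or [side.get("meta", {})] * arr.shape[0]
    frames = []
    for k in range(arr.shape[0]):
        s = dict(side)
        s["meta"] = frame_meta[k] if k < len(frame_meta) else {}
        s["frame_index"] = k
        frames.append(_stack_from(arr[k], s))
    return frames


# -- GP maps and masks ------------------------------------------------------


def save_gp_image(gp_img: GPImage, path: PathLike) -> None:
    """GP map as 32-bit float TIFF (NaN outside mask) + 8-bit mask TIFF."""
    path = Path(path)
    tifffile.imwrite(path, gp_img.gp.astype(np.float32))
    mask_path = path.with_name(path.stem + "_mask" + path.suffix)
    tifffile.imwrite(mask_path, gp_img.mask.astype(np.uint8) * 255)
    _write_sidecar(
        path,
        {
            "threshold_used": gp_img.threshold_used,
            "mean_gp": gp_img.mean_gp,
            "n_valid": gp_img.n_valid,
            "meta": gp_img.meta,
        },
    )


def load_mask(path: PathLike) -> np.ndarray:
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"malformed mask TIFF {path}: {exc}") from exc
    return np.asarray(arr) > 0


def parse_roi(spec: str, shape: tuple[int, int]) -> np.ndarray:
    """Rectangle ROI from an ``x0,y0,x1,y1`` string (end-exclusive)."""
    try:
        x0, y0, x1, y1 = (int(v) for v in spec.split(","))
    except ValueError as exc:
        raise ValueError(f"malformed ROI {spec!r}: expected x0,y0,x1,y1") from exc
    mask = np.zeros(shape, bool)
    mask[y0:y1, x0:x1] = True
    if not mask.any():
        raise ValueError(f"ROI {spec!r} selects no pixels in image {shape}")
    return mask


# -- fit tables -------------------------------------------------------------


def fit_record(name: str, channel: str, fit: DiffusionFit) -> dict:
    """One fit-table row (file, channel, N, tau_D, alpha, CPM, GP, chi2)."""
    return {
        "file": name,
        "channel": channel,
        "n": fit.n,
        "tau_d_ms": fit.tau_d,
        "alpha": fit.alpha,
        "cpm_khz": fit.cpm if fit.cpm is not None else np.nan,
        "gp": fit.gp if fit.gp is not None else np.nan,
        "chi2": fit.chi2,
        "converged": fit.converged,
    }


def fits_to_csv(records: Sequence[dict], path: PathLike) -> pd.DataFrame:
    df = pd.DataFrame(list(records))
    df.to_csv(path, index=False)
    return df
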