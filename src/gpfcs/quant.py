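"""Time-lapse ROI quantification: photobleaching curves, internalization
ratios and GP time-courses.

ROI masks are supplied by the caller (drawn manually in practice); no
automatic segmentation is attempted.  Intensities are the per-pixel sums
over channels unless stated otherwise.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .containers import ChannelStack, RoiTimeSeries
from .gpimage import DEFAULT_THRESHOLD_FRACTION

__all__ = ["bleach_curve", "internalization_series", "gp_timecourse"]


def _frame_interval(frames: Sequence[ChannelStack]) -> float:
    return float(frames[0].meta.get("frame_interval_s", float("nan")))


def _roi_mean(frame: ChannelStack, mask: np.ndarray) -> float:
    return float(frame.total_intensity[mask].mean())


def bleach_curve(
    frames: Sequence[ChannelStack],
    roi_mask: np.ndarray,
    background_mask: np.ndarray,
    label: str = "membrane",
) -> RoiTimeSeries:
    """Background-subtracted, first-frame-normalized intensity course.

    Per frame, the mean background intensity (a region devoid of signal)
    is subtracted from the mean ROI intensity; the series is then divided
    by its first value, so frame 1 is 1.0 by construction.  A permanently
    bound dye under bleaching decays; an exchangeable dye, replenished
    from solution, stays at 1 within noise.
    """
    if len(frames) < 2:
        raise ValueError("at least 2 frames required")
    roi_mask = np.asarray(roi_mask, bool)
    background_mask = np.asarray(background_mask, bool)
    if not roi_mask.any() or not background_mask.any():
        raise ValueError("ROI and background masks must be nonempty")
    if np.any(roi_mask & background_mask):
        raise ValueError("ROI and background masks must be disjoint")
    vals = np.array(
        [_roi_mean(f, roi_mask) - _roi_mean(f, background_mask) for f in frames]
    )
    if vals[0] <= 0:
        raise ValueError("no signal above background in the first frame")
    return RoiTimeSeries(label, vals / vals[0], frame_interval=_frame_interval(frames))


def internalization_series(
    frames: Sequence[ChannelStack],
    masks: Mapping[str, np.ndarray],
) -> dict[str, RoiTimeSeries]:
    """Compartment intensities as percent of the plasma-membrane signal.

    ``masks`` must provide ``membrane``, ``cytosol`` and ``nucleus``
    regions; each compartment's per-frame mean intensity is divided by
    the membrane mean of the same frame and scaled to percent, so the
    membrane series is 100 everywhere.
    """
    for key in ("membrane", "cytosol", "nucleus"):
        if key not in masks or not np.asarray(masks[key], bool).any():
            raise ValueError(f"mask {key!r} missing or empty")
    dt = _frame_interval(frames)
    mem = np.array([_roi_mean(f, np.asarray(masks["membrane"], bool)) for f in frames])
    if np.any(mem == 0):
        raise ValueError("membrane mean intensity is zero in some frame")
    out = {}
    for key in ("membrane", "cytosol", "nucleus"):
        vals = np.array([_roi_mean(f, np.asarray(masks[key], bool)) for f in frames])
        out[key] = RoiTimeSeries(key, vals / mem * 100.0, frame_interval=dt)
    return out


def gp_timecourse(
    frames: Sequence[ChannelStack],
    mask_per_frame: Union[np.ndarray, Sequence[Optional[np.ndarray]]],
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> list[tuple[float, float]]:
    """Per-frame (mean GP, SD GP) of a two-band time-lapse within an ROI.

    The intensity threshold is fractional, taken relative to the maximal
    channel sum *inside the frame's ROI*.  A frame whose ROI is empty
    after thresholding (e.g. the vesicle left the focal plane) yields
    (nan, nan) and the series continues.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    if isinstance(mask_per_frame, np.ndarray) and mask_per_frame.ndim == 2:
        masks: Sequence[Optional[np.ndarray]] = [mask_per_frame] * len(frames)
    else:
        masks = mask_per_frame
        if len(masks) != len(frames):
            raise ValueError("need one mask per frame")
    series: list[tuple[float, float]] = []
    for frame, mask in zip(frames, masks):
        if frame.kind != "banded":
            raise ValueError("gp_timecourse requires 2-band frames")
        if mask is None or not np.asarray(mask, bool).any():
            series.append((float("nan"), float("nan")))
            continue
        roi = np.asarray(mask, bool)
        ib = frame.pixels[:, :, 0]
        ir = frame.pixels[:, :, 1]
        total = ib + ir
        thr = threshold_fraction * float(total[roi].max())
        valid = roi & (total >= thr) & (total > 0)
        if not valid.any():
            series.append((float("nan"), float("nan")))
            continue
        gp = (ib[valid] - ir[valid]) / total[valid]
        series.append((float(gp.mean()), float(gp.std())))
    return series
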