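"""Generalized-polarization (GP) imaging.

GP quantifies lipid packing per pixel from two emission readings, a blue
(ordered-phase) intensity Ib and a red (disordered-phase) intensity Ir:

    GP = (Ib - Ir) / (Ib + Ir),   GP in [-1, 1].

Two input paths are supported, matching the two acquisition modes of
polarity-sensitive dye experiments: full spectral stacks (Ib/Ir read from
the detector channels nearest the analysis wavelengths, absolute
intensity threshold, default 40 counts) and two-band ordered/disordered
images (fractional threshold on the channel sum, default 0.25 of the
image maximum).  Spectra are summarized as per-channel means only — no
line-shape model is fitted.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .containers import ChannelStack, GPImage

__all__ = [
    "gp_from_spectral",
    "gp_from_two_channel",
    "delta_gp",
    "mean_spectrum",
    "experiment_mean_gp",
    "DEFAULT_THRESHOLD_COUNTS",
    "DEFAULT_THRESHOLD_FRACTION",
]

DEFAULT_THRESHOLD_COUNTS = 40.0
DEFAULT_THRESHOLD_FRACTION = 0.25  # two-channel threshold, 20-30% of max


def _gp_of(ib: np.ndarray, ir: np.ndarray, mask: np.ndarray) -> np.ndarray:
    gp = np.full(ib.shape, np.nan)
    denom = ib + ir
    np.divide(ib - ir, denom, out=gp, where=mask)
    return gp


def gp_from_spectral(
    stack: ChannelStack,
    lambda_b: float = 575.0,
    lambda_r: float = 640.0,
    threshold: float = DEFAULT_THRESHOLD_COUNTS,
) -> GPImage:
    """Per-pixel GP from a spectral stack.

    Ib and Ir come from the channels whose centers are nearest
    ``lambda_b`` and ``lambda_r`` (no interpolation).  Pixels whose total
    intensity (summed over all channels) falls below ``threshold``, or
    with Ib + Ir = 0, are masked out.  A threshold that masks everything
    yields a valid result with zero valid pixels, not an exception.
    """
    if stack.kind != "spectral":
        raise ValueError("gp_from_spectral requires a spectral stack")
    if lambda_b >= lambda_r:
        raise ValueError("lambda_b must be shorter than lambda_r")
    centers = stack.channel_centers
    step = float(np.median(np.diff(centers)))
    for lam in (lambda_b, lambda_r):
        if not (centers[0] - step / 2 <= lam <= centers[-1] + step / 2):
            raise ValueError(
                f"analysis wavelength {lam} nm outside channel range "
                f"[{centers[0]:.1f}, {centers[-1]:.1f}] nm"
            )
    ib = stack.pixels[:, :, int(np.argmin(np.abs(centers - lambda_b)))]
    ir = stack.pixels[:, :, int(np.argmin(np.abs(centers - lambda_r)))]
    mask = (stack.total_intensity >= threshold) & (ib + ir > 0)
    return GPImage(
        _gp_of(ib, ir, mask), mask, threshold_used=threshold,
        meta={"lambda_b_nm": lambda_b, "lambda_r_nm": lambda_r, **stack.meta},
    )


def gp_from_two_channel(
    img: ChannelStack, threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
) -> GPImage:
    """Per-pixel GP from a two-band (ordered, disordered) image.

    The mask keeps pixels whose channel sum reaches ``threshold_fraction``
    of the maximal channel sum in the image; Ib is the ordered band and
    Ir the disordered band.
    """
    if img.kind != "banded":
        raise ValueError("gp_from_two_channel requires a 2-band image")
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    ib = img.pixels[:, :, 0]
    ir = img.pixels[:, :, 1]
    total = ib + ir
    thr = threshold_fraction * float(total.max())
    mask = (total >= thr) & (total > 0)
    return GPImage(
        _gp_of(ib, ir, mask), mask, threshold_used=thr,
        meta={"threshold_fraction": threshold_fraction, **img.meta},
    )


def delta_gp(gp_img: GPImage, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Mean-GP difference between two regions (e.g. Lo minus Ld sectors).

    Each region is intersected with the image's validity mask first;
    swapping the regions flips the sign exactly.
    """
    for name, region in (("mask_a", mask_a), ("mask_b", mask_b)):
        if not np.any(np.asarray(region, bool) & gp_img.mask):
            raise ValueError(f"{name} has no valid pixels")
    a = gp_img.gp[np.asarray(mask_a, bool) & gp_img.mask]
    b = gp_img.gp[np.asarray(mask_b, bool) & gp_img.mask]
    return float(a.mean() - b.mean())


def mean_spectrum(
    stack: ChannelStack, mask: np.ndarray
) -> tuple[np.ndarray, float]:
    """Average emission spectrum over a pixel mask.

    Returns the per-channel mean intensities and the center wavelength of
    the brightest channel (the discrete emission maximum).
    """
    if stack.kind != "spectral":
        raise ValueError("mean_spectrum requires a spectral stack")
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    spectrum = stack.pixels[mask].mean(axis=0)
    peak = float(stack.channel_centers[int(np.argmax(spectrum))])
    return spectrum, peak


def experiment_mean_gp(images: Sequence[GPImage]) -> float:
    """Two-level average: mean over per-image mean GPs.

    Mirrors the aggregation used when an experiment's GP is reported as
    the mean over several images (each image weighted equally regardless
    of its valid-pixel count).
    """
    means = [img.mean_gp for img in images if img.n_valid > 0]
    if not means:
        raise ValueError("no image with valid pixels")
    return float(np.mean(means))
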