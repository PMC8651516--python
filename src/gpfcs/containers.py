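"""Core in-memory containers shared by the pipeline stages.

Unit conventions (applied everywhere unless a field name says otherwise):
times in seconds, transit times ``tau_d`` in milliseconds, count rates in
kHz, lengths/wavelengths in nanometres, diffusion coefficients in um^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

__all__ = [
    "PhotonTrace",
    "CorrelationCurve",
    "DiffusionFit",
    "ChannelStack",
    "GPImage",
    "RoiTimeSeries",
    "SpotCalibration",
]


@dataclass
class PhotonTrace:
    """Binned photon counts in the blue and red detection channels.

    The two channels correspond to the ordered (shorter-wavelength) and
    disordered (longer-wavelength) emission bands of a polarity-sensitive
    dye.  ``meta`` carries provenance: ground-truth parameters when the
    trace was simulated, an acquisition label otherwise.
    """

    counts_blue: np.ndarray
    counts_red: np.ndarray
    bin_width: float  # seconds
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts_blue = np.asarray(self.counts_blue)
        self.counts_red = np.asarray(self.counts_red)
        if self.counts_blue.shape != self.counts_red.shape:
            raise ValueError("blue and red channels must have the same length")
        if self.counts_blue.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for name, c in (("blue", self.counts_blue), ("red", self.counts_red)):
            if np.any(c < 0):
                raise ValueError(f"negative counts in {name} channel")

    @property
    def n_bins(self) -> int:
        return self.counts_blue.size

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return self.n_bins * self.bin_width

    def channel(self, which: str) -> np.ndarray:
        """Return the count stream for ``blue``, ``red`` or their ``sum``."""
        if which == "blue":
            return self.counts_blue
        if which == "red":
            return self.counts_red
        if which == "sum":
            return self.counts_blue + self.counts_red
        raise ValueError(f"unknown channel {which!r}; expected blue|red|sum")

    def mean_rate_khz(self, which: str = "sum") -> float:
        """Mean count rate of a channel in kHz."""
        return float(self.channel(which).mean()) / self.bin_width / 1e3


@dataclass
class CorrelationCurve:
    """Normalized intensity autocorrelation G(tau).

    ``g`` uses the fluctuation normalization: an uncorrelated (shot-noise
    only) trace gives g ~ 0 at every lag, and for a diffusing species the
    zero-lag extrapolation tends to 1/N.
    """

    lags: np.ndarray  # seconds, strictly increasing, > 0
    g: np.ndarray
    mean_count_rate_blue: float = float("nan")  # kHz
    mean_count_rate_red: float = float("nan")  # kHz
    acquisition_time: float = float("nan")  # seconds
    channel: str = "sum"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.shape != self.g.shape:
            raise ValueError("lags and g must have the same length")
        if self.lags.size and (np.any(np.diff(self.lags) <= 0) or self.lags[0] <= 0):
            raise ValueError("lags must be strictly increasing and positive")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("g must be finite at all lags")

    @property
    def mean_count_rate(self) -> float:
        """Count rate (kHz) of the correlated channel."""
        if self.channel == "blue":
            return self.mean_count_rate_blue
        if self.channel == "red":
            return self.mean_count_rate_red
        return self.mean_count_rate_blue + self.mean_count_rate_red


@dataclass
class DiffusionFit:
    """Result of fitting the 2D anomalous-diffusion FCS model.

    Model: G(tau) = (1/N) * (1 + (tau/tau_d)^alpha)^-1 with occupancy N,
    transit time tau_d and anomaly exponent alpha (alpha = 1 for free
    Brownian diffusion).
    """

    n: float
    tau_d: float  # milliseconds
    alpha: float
    chi2: float
    converged: bool
    fitted_curve: Optional[np.ndarray] = None
    cpm: Optional[float] = None  # kHz
    gp: Optional[float] = None
    message: str = ""

    def model(self, lags_s: np.ndarray) -> np.ndarray:
        """Evaluate the fitted model at lag times given in seconds."""
        tau_ms = np.asarray(lags_s, dtype=float) * 1e3
        return diffusion_model(tau_ms, self.n, self.tau_d, self.alpha)


def diffusion_model(
    tau_ms: np.ndarray, n: float, tau_d_ms: float, alpha: float
) -> np.ndarray:
    """2D anomalous-diffusion autocorrelation, tau and tau_d in ms."""
    tau_ms = np.asarray(tau_ms, dtype=float)
    return 1.0 / (n * (1.0 + (tau_ms / tau_d_ms) ** alpha))


@dataclass
class ChannelStack:
    """Multi-channel image: a 32-channel spectral stack or a 2-band image.

    ``pixels`` has shape (rows, cols, channels).  For ``kind='spectral'``
    the channel centers are wavelengths in nm (strictly increasing); for
    ``kind='banded'`` there are exactly two channels, the ordered
    (shorter-wavelength) and disordered band, with optional band edges.
    """

    pixels: np.ndarray
    kind: str = "spectral"  # 'spectral' | 'banded'
    channel_centers: Optional[np.ndarray] = None  # nm, spectral only
    band_edges: Optional[Sequence[tuple]] = None  # nm, banded only
    pixel_size: float = float("nan")  # nm
    frame_index: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be rows x cols x channels")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be nonnegative")
        if self.kind == "spectral":
            if self.channel_centers is None:
                raise ValueError("spectral stack needs channel_centers")
            self.channel_centers = np.asarray(self.channel_centers, dtype=float)
            if self.channel_centers.size != self.pixels.shape[2]:
                raise ValueError("channel_centers length must match channel axis")
            if np.any(np.diff(self.channel_centers) <= 0):
                raise ValueError("channel centers must be strictly increasing")
        elif self.kind == "banded":
            if self.pixels.shape[2] != 2:
                raise ValueError("banded image must have exactly 2 channels")
        else:
            raise ValueError(f"unknown stack kind {self.kind!r}")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def total_intensity(self) -> np.ndarray:
        """Per-pixel intensity summed over channels."""
        return self.pixels.sum(axis=2)


@dataclass
class GPImage:
    """Per-pixel generalized polarization with a validity mask."""

    gp: np.ndarray  # NaN outside mask
    mask: np.ndarray  # bool, True where gp is defined
    threshold_used: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gp = np.asarray(self.gp, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.gp.shape != self.mask.shape:
            raise ValueError("gp and mask shapes differ")
        valid = self.gp[self.mask]
        if valid.size and (np.nanmax(valid) > 1 + 1e-12 or np.nanmin(valid) < -1 - 1e-12):
            raise ValueError("GP values outside [-1, 1]")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def mean_gp(self) -> float:
        """Unweighted mean GP over valid pixels; NaN when none are valid."""
        if self.n_valid == 0:
            return float("nan")
        return float(self.gp[self.mask].mean())

    @property
    def sd_gp(self) -> float:
        if self.n_valid == 0:
            return float("nan")
        return float(self.gp[self.mask].std())


@dataclass
class RoiTimeSeries:
    """Per-frame mean intensity of a region of interest."""

    label: str  # membrane|cytosol|nucleus|background|custom
    values: np.ndarray
    frame_interval: float = float("nan")  # seconds

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.frame_interval


@dataclass
class CalibrationEntry:
    power: str  # STED power label, e.g. "250 mW"
    tau_d_sted: float  # ms
    tau_d_conf: float  # ms
    omega0_apparent: float  # nm
    d: float  # um^2/s


@dataclass
class SpotCalibration:
    """STED-FCS resolution calibration: spot radius and D per STED power."""

    omega0_conf: float  # nm
    entries: list = field(default_factory=list)

    def to_records(self) -> list[dict[str, Any]]:
        return [
            {
                "power_mw": e.power,
                "tau_d_sted_ms": e.tau_d_sted,
                "tau_d_conf_ms": e.tau_d_conf,
                "omega0_nm": e.omega0_apparent,
                "d_um2_s": e.d,
            }
            for e in self.entries
        ]
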