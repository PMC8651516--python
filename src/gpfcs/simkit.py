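"""Photon-level synthetic data for membrane-dye experiments.

Three generators mirror the three raw-data kinds of a polarity-sensitive
dye study:

* :func:`simulate_trace` — FCS photon traces from dyes diffusing in a 2D
  membrane through a Gaussian observation spot, with Poisson photon noise,
  a GP-parameterized two-channel split, optional membrane exchange
  (unbinding/rebinding) and optional photobleaching.
* :func:`simulate_vesicle_stack` — 32-channel spectral images of a
  phase-separated vesicle equatorial cross-section, one Gaussian emission
  spectrum per phase sector.
* :func:`simulate_timelapse` — two-band (ordered/disordered) time-lapse
  image series of a cell-like scene for bleaching and internalization
  quantification, contrasting exchangeable and permanently bound dyes.

The membrane is modeled as a flat 2D plane (supported-bilayer geometry)
with periodic boundaries; the observation spot is a fixed Gaussian at the
box center.  Analytic expectations for count rate, occupancy and spectral
GP are provided as oracles for the downstream analysis modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from numba import njit
from scipy.optimize import brentq
from scipy.special import ndtr

from .containers import ChannelStack, PhotonTrace

__all__ = [
    "SimulationConfig",
    "VesiclePhase",
    "VesicleImageConfig",
    "simulate_trace",
    "simulate_vesicle_stack",
    "simulate_timelapse",
    "timelapse_masks",
    "expected_count_rate_khz",
    "expected_occupancy",
    "mean_molecules_for_occupancy",
    "spectral_channel_weights",
    "analytic_channel_gp",
    "lambda_max_for_gp",
    "analytic_sector_gp",
    "default_channel_centers",
]

# Spectral acquisition defaults: 32 detector channels of 8.9-nm width
# starting at 570 nm (561-nm excitation, red-emitting Nile-red dyes).
N_CHANNELS_DEFAULT = 32
CHANNEL_STEP_NM = 8.9
CHANNEL_START_NM = 570.0
LAMBDA_B_NM = 575.0  # blue/ordered analysis wavelength
LAMBDA_R_NM = 640.0  # red/disordered analysis wavelength


# ---------------------------------------------------------------------------
# FCS trace simulation


@dataclass
class SimulationConfig:
    """Ground truth for one simulated FCS acquisition.

    Parameters
    ----------
    box_side : float
        Side of the periodic simulation box, um.  Should be >= 10 * omega0
        so that boundary wrap does not distort the spot statistics.
    d_true : float
        Diffusion coefficient of the dye in the membrane, um^2/s.
    omega0 : float
        1/e^2 radius of the Gaussian observation spot, nm.
    mean_molecules : float
        Expected number of membrane-bound dye molecules in the box.
    brightness : float
        Peak detected count rate of one molecule at the spot center, kHz.
    gp_true : float
        Ground-truth GP of the environment; each photon is blue with
        probability (1 + gp_true) / 2.
    k_off : float
        Membrane unbinding rate, 1/s.  0 means permanent binding; an
        unbinding molecule is instantaneously replaced by a fresh one at a
        uniform random position (reservoir exchange).
    bleach_rate : float
        Peak bleaching hazard at the spot center, 1/s; scales with the
        local excitation profile exp(-2 r^2 / omega0^2).
    bin_width : float
        Photon binning time, seconds.
    duration : float
        Trace length, seconds.
    seed : int
        RNG seed; identical config + seed gives a bit-identical trace.
    """

    box_side: float = 2.9
    d_true: float = 1.0
    omega0: float = 290.0
    mean_molecules: float = 100.0
    brightness: float = 3.0
    gp_true: float = 0.0
    k_off: float = 0.0
    bleach_rate: float = 0.0
    bin_width: float = 1e-6
    duration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.gp_true <= 1.0:
            raise ValueError("gp_true must be in [-1, 1]")
        for name in ("box_side", "omega0", "bin_width", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("d_true", "brightness", "k_off", "bleach_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.mean_molecules <= 0:
            raise ValueError("mean_molecules must be positive")

    @property
    def omega0_um(self) -> float:
        return self.omega0 * 1e-3

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_width))

    @property
    def tau_d_ms(self) -> float:
        """Expected transit time omega0^2 / (4 D) in ms (inf when D = 0)."""
        if self.d_true == 0:
            return float("inf")
        return self.omega0_um**2 / (4.0 * self.d_true) * 1e3


def expected_occupancy(config: SimulationConfig) -> float:
    """Expected FCS occupancy N = c * pi * omega0^2.

    This is the N a 2D-Gaussian-spot FCS fit reports: the amplitude of the
    normalized autocorrelation extrapolates to 1 / (c * pi * omega0^2) for
    surface concentration c.
    """
    return config.mean_molecules * math.pi * config.omega0_um**2 / config.box_side**2


def mean_molecules_for_occupancy(
    n_spot: float, box_side: float = 2.9, omega0: float = 290.0
) -> float:
    """Box molecule count giving FCS occupancy ``n_spot``."""
    return n_spot * box_side**2 / (math.pi * (omega0 * 1e-3) ** 2)


def expected_count_rate_khz(config: SimulationConfig) -> float:
    """Mean total detected count rate, kHz.

    At bath concentration c = mean_molecules / box_side^2 the detected
    rate is c * brightness * integral of the Gaussian profile
    = c * brightness * pi * omega0^2 / 2; with box_side >= 10 * omega0 the
    profile mass outside the box is ~exp(-50) and ignored.
    """
    return (
        config.mean_molecules
        * config.brightness
        * math.pi
        * config.omega0_um**2
        / (2.0 * config.box_side**2)
    )


def _position_step(config: SimulationConfig) -> int:
    """Bins per position update so RMS step displacement <= omega0 / 10."""
    if config.d_true == 0:
        return config.n_bins
    dt_max = (config.omega0_um / 10.0) ** 2 / (4.0 * config.d_true)
    if dt_max < config.bin_width:
        raise ValueError(
            "bin_width is the limiting parameter: molecules move more than "
            f"omega0/10 per bin (need bin_width <= {dt_max:.3g} s for "
            f"d_true = {config.d_true} um^2/s, omega0 = {config.omega0} nm)"
        )
    return max(1, int(dt_max / config.bin_width))


def _min_image_r2(pos: np.ndarray, box: float) -> np.ndarray:
    """Squared minimum-image distance to the box center; pos shape (..., 2)."""
    d = (pos - box / 2.0 + box / 2.0) % box - box / 2.0
    return np.square(d).sum(axis=-1)


@njit(cache=False)
def _seed_numba(seed: int) -> None:  # pragma: no cover
    np.random.seed(seed)


@njit(cache=False)
def _open_box_chunk(
    steps: np.ndarray,  # (k, cap, 2) float32 unit-normal increments
    n_in: np.ndarray,  # (k,) entrants per step
    pos: np.ndarray,  # (cap, 2) molecule positions, mutated
    active: np.ndarray,  # (cap,) uint8, mutated
    free: np.ndarray,  # (cap,) free-slot stack, mutated
    nfree: int,
    box: float,
    sigma: float,
    inv_w2: float,
    rate: np.ndarray,  # (k,) output: summed exp profile per step
) -> int:  # pragma: no cover - exercised via simulate_trace
    """Advance one chunk of position steps in the open box.

    A molecule stepping outside the box is handed back to the surrounding
    uniform bath (its detected intensity out there is ~exp(-50) of peak,
    so dropping it is exact at double precision); entrants arrive as a
    Poisson boundary flux with the overshoot-depth law of a uniform bath.
    The in-box molecule number is thus Poisson at every time, as in an
    unbounded membrane — a closed box would imprint a spurious -1/M
    offset on the normalized autocorrelation.
    """
    k, cap = steps.shape[0], pos.shape[0]
    r2_cut = 20.0 / inv_w2  # exp(-2 r^2 / w^2) < 2e-9 beyond this
    center = box / 2.0
    for t in range(k):
        s = 0.0
        for i in range(cap):
            if active[i] == 1:
                dx = pos[i, 0] - center
                dy = pos[i, 1] - center
                r2 = dx * dx + dy * dy
                if r2 < r2_cut:
                    s += math.exp(-inv_w2 * r2)
                if sigma > 0.0:
                    x = pos[i, 0] + sigma * steps[t, i, 0]
                    y = pos[i, 1] + sigma * steps[t, i, 1]
                    if x < 0.0 or x >= box or y < 0.0 or y >= box:
                        active[i] = 0
                        free[nfree] = i
                        nfree += 1
                    else:
                        pos[i, 0] = x
                        pos[i, 1] = y
        rate[t] = s
        for _ in range(n_in[t]):
            if nfree == 0:
                break
            # entry depth: overshoot of a Gaussian step past a uniform
            # bath distance (rejection from u ~ U(0, 6 sigma))
            d = -1.0
            while d < 0.0:
                u = np.random.random() * 6.0 * sigma
                step = abs(np.random.normal()) * sigma
                if step > u:
                    d = step - u
            e = int(np.random.random() * 4.0)
            a = np.random.random() * box
            if e == 0:
                x, y = d, a
            elif e == 1:
                x, y = box - d, a
            elif e == 2:
                x, y = a, d
            else:
                x, y = a, box - d
            i = free[nfree - 1]
            nfree -= 1
            active[i] = 1
            pos[i, 0] = x
            pos[i, 1] = y
    return nfree


def _rates_pure_diffusion(
    config: SimulationConfig, n_steps: int, dt: float
) -> np.ndarray:
    """Per-step summed emission rate for exchange- and bleach-free dye.

    Grand-canonical open-box dynamics: step increments are bulk-generated
    (float32, the step is ~omega0/14 so single precision is far below
    thermal position noise) and consumed by the compiled chunk kernel.
    """
    if config.mean_molecules == 0 or config.brightness == 0:
        return np.zeros(n_steps)
    box = config.box_side
    sigma = math.sqrt(2.0 * config.d_true * dt)
    cap = int(config.mean_molecules + 10.0 * math.sqrt(config.mean_molecules) + 64)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x0B0E]))
    _seed_numba(config.seed % (2**31))
    pos = rng.uniform(0.0, box, size=(cap, 2))
    m0 = min(cap, int(rng.poisson(config.mean_molecules)))
    active = np.zeros(cap, np.uint8)
    active[:m0] = 1
    free = np.concatenate([np.arange(cap - 1, m0 - 1, -1), np.zeros(m0, np.int64)])
    nfree = cap - m0
    mu_in = (
        4.0 * box * (config.mean_molecules / box**2) * sigma / math.sqrt(2.0 * math.pi)
        if sigma > 0
        else 0.0
    )
    rate = np.empty(n_steps)
    chunk = max(64, int(4_000_000 // cap))
    done = 0
    while done < n_steps:
        k = min(chunk, n_steps - done)
        if sigma > 0:
            steps = rng.standard_normal((k, cap, 2), dtype=np.float32)
        else:
            steps = np.zeros((1, cap, 2), np.float32)[:1].repeat(k, axis=0)
        n_in = rng.poisson(mu_in, k) if mu_in > 0 else np.zeros(k, np.int64)
        nfree = _open_box_chunk(
            steps, n_in.astype(np.int64), pos, active, free, nfree,
            box, sigma, 2.0 / config.omega0_um**2, rate[done : done + k],
        )
        done += k
    return rate * (config.brightness * 1e3)


def _rates_with_events(
    config: SimulationConfig, rng: np.random.Generator, n_steps: int, dt: float
) -> np.ndarray:
    """Per-step summed rate with unbinding/rebinding and bleaching.

    Sequential over position steps (events change the state), vectorized
    over molecules.  Bleached molecules of a permanent dye stay dark; a
    bleached exchangeable molecule is replaced by fresh dye when it
    unbinds, so the fluorescent pool is stationary.
    """
    m = int(rng.poisson(config.mean_molecules))
    box = config.box_side
    rate = np.zeros(n_steps)
    if m == 0 or config.brightness == 0:
        return rate
    pos = rng.uniform(0.0, box, size=(m, 2))
    alive = np.ones(m, dtype=bool)
    sigma = math.sqrt(2.0 * config.d_true * dt)
    b_cps = config.brightness * 1e3
    inv_w2 = 2.0 / config.omega0_um**2
    p_unbind = -math.expm1(-config.k_off * dt) if config.k_off > 0 else 0.0
    for s in range(n_steps):
        w = np.exp(-inv_w2 * _min_image_r2(pos, box))
        rate[s] = b_cps * w[alive].sum()
        if config.bleach_rate > 0:
            p_bleach = -np.expm1(-config.bleach_rate * w * dt)
            alive &= rng.random(m) >= p_bleach
        if p_unbind > 0:
            ub = rng.random(m) < p_unbind
            n_ub = int(ub.sum())
            if n_ub:
                pos[ub] = rng.uniform(0.0, box, size=(n_ub, 2))
                alive[ub] = True
        if sigma > 0:
            pos += rng.standard_normal((m, 2)) * sigma
            pos %= box
    return rate


def simulate_trace(config: SimulationConfig) -> PhotonTrace:
    """Simulate one binned two-channel photon trace.

    Molecules perform 2D Brownian steps in a periodic box; positions are
    advanced on the coarsest grid keeping the RMS step below omega0 / 10,
    and the emission rate is held constant between updates.  Photon counts
    per bin are Poisson with rate brightness * exp(-2 r^2 / omega0^2)
    summed over fluorescent molecules; each photon lands in the blue
    channel with probability (1 + gp_true) / 2.
    """
    n_bins = config.n_bins
    if n_bins < 10:
        raise ValueError(
            f"duration gives only {n_bins} bins; at least 10 are required"
        )
    bins_per_step = _position_step(config)
    n_steps = -(-n_bins // bins_per_step)
    dt = bins_per_step * config.bin_width
    rng = np.random.default_rng(config.seed)
    if config.k_off > 0 or config.bleach_rate > 0:
        rate = _rates_with_events(config, rng, n_steps, dt)
    else:
        rate = _rates_pure_diffusion(config, n_steps, dt)
    lam = np.repeat(rate, bins_per_step)[:n_bins] * config.bin_width
    total = rng.poisson(lam)
    p_blue = (1.0 + config.gp_true) / 2.0
    blue = rng.binomial(total, p_blue)
    red = total - blue
    meta = {
        "simulated": True,
        "d_true_um2_s": config.d_true,
        "omega0_nm": config.omega0,
        "gp_true": config.gp_true,
        "brightness_khz": config.brightness,
        "mean_molecules": config.mean_molecules,
        "k_off_per_s": config.k_off,
        "bleach_rate_per_s": config.bleach_rate,
        "seed": config.seed,
        "expected_occupancy": expected_occupancy(config),
        "expected_rate_khz": expected_count_rate_khz(config),
        "tau_d_expected_ms": config.tau_d_ms,
    }
    return PhotonTrace(blue, red, config.bin_width, meta=meta)


# ---------------------------------------------------------------------------
# Spectral vesicle images


def default_channel_centers(
    n_channels: int = N_CHANNELS_DEFAULT,
    start: float = CHANNEL_START_NM,
    step: float = CHANNEL_STEP_NM,
) -> np.ndarray:
    """Center wavelengths (nm) of the spectral detector channels."""
    return start + step * np.arange(n_channels)


def spectral_channel_weights(
    lambda_max: float, sigma_lambda: float, centers: np.ndarray, step: float
) -> np.ndarray:
    """Fraction of a Gaussian emission spectrum falling in each channel.

    Each channel integrates the unit-normalized Gaussian over its
    ``step``-wide window centered at the channel wavelength.
    """
    centers = np.asarray(centers, dtype=float)
    lo = (centers - step / 2.0 - lambda_max) / sigma_lambda
    hi = (centers + step / 2.0 - lambda_max) / sigma_lambda
    return ndtr(hi) - ndtr(lo)


def _analysis_channels(
    centers: np.ndarray, lambda_b: float, lambda_r: float
) -> tuple[int, int]:
    centers = np.asarray(centers, dtype=float)
    for lam in (lambda_b, lambda_r):
        if not (centers[0] - CHANNEL_STEP_NM / 2 <= lam <= centers[-1] + CHANNEL_STEP_NM / 2):
            raise ValueError(
                f"analysis wavelength {lam} nm outside channel range "
                f"[{centers[0]}, {centers[-1]}] nm"
            )
    ib = int(np.argmin(np.abs(centers - lambda_b)))
    ir = int(np.argmin(np.abs(centers - lambda_r)))
    return ib, ir


def analytic_channel_gp(
    lambda_max: float,
    sigma_lambda: float,
    centers: Optional[np.ndarray] = None,
    step: float = CHANNEL_STEP_NM,
    lambda_b: float = LAMBDA_B_NM,
    lambda_r: float = LAMBDA_R_NM,
) -> float:
    """GP of a noiseless Gaussian spectrum read at the two analysis channels.

    This is the oracle for the GP-imaging path: Ib and Ir are the channel
    integrals nearest to ``lambda_b`` and ``lambda_r``.
    """
    if centers is None:
        centers = default_channel_centers()
    w = spectral_channel_weights(lambda_max, sigma_lambda, centers, step)
    ib, ir = _analysis_channels(centers, lambda_b, lambda_r)
    return float((w[ib] - w[ir]) / (w[ib] + w[ir]))


def lambda_max_for_gp(
    gp: float,
    sigma_lambda: float = 30.0,
    centers: Optional[np.ndarray] = None,
    step: float = CHANNEL_STEP_NM,
    lambda_b: float = LAMBDA_B_NM,
    lambda_r: float = LAMBDA_R_NM,
) -> float:
    """Invert :func:`analytic_channel_gp`: emission peak giving target GP.

    GP decreases monotonically as the emission maximum red-shifts, so the
    root is unique.
    """
    if not -1.0 < gp < 1.0:
        raise ValueError("gp must be strictly inside (-1, 1)")
    if centers is None:
        centers = default_channel_centers()
    lo, hi = lambda_b - 4 * sigma_lambda, lambda_r + 4 * sigma_lambda
    return float(
        brentq(
            lambda lam: analytic_channel_gp(lam, sigma_lambda, centers, step, lambda_b, lambda_r)
            - gp,
            lo,
            hi,
        )
    )


@dataclass
class VesiclePhase:
    """One angular sector of the vesicle ring (a lipid phase).

    Exactly one of ``lambda_max`` (emission peak, nm) or ``gp_true`` must
    be given; a GP is converted to the emission peak that yields it at the
    analysis channels.
    """

    theta_start: float  # radians in [0, 2 pi)
    theta_end: float
    amplitude: float  # expected peak-channel counts at the ring crest
    lambda_max: Optional[float] = None
    gp_true: Optional[float] = None
    sigma_lambda: float = 30.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("sector amplitude must be nonnegative")
        if (self.lambda_max is None) == (self.gp_true is None):
            raise ValueError("give exactly one of lambda_max or gp_true")


@dataclass
class VesicleImageConfig:
    """Geometry and spectroscopy of a synthetic phase-separated vesicle."""

    phases: Sequence[VesiclePhase] = field(default_factory=list)
    image_size: int = 64
    pixel_size: float = 100.0  # nm
    ring_radius: float = 2000.0  # nm
    ring_width: float = 150.0  # Gaussian radial sigma, nm
    n_channels: int = N_CHANNELS_DEFAULT
    channel_start: float = CHANNEL_START_NM
    channel_step: float = CHANNEL_STEP_NM
    background: float = 1.0  # expected counts per pixel per channel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 spectral channels")
        if self.channel_step <= 0:
            raise ValueError("channel_step must be positive")
        if not self.phases:
            raise ValueError("at least one phase sector required")
        starts = sorted(p.theta_start for p in self.phases)
        order = sorted(self.phases, key=lambda p: p.theta_start)
        for a, b in zip(order, order[1:]):
            if not math.isclose(a.theta_end, b.theta_start, abs_tol=1e-9):
                raise ValueError("phase sectors must partition [0, 2 pi)")
        if not math.isclose(
            order[-1].theta_end - order[0].theta_start, 2 * math.pi, abs_tol=1e-9
        ):
            raise ValueError("phase sectors must partition [0, 2 pi)")

    @property
    def channel_centers(self) -> np.ndarray:
        return default_channel_centers(self.n_channels, self.channel_start, self.channel_step)


def _phase_lambda_max(phase: VesiclePhase, config: VesicleImageConfig) -> float:
    if phase.lambda_max is not None:
        return phase.lambda_max
    return lambda_max_for_gp(
        phase.gp_true, phase.sigma_lambda, config.channel_centers, config.channel_step
    )


def analytic_sector_gp(
    phase: VesiclePhase,
    config: VesicleImageConfig,
    lambda_b: float = LAMBDA_B_NM,
    lambda_r: float = LAMBDA_R_NM,
) -> float:
    """Noiseless GP of one sector of a configured vesicle (test oracle)."""
    lam = _phase_lambda_max(phase, config)
    return analytic_channel_gp(
        lam, phase.sigma_lambda, config.channel_centers, config.channel_step,
        lambda_b, lambda_r,
    )


def sector_masks(config: VesicleImageConfig) -> list[np.ndarray]:
    """Boolean pixel masks of each phase sector (full angular wedges)."""
    n = config.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    theta = np.mod(np.arctan2(yy - c, xx - c), 2 * math.pi)
    masks = []
    for p in config.phases:
        masks.append((theta >= p.theta_start - 1e-12) & (theta < p.theta_end - 1e-12))
    return masks


def simulate_vesicle_stack(config: VesicleImageConfig) -> ChannelStack:
    """Render a spectral image stack of a phase-separated vesicle.

    The equatorial cross-section is a ring with a Gaussian radial profile;
    each angular sector emits a Gaussian spectrum integrated over the
    detector channels, scaled so the crest of the ring reaches the
    sector's ``amplitude`` in the peak channel.  Poisson noise throughout;
    deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r_nm = np.hypot(yy - c, xx - c) * config.pixel_size
    profile = np.exp(-((r_nm - config.ring_radius) ** 2) / (2.0 * config.ring_width**2))
    centers = config.channel_centers
    expected = np.full((n, n, config.n_channels), float(config.background))
    for phase, mask in zip(config.phases, sector_masks(config)):
        lam = _phase_lambda_max(phase, config)
        w = spectral_channel_weights(lam, phase.sigma_lambda, centers, config.channel_step)
        if w.max() > 0:
            w = w / w.max()
        expected[mask] += phase.amplitude * profile[mask, None] * w[None, :]
    counts = rng.poisson(expected).astype(float)
    return ChannelStack(
        counts,
        kind="spectral",
        channel_centers=centers,
        pixel_size=config.pixel_size,
        meta={
            "simulated": True,
            "seed": config.seed,
            "ring_radius_nm": config.ring_radius,
            "sector_lambda_max_nm": [
                _phase_lambda_max(p, config) for p in config.phases
            ],
        },
    )


# ---------------------------------------------------------------------------
# Two-band time-lapse series


def timelapse_masks(image_size: int = 64) -> dict[str, np.ndarray]:
    """Compartment masks of the synthetic cell scene.

    Concentric geometry: membrane ring, cytosol annulus, nucleus disk and
    a signal-free background region outside the cell.
    """
    n = image_size
    s = n / 64.0
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(yy - c, xx - c)
    return {
        "membrane": np.abs(r - 20 * s) <= 2 * s,
        "cytosol": (r < 17 * s) & (r >= 8 * s),
        "nucleus": r < 7 * s,
        "background": r > 26 * s,
    }


def simulate_timelapse(
    dye_kind: str,
    frames: int,
    bleach_per_frame: Union[float, tuple[float, float]] = 0.0,
    internalization_rate: float = 0.0,
    seed: int = 0,
    *,
    gp_membrane: Union[float, Sequence[float]] = 0.3,
    image_size: int = 64,
    membrane_intensity: float = 200.0,
    cytosol_intensity: float = 4.0,
    nucleus_intensity: float = 2.0,
    background: float = 2.0,
    frame_interval: float = 10.0,
) -> list[ChannelStack]:
    """Simulate a two-band (ordered/disordered) time-lapse image series.

    A ``permanent`` dye's membrane signal decays geometrically by
    (1 - bleach_per_frame) per frame; an ``exchangeable`` dye's membrane
    pool is replenished from solution so its expected intensity is
    stationary regardless of bleaching, with an optional linear cytosol
    rise of ``internalization_rate`` (fraction of the initial membrane
    intensity per frame).  ``bleach_per_frame`` may be a (blue, red) pair
    to emulate channel-biased bleaching and the resulting apparent GP
    drift.  ``gp_membrane`` may be a per-frame sequence to script GP
    time-courses (e.g. lipid exchange during fusion).
    """
    if dye_kind not in ("exchangeable", "permanent"):
        raise ValueError("dye_kind must be 'exchangeable' or 'permanent'")
    if frames < 2:
        raise ValueError("at least 2 frames required")
    if np.isscalar(bleach_per_frame):
        b_blue = b_red = float(bleach_per_frame)
    else:
        b_blue, b_red = (float(b) for b in bleach_per_frame)
    for b in (b_blue, b_red):
        if not 0.0 <= b < 1.0:
            raise ValueError("bleach_per_frame must be in [0, 1)")
    gp_frames = np.broadcast_to(np.asarray(gp_membrane, dtype=float), (frames,))
    if np.any(np.abs(gp_frames) > 1):
        raise ValueError("gp_membrane must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    masks = timelapse_masks(image_size)
    out: list[ChannelStack] = []
    for k in range(frames):
        gp = gp_frames[k]
        split = np.array([(1.0 + gp) / 2.0, (1.0 - gp) / 2.0])
        if dye_kind == "permanent":
            mem = membrane_intensity * split * np.array(
                [(1.0 - b_blue) ** k, (1.0 - b_red) ** k]
            )
            cyt = np.full(2, cytosol_intensity / 2.0)
        else:
            mem = membrane_intensity * split
            cyt = np.full(
                2,
                (cytosol_intensity + internalization_rate * k * membrane_intensity)
                / 2.0,
            )
        expected = np.full((image_size, image_size, 2), background / 2.0)
        expected[masks["membrane"]] += mem
        expected[masks["cytosol"]] += cyt
        expected[masks["nucleus"]] += nucleus_intensity / 2.0
        counts = rng.poisson(expected).astype(float)
        out.append(
            ChannelStack(
                counts,
                kind="banded",
                band_edges=[(580.0, 630.0), (650.0, 700.0)],
                pixel_size=40.0,
                frame_index=k,
                meta={
                    "simulated": True,
                    "dye_kind": dye_kind,
                    "frame_interval_s": frame_interval,
                    "gp_membrane": float(gp),
                    "bleach_per_frame": (b_blue, b_red),
                    "internalization_rate": internalization_rate,
                    "seed": seed,
                },
            )
        )
    return out
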