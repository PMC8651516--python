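"""STED-FCS observation-spot calibration.

Shrinking the observation spot with a STED depletion beam shortens the
transit time of a freely diffusing dye in proportion to the spot area, so
the apparent spot radius at a given STED power follows from the transit
times alone:

    omega0(STED) = omega0_conf * sqrt(tau_D(STED) / tau_D(conf))

and the diffusion coefficient, spot-size independent for free 2D
diffusion, is D = omega0^2 / (4 tau_D).  The confocal reference radius
defaults to 290 nm and is instrument-specific.
"""

from __future__ import annotations

from typing import Mapping

from .containers import CalibrationEntry, DiffusionFit, SpotCalibration

__all__ = [
    "apparent_spot_size",
    "diffusion_coefficient",
    "calibration_series",
    "OMEGA0_CONF_NM",
]

OMEGA0_CONF_NM = 290.0


def apparent_spot_size(
    tau_d_sted: float, tau_d_conf: float, omega0_conf: float = OMEGA0_CONF_NM
) -> float:
    """Apparent 1/e^2 spot radius (nm) from STED and confocal transit times.

    Equal transit times return the confocal reference radius exactly.
    """
    if tau_d_sted <= 0 or tau_d_conf <= 0:
        raise ValueError("transit times must be positive")
    if omega0_conf <= 0:
        raise ValueError("omega0_conf must be positive")
    return omega0_conf * (tau_d_sted / tau_d_conf) ** 0.5


def diffusion_coefficient(omega0: float, tau_d: float) -> float:
    """D = omega0^2 / (4 tau_D) for 2D diffusion; omega0 in nm, tau_d in
    ms, result in um^2/s."""
    if omega0 <= 0 or tau_d <= 0:
        raise ValueError("omega0 and tau_d must be positive")
    omega_um = omega0 * 1e-3
    tau_s = tau_d * 1e-3
    return omega_um**2 / (4.0 * tau_s)


def calibration_series(
    fits_by_power: Mapping[str, DiffusionFit],
    conf_fit: DiffusionFit,
    omega0_conf: float = OMEGA0_CONF_NM,
) -> SpotCalibration:
    """Build the per-power calibration table from diffusion fits.

    Each STED power contributes an apparent spot radius from its transit
    time relative to the confocal fit, and a diffusion coefficient from
    its own (omega0, tau_D) pair.  STED powers are opaque labels; no
    power-resolution curve is modeled.
    """
    if not conf_fit.converged:
        raise ValueError("confocal fit did not converge; cannot calibrate")
    if not fits_by_power:
        raise ValueError("need at least one STED power entry")
    cal = SpotCalibration(omega0_conf=omega0_conf)
    for power, fit in fits_by_power.items():
        omega = apparent_spot_size(fit.tau_d, conf_fit.tau_d, omega0_conf)
        cal.entries.append(
            CalibrationEntry(
                power=str(power),
                tau_d_sted=fit.tau_d,
                tau_d_conf=conf_fit.tau_d,
                omega0_apparent=omega,
                d=diffusion_coefficient(omega, fit.tau_d),
            )
        )
    return cal
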