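"""Insertion kinematics: linear drive with superimposed axial oscillation.

The shuttle is driven at a constant linear speed v while a piezo stage adds a
uniaxial sinusoid of frequency f and peak-to-peak amplitude A_pp along the
same (insertion) axis:

    position(t) = v*t + (A_pp/2) * sin(2*pi*f*t)

Velocity and acceleration are the exact derivatives, so the maximum
instantaneous speed is v + pi*f*A_pp and the maximum acceleration is
(2*pi*f)^2 * A_pp/2.  Amplitude is stored peak-to-peak (how hardware is
specified); phase starts at zero, which is irrelevant to the peaks.

Units: v in mm/s, f in Hz, A_pp in um; positions in um, velocities in mm/s,
accelerations in m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["InsertionProfile", "trajectory", "peak_speed", "peak_acceleration"]

#: Peak-to-peak amplitude ceiling (µm) of the piezo hardware the profile
#: models; override ``max_amplitude_pp_um`` for other actuators.
DEFAULT_AMPLITUDE_CEILING_UM = 70.0


@dataclass(frozen=True)
class InsertionProfile:
    """Motion profile: linear speed + axial sinusoidal oscillation."""

    linear_speed_mm_s: float
    osc_frequency_hz: float = 0.0
    amplitude_pp_um: float = 0.0
    duration_s: float = 1.0
    max_amplitude_pp_um: float = DEFAULT_AMPLITUDE_CEILING_UM

    def __post_init__(self) -> None:
        if min(
            self.linear_speed_mm_s,
            self.osc_frequency_hz,
            self.amplitude_pp_um,
            self.duration_s,
        ) < 0:
            raise ValueError("profile parameters must be non-negative")
        if self.amplitude_pp_um > self.max_amplitude_pp_um:
            raise ValueError(
                f"peak-to-peak amplitude {self.amplitude_pp_um} µm exceeds the "
                f"configured ceiling {self.max_amplitude_pp_um} µm"
            )


def trajectory(profile: InsertionProfile, t_grid: np.ndarray) -> pd.DataFrame:
    """Sample position/velocity/acceleration on a sorted time grid (s >= 0)."""
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if (t < 0).any() or (np.diff(t) < 0).any():
        raise ValueError("t_grid must be sorted and non-negative")
    half_um = profile.amplitude_pp_um / 2.0
    omega = 2.0 * np.pi * profile.osc_frequency_hz
    pos_um = profile.linear_speed_mm_s * 1000.0 * t + half_um * np.sin(omega * t)
    vel_mm_s = profile.linear_speed_mm_s + half_um * omega * np.cos(omega * t) * 1e-3
    acc_m_s2 = -half_um * omega ** 2 * np.sin(omega * t) * 1e-6
    return pd.DataFrame(
        {"t_s": t, "position_um": pos_um, "velocity_mm_s": vel_mm_s,
         "acceleration_m_s2": acc_m_s2}
    )


def peak_speed(profile: InsertionProfile) -> float:
    """Maximum instantaneous speed, mm/s:  v + pi*f*A_pp."""
    return (
        profile.linear_speed_mm_s
        + np.pi * profile.osc_frequency_hz * profile.amplitude_pp_um * 1e-3
    )


def peak_acceleration(profile: InsertionProfile) -> float:
    """Maximum instantaneous acceleration, m/s^2:  (2*pi*f)^2 * A_pp/2."""
    omega = 2.0 * np.pi * profile.osc_frequency_hz
    return omega ** 2 * (profile.amplitude_pp_um / 2.0) * 1e-6
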