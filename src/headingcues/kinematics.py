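"""Stimulus motion profiles for the heading-discrimination platform.

The heading stimulus is a straight-line translation whose acceleration is a
single cycle of a sine wave: a(t) = A sin(2*pi*t/T) for 0 <= t <= T.  With
A = 2*pi*d/T**2 the trajectory starts and ends at rest and covers a total
displacement d, with closed-form peaks

    peak velocity     = 2*d/T
    peak acceleration = A = 2*pi*d/T**2

The default stimulus (d = 16 cm, T = 2 s) therefore peaks at 16 cm/s and
8*pi ~ 25 cm/s^2.  Motion can be angled up to +/-50 deg left/right of
straight ahead; the planar displacement is decomposed onto the lateral
(sway, x) and fore-aft (surge, y) axes.

A separate vertical (heave, z) vibration can be superimposed: a sinusoidal
position trace at a fixed frequency.  The vibration "amplitude" is
interpreted throughout as the PEAK-TO-PEAK displacement; this is the only
reading under which a 0.20 cm amplitude at 6 Hz yields the platform's
measured peak velocity of 3.77 cm/s and peak acceleration of 0.145 g.

Units: cm, s, degrees; g = 981 cm/s^2.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "G_CM_S2",
    "MotionProfile",
    "PeakSummary",
    "heading_profile",
    "vibration_profile",
    "combine_profiles",
    "peak_kinematics",
    "profile_to_csv",
]

#: Standard gravity used for unit conversion, cm/s^2.
G_CM_S2 = 981.0

#: Fine grid used for analytic validation of the stimulus (s).
DT_VALIDATION = 1e-4
#: Display-rate grid (60 Hz) for profiles meant to drive rendering (s).
DT_DISPLAY = 1.0 / 60.0

_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class MotionProfile:
    """Sampled position/velocity/acceleration of one stimulus.

    Axes follow motion-platform convention: x = lateral (sway, positive
    rightward), y = fore-aft (surge, positive forward), z = vertical
    (heave, positive up).  ``heading_angle`` is degrees rightward of the
    midline for the planar (heading) component; pure-vibration profiles
    carry a heading of 0.
    """

    t: np.ndarray
    pos_x: np.ndarray
    pos_y: np.ndarray
    pos_z: np.ndarray
    vel_x: np.ndarray
    vel_y: np.ndarray
    vel_z: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    heading_angle: float = 0.0

    def __post_init__(self) -> None:
        n = self.t.shape[0]
        for f in fields(self):
            if f.name in ("heading_angle",):
                continue
            arr = getattr(self, f.name)
            if arr.shape != (n,):
                raise ValueError(f"field {f.name} has shape {arr.shape}, expected ({n},)")

    @property
    def pos(self) -> np.ndarray:
        """(n, 3) position array in axis order x, y, z."""
        return np.column_stack([self.pos_x, self.pos_y, self.pos_z])

    @property
    def vel(self) -> np.ndarray:
        return np.column_stack([self.vel_x, self.vel_y, self.vel_z])

    @property
    def acc(self) -> np.ndarray:
        return np.column_stack([self.acc_x, self.acc_y, self.acc_z])


@dataclass(frozen=True)
class PeakSummary:
    """Peak kinematic quantities of a profile (Euclidean norms over the grid)."""

    peak_speed: float
    peak_acceleration: float
    total_displacement: float
    per_axis_peak_pos: dict
    per_axis_peak_vel: dict
    per_axis_peak_acc: dict


def _time_grid(duration: float, dt: float) -> np.ndarray:
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    n = duration / dt
    n_round = round(n)
    if n_round < 1 or abs(n - n_round) > 1e-9 * max(1.0, n):
        raise ValueError(f"dt={dt} does not divide duration={duration}")
    return np.linspace(0.0, duration, n_round + 1)


def heading_profile(
    displacement: float,
    duration: float,
    heading_angle: float,
    dt: float = DT_VALIDATION,
) -> MotionProfile:
    """Single-cycle sine-in-acceleration translation along a fixed heading.

    Parameters
    ----------
    displacement : float
        Total path length in cm (>= 0; 0 gives an all-zero profile).
    duration : float
        Stimulus duration in s (one full acceleration cycle).
    heading_angle : float
        Direction of travel, degrees rightward of the midline, |angle| <= 90.
    dt : float
        Sample interval in s; must divide ``duration``.

    Returns
    -------
    MotionProfile
        Closed-form position/velocity/acceleration on the grid; z is 0.
    """
    if displacement < 0:
        raise ValueError(f"displacement must be non-negative, got {displacement}")
    if abs(heading_angle) > 90:
        raise ValueError(f"|heading_angle| must be <= 90 deg, got {heading_angle}")
    t = _time_grid(duration, dt)
    omega = 2.0 * np.pi / duration
    amp = 2.0 * np.pi * displacement / duration**2  # peak acceleration
    acc = amp * np.sin(omega * t)
    vel = amp / omega * (1.0 - np.cos(omega * t))
    pos = amp / omega * (t - np.sin(omega * t) / omega)

    theta = np.deg2rad(heading_angle)
    sx, sy = np.sin(theta), np.cos(theta)
    zero = np.zeros_like(t)
    return MotionProfile(
        t=t,
        pos_x=sx * pos, pos_y=sy * pos, pos_z=zero,
        vel_x=sx * vel, vel_y=sy * vel, vel_z=zero,
        acc_x=sx * acc, acc_y=sy * acc, acc_z=zero,
        heading_angle=float(heading_angle),
    )


def vibration_profile(
    amplitude_p2p: float,
    frequency: float,
    duration: float,
    dt: float = DT_VALIDATION,
    phase: float = 0.0,
) -> MotionProfile:
    """Sinusoidal vertical (heave) vibration.

    ``amplitude_p2p`` is the peak-to-peak displacement in cm, so the position
    trace is z(t) = (amplitude_p2p / 2) * sin(2*pi*f*t + phase).  Closed-form
    peaks: velocity pi*f*amplitude_p2p, acceleration 2*pi^2*f^2*amplitude_p2p.
    An amplitude of 0 returns the all-zero (no-vibration) profile.
    """
    if amplitude_p2p < 0:
        raise ValueError(f"amplitude_p2p must be non-negative, got {amplitude_p2p}")
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    t = _time_grid(duration, dt)
    omega = 2.0 * np.pi * frequency
    half = amplitude_p2p / 2.0
    zero = np.zeros_like(t)
    return MotionProfile(
        t=t,
        pos_x=zero, pos_y=zero, pos_z=half * np.sin(omega * t + phase),
        vel_x=zero, vel_y=zero, vel_z=half * omega * np.cos(omega * t + phase),
        acc_x=zero, acc_y=zero, acc_z=-half * omega**2 * np.sin(omega * t + phase),
        heading_angle=0.0,
    )


def combine_profiles(heading: MotionProfile, vibration: MotionProfile) -> MotionProfile:
    """Superimpose a heading translation and a vibration on one time grid.

    The axes of the two components are orthogonal by construction (heading is
    planar, vibration is heave), so their peak kinematics do not interact.
    The combined profile inherits the heading component's ``heading_angle``.
    """
    if heading.t.shape != vibration.t.shape or not np.allclose(
        heading.t, vibration.t, rtol=0.0, atol=1e-12
    ):
        raise ValueError("profiles must share an identical time grid")
    kw = {"t": heading.t, "heading_angle": heading.heading_angle}
    for f in ("pos", "vel", "acc"):
        for ax in _AXES:
            name = f"{f}_{ax}"
            kw[name] = getattr(heading, name) + getattr(vibration, name)
    return MotionProfile(**kw)


def peak_kinematics(profile: MotionProfile) -> PeakSummary:
    """Peak speed/acceleration (Euclidean norm) and net displacement of a profile."""
    if profile.t.size == 0:
        raise ValueError("profile is empty")
    speed = np.linalg.norm(profile.vel, axis=1)
    accmag = np.linalg.norm(profile.acc, axis=1)
    net = profile.pos[-1] - profile.pos[0]
    return PeakSummary(
        peak_speed=float(speed.max()),
        peak_acceleration=float(accmag.max()),
        total_displacement=float(np.linalg.norm(net)),
        per_axis_peak_pos={ax: float(np.abs(getattr(profile, f"pos_{ax}")).max()) for ax in _AXES},
        per_axis_peak_vel={ax: float(np.abs(getattr(profile, f"vel_{ax}")).max()) for ax in _AXES},
        per_axis_peak_acc={ax: float(np.abs(getattr(profile, f"acc_{ax}")).max()) for ax in _AXES},
    )


def profile_to_csv(profile: MotionProfile, path_or_buf) -> None:
    """Write a profile as plain CSV with a leading unit comment line."""
    cols = ["t"] + [f"{f}_{ax}" for f in ("pos", "vel", "acc") for ax in _AXES]
    header = "# units: t s, pos cm, vel cm/s, acc cm/s^2; heading_angle %.6f deg\n" % (
        profile.heading_angle,
    )
    data = np.column_stack([getattr(profile, c) for c in cols])
    buf = io.StringIO()
    buf.write(header)
    buf.write(",".join(cols) + "\n")
    np.savetxt(buf, data, delimiter=",", fmt="%.10g")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)
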