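"""Synthetic observers for the heading-discrimination task.

An observer is a parametric subject whose left/right judgments are drawn
from condition-dependent cumulative-Gaussian psychometric functions.  The
model captures the statistical structure the analysis assumes:

* **Sign convention** (fixed project-wide): headings are degrees rightward
  of the midline; the PSE mu is the heading judged rightward 50% of the
  time, so mu > 0 means a midline stimulus is more likely reported "left".
* **Visual** headings are encoded retinotopically, so eccentric gaze biases
  them *opposite* gaze: mu_V = +bias_V under right gaze, -bias_V under left.
* **Inertial** headings are in body coordinates with a small bias *toward*
  gaze: mu_I = -bias_I under right gaze, +bias_I under left.
* **Vibration** degrades inertial reliability as a step, not a dose:
  sigma_I = sigma_I0 * vib_inflation whenever any vertical vibration is
  present, independent of its amplitude.
* **Combined** (visual-inertial) conditions follow the weighted-sum fusion
  rule mu_VI = w_I*mu_I + w_V*mu_V with w_V = 1 - w_I.  In ``optimal`` mode
  the weights are the inverse-variance (maximum-likelihood) weights
  w_V = sigma_I^2/(sigma_I^2 + sigma_V^2); in ``fixed`` mode w_I is a free
  parameter, allowing inertial-overweighted observers.  The combined sigma
  defaults to the optimal-fusion value sigma_V*sigma_I/sqrt(sigma_V^2 +
  sigma_I^2) and can be overridden for sensitivity analyses.

The response rule is P(right) = lapse/2 + (1-lapse)*Phi((h - mu)/sigma);
the lapse rate defaults to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .integration import optimal_weights

__all__ = [
    "ObserverParams",
    "ConditionSpec",
    "DEFAULT_COHORT_RANGES",
    "condition_psychometric",
    "respond",
    "make_cohort",
]

#: Vibration amplitudes (peak-to-peak cm) used in the experiment.
VIBRATION_AMPLITUDES = (0.0, 0.10, 0.15, 0.20)


@dataclass(frozen=True)
class ObserverParams:
    """One synthetic subject.

    Defaults are the group-average values of the study this package
    emulates: visual sigma 3.6 deg at 50% coherence, inertial sigma 4.8 deg
    without vibration inflating to 8.8 deg with vibration (factor 11/6),
    visual gaze bias 9.6 deg opposite gaze, inertial gaze bias ~3 deg
    toward gaze.
    """

    sigma_V: float = 3.6
    sigma_I0: float = 4.8
    vib_inflation: float = 8.8 / 4.8
    bias_V: float = 9.6
    bias_I: float = 3.0
    integration_mode: str = "optimal"  # "optimal" or "fixed"
    w_I_fixed: Optional[float] = None
    sigma_VI_mode: str = "optimal"  # "optimal" or "override"
    sigma_VI_override: Optional[float] = None
    lapse: float = 0.0
    subject_id: str = "s1"

    def __post_init__(self) -> None:
        if self.sigma_V <= 0 or self.sigma_I0 <= 0:
            raise ValueError("sigmas must be positive")
        if self.vib_inflation < 1:
            raise ValueError(f"vib_inflation must be >= 1, got {self.vib_inflation}")
        if not (0 <= self.lapse < 0.5):
            raise ValueError(f"lapse must be in [0, 0.5), got {self.lapse}")
        if self.integration_mode not in ("optimal", "fixed"):
            raise ValueError(f"unknown integration_mode {self.integration_mode!r}")
        if self.integration_mode == "fixed" and (
            self.w_I_fixed is None or not math.isfinite(self.w_I_fixed)
        ):
            raise ValueError("fixed integration mode requires a finite w_I_fixed")
        if self.sigma_VI_mode not in ("optimal", "override"):
            raise ValueError(f"unknown sigma_VI_mode {self.sigma_VI_mode!r}")
        if self.sigma_VI_mode == "override" and (
            self.sigma_VI_override is None or self.sigma_VI_override <= 0
        ):
            raise ValueError("sigma_VI override must be positive")


@dataclass(frozen=True)
class ConditionSpec:
    """One stimulus condition: modality, vibration, coherence, gaze.

    In combined conditions the visual and inertial components are
    synchronized and direction-consistent by construction, so a single
    heading describes both.  Coherence is metadata only (all visual stimuli
    are 50% coherence in this design).
    """

    modality: str
    vibration_amplitude: float = 0.0
    coherence: float = 0.5
    gaze: str = "right"

    def __post_init__(self) -> None:
        if self.modality not in ("visual", "inertial", "combined"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.vibration_amplitude < 0:
            raise ValueError("vibration amplitude must be non-negative")
        if self.modality == "visual" and self.vibration_amplitude != 0:
            raise ValueError("visual-only conditions carry no vibration")
        if self.gaze not in ("left", "right"):
            raise ValueError(f"gaze must be 'left' or 'right', got {self.gaze!r}")


def _gaze_sign(gaze: str) -> float:
    return 1.0 if gaze == "right" else -1.0


def condition_psychometric(observer: ObserverParams, condition: ConditionSpec):
    """True (mu, sigma) of the observer's psychometric function in a condition.

    Returns the PSE mu (deg; positive = midline perceived leftward) and the
    discrimination sigma (deg).
    """
    g = _gaze_sign(condition.gaze)
    mu_V = g * observer.bias_V
    mu_I = -g * observer.bias_I
    sigma_V = observer.sigma_V
    sigma_I = observer.sigma_I0 * (
        observer.vib_inflation if condition.vibration_amplitude > 0 else 1.0
    )
    if condition.modality == "visual":
        return mu_V, sigma_V
    if condition.modality == "inertial":
        return mu_I, sigma_I
    # combined
    if observer.integration_mode == "optimal":
        w_V, w_I = optimal_weights(sigma_V, sigma_I)
    else:
        w_I = observer.w_I_fixed
        w_V = 1.0 - w_I
    mu_VI = w_I * mu_I + w_V * mu_V
    if observer.sigma_VI_mode == "optimal":
        sigma_VI = math.sqrt(sigma_V**2 * sigma_I**2 / (sigma_V**2 + sigma_I**2))
    else:
        sigma_VI = observer.sigma_VI_override
    return mu_VI, sigma_VI


def p_right(observer: ObserverParams, condition: ConditionSpec, heading) -> float:
    """Probability of a rightward report at the given heading (deg)."""
    from scipy.special import ndtr

    mu, sigma = condition_psychometric(observer, condition)
    z = (np.asarray(heading, dtype=float) - mu) / sigma
    return observer.lapse / 2.0 + (1.0 - observer.lapse) * ndtr(z)


def respond(observer: ObserverParams, condition: ConditionSpec, heading: float, rng) -> str:
    """Draw one binary left/right judgment at the given heading."""
    return "right" if rng.random() < p_right(observer, condition, heading) else "left"


#: Default per-parameter sampling ranges for synthetic cohorts, spanning the
#: between-subject spread around the study's group values.  ``p_fixed`` is the
#: probability that a subject integrates with a fixed (typically
#: inertial-overweighted) weight rather than optimally, and ``w_I_fixed``
#: spans weights at and above the group-average empirical inertial weight.
DEFAULT_COHORT_RANGES: dict = {
    "sigma_V": (2.0, 5.5),
    "sigma_I0": (3.0, 7.0),
    "vib_inflation": (1.5, 2.2),
    "bias_V": (7.0, 12.0),
    "bias_I": (2.0, 4.0),
    "w_I_fixed": (0.87, 0.95),
    "p_fixed": 0.6,
    "lapse": (0.0, 0.0),
}


def make_cohort(n_subjects: int, parameter_ranges: dict | None = None, seed=None) -> list:
    """Reproducibly draw a heterogeneous cohort of observers.

    Each scalar parameter is drawn uniformly from its ``(lo, hi)`` range;
    integration mode is ``fixed`` with probability ``p_fixed`` (at least one
    fixed-weight, inertial-overweighted observer is guaranteed when
    ``p_fixed > 0`` and n_subjects >= 1, mirroring the population the design
    is built to detect).  Degenerate ranges (lo == hi) give identical
    observers.  Deterministic under ``seed``.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    ranges = dict(DEFAULT_COHORT_RANGES)
    if parameter_ranges is not None:
        if not parameter_ranges:
            raise ValueError("parameter_ranges must be a non-empty mapping (or None)")
        unknown = set(parameter_ranges) - set(DEFAULT_COHORT_RANGES)
        if unknown:
            raise ValueError(f"unknown cohort parameters: {sorted(unknown)}")
        ranges.update(parameter_ranges)

    rng = np.random.default_rng(seed)

    def draw(name):
        lo, hi = ranges[name]
        return float(rng.uniform(lo, hi))

    cohort = []
    fixed_flags = rng.random(n_subjects) < ranges["p_fixed"]
    if ranges["p_fixed"] > 0 and not fixed_flags.any():
        fixed_flags[0] = True
    for i in range(n_subjects):
        fixed = bool(fixed_flags[i])
        cohort.append(
            ObserverParams(
                sigma_V=draw("sigma_V"),
                sigma_I0=draw("sigma_I0"),
                vib_inflation=draw("vib_inflation"),
                bias_V=draw("bias_V"),
                bias_I=draw("bias_I"),
                integration_mode="fixed" if fixed else "optimal",
                w_I_fixed=draw("w_I_fixed") if fixed else None,
                lapse=draw("lapse"),
                subject_id=f"s{i + 1}",
            )
        )
    return cohort
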