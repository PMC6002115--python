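"""Visual-inertial cue weights and derived gaze-bias statistics.

Under the weighted-sum fusion model the combined heading percept is
S_VI = w_I*S_I + w_V*S_V with w_V + w_I = 1.  Two weight estimates are
compared:

* **Optimal** (inverse-variance / maximum-likelihood) weights from the
  unisensory discrimination sigmas:

      w_V_opt = sigma_I^2 / (sigma_I^2 + sigma_V^2),   w_I_opt = 1 - w_V_opt

* **Empirical** weights from the measured PSEs of the unisensory and
  combined conditions, exploiting the gaze-driven dissociation of the
  visual and inertial PSEs:

      w_V_emp = (mu_VI - mu_I) / (mu_V - mu_I),        w_I_emp = 1 - w_V_emp

Empirical weights are unconstrained: values outside [0, 1] (e.g. a negative
visual weight when the inertial cue is weighted beyond unity) are a genuine
finding and are flagged, never clipped.  Confidence intervals for both kinds
of weight are propagated from bootstrap resamples of the three underlying
psychometric fits, paired by resample index, and reported as the 5th-95th
percentile interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .exceptions import DegenerateDataError, DegenerateSeparationError, IncompleteDesignError

__all__ = [
    "EmpiricalWeights",
    "WeightEstimate",
    "optimal_weights",
    "empirical_weights",
    "weight_cis",
    "separation_statistic",
    "gaze_bias_summary",
]

#: Minimum |mu_V - mu_I| (deg) below which empirical weights are unidentifiable.
SEPARATION_FLOOR = 1e-6


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the human-readable tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


class EmpiricalWeights(NamedTuple):
    w_V: float
    w_I: float
    out_of_range: bool


def optimal_weights(sigma_V: float, sigma_I: float) -> tuple:
    """Inverse-variance weights (w_V_opt, w_I_opt); the pair sums to 1 exactly."""
    if sigma_V <= 0 or sigma_I <= 0:
        raise ValueError(f"sigmas must be positive, got sigma_V={sigma_V}, sigma_I={sigma_I}")
    w_V = sigma_I**2 / (sigma_I**2 + sigma_V**2)
    return w_V, 1.0 - w_V


def empirical_weights(
    mu_V: float,
    mu_I: float,
    mu_VI: float,
    separation_floor: float = SEPARATION_FLOOR,
) -> EmpiricalWeights:
    """Weights implied by the combined PSE's position between the unisensory PSEs.

    Raises :class:`DegenerateSeparationError` when the unisensory PSEs
    coincide (|mu_V - mu_I| below ``separation_floor``), since the weights
    are then unidentifiable.  A combined PSE outside the interval spanned by
    the unisensory PSEs yields weights outside [0, 1]; these are returned
    with ``out_of_range=True``.
    """
    sep = mu_V - mu_I
    if abs(sep) < separation_floor:
        raise DegenerateSeparationError(
            f"|mu_V - mu_I| = {abs(sep):.3g} deg is below the separation floor "
            f"{separation_floor:g}; empirical weights are unidentifiable"
        )
    w_I = (mu_VI - mu_V) / (mu_I - mu_V)
    w_V = 1.0 - w_I
    out = not (0.0 <= w_I <= 1.0)
    return EmpiricalWeights(w_V=w_V, w_I=w_I, out_of_range=out)


@dataclass
class WeightEstimate:
    """Optimal and empirical weight pairs with percentile CIs for one condition."""

    w_I_opt: float
    w_V_opt: float
    w_I_emp: float
    w_V_emp: float
    ci_w_I_opt: Optional[tuple] = None
    ci_w_I_emp: Optional[tuple] = None
    ci_w_V_opt: Optional[tuple] = None
    ci_w_V_emp: Optional[tuple] = None
    out_of_range: bool = False
    n_resamples: int = 0
    n_dropped: int = 0
    condition: object = None
    sources: dict = field(default_factory=dict)


def weight_cis(
    boot_V,
    boot_I,
    boot_VI,
    point_V=None,
    point_I=None,
    point_VI=None,
    seed=None,
    percentiles=(5.0, 95.0),
    separation_floor: float = SEPARATION_FLOOR,
) -> WeightEstimate:
    """Propagate bootstrap (mu, sigma) resamples into weight confidence intervals.

    ``boot_V``, ``boot_I``, ``boot_VI`` are equal-length arrays of resampled
    (mu, sigma) pairs from the visual, inertial and combined fits.  When
    ``seed`` is given, each list is independently shuffled before pairing by
    index (the three bootstraps are independent, so any pairing is valid; the
    shuffle makes the arbitrary pairing explicit and reproducible).  Each
    triple yields one optimal pair (from the sigmas) and one empirical pair
    (from the mus); degenerate triples (non-positive sigma or unisensory-PSE
    separation below the floor) are dropped and counted, and intervals are
    the requested percentiles (default 5th-95th) of the survivors.

    Point estimates, if supplied as (mu, sigma) pairs from the original fits,
    populate the central values; otherwise resample medians are used.
    """
    bV, bI, bVI = (np.asarray(b, dtype=float) for b in (boot_V, boot_I, boot_VI))
    if not (bV.shape == bI.shape == bVI.shape) or bV.ndim != 2 or bV.shape[1] != 2:
        raise ValueError("resample lists must be equal-length arrays of (mu, sigma) pairs")
    n = bV.shape[0]
    if n == 0:
        raise ValueError("resample lists are empty")
    if seed is not None:
        rng = np.random.default_rng(seed)
        bV, bI, bVI = (b[rng.permutation(n)] for b in (bV, bI, bVI))

    mu_V, s_V = bV[:, 0], bV[:, 1]
    mu_I, s_I = bI[:, 0], bI[:, 1]
    mu_VI = bVI[:, 0]

    ok = (s_V > 0) & (s_I > 0) & (np.abs(mu_V - mu_I) >= separation_floor)
    n_dropped = int(n - ok.sum())
    if n_dropped > n / 2:
        raise DegenerateDataError(
            f"{n_dropped} of {n} weight resamples degenerate (> 50%)"
        )
    w_V_opt = s_I[ok] ** 2 / (s_I[ok] ** 2 + s_V[ok] ** 2)
    w_I_emp = (mu_VI[ok] - mu_V[ok]) / (mu_I[ok] - mu_V[ok])

    lo, hi = percentiles

    def ci(arr):
        return (float(np.percentile(arr, lo)), float(np.percentile(arr, hi)))

    if point_V is not None and point_I is not None and point_VI is not None:
        pw_V_opt, pw_I_opt = optimal_weights(point_V[1], point_I[1])
        emp = empirical_weights(point_V[0], point_I[0], point_VI[0],
                                separation_floor=separation_floor)
        pw_V_emp, pw_I_emp, out = emp.w_V, emp.w_I, emp.out_of_range
    else:
        pw_V_opt = float(np.median(w_V_opt))
        pw_I_opt = 1.0 - pw_V_opt
        pw_I_emp = float(np.median(w_I_emp))
        pw_V_emp = 1.0 - pw_I_emp
        out = not (0.0 <= pw_I_emp <= 1.0)

    return WeightEstimate(
        w_I_opt=pw_I_opt,
        w_V_opt=pw_V_opt,
        w_I_emp=pw_I_emp,
        w_V_emp=pw_V_emp,
        ci_w_I_opt=ci(1.0 - w_V_opt),
        ci_w_V_opt=ci(w_V_opt),
        ci_w_I_emp=ci(w_I_emp),
        ci_w_V_emp=ci(1.0 - w_I_emp),
        out_of_range=out,
        n_resamples=int(ok.sum()),
        n_dropped=n_dropped,
    )


def separation_statistic(
    mu_V_left: float, mu_V_right: float, mu_I_left: float, mu_I_right: float
) -> float:
    """Mean gaze-wise |visual PSE - inertial PSE| separation, deg (1 decimal).

    This is the dissociation that makes empirical weights measurable: under
    eccentric gaze the visual and inertial PSEs move apart, and the combined
    PSE's position between them reveals the cue weighting.  Averages the
    absolute separation over the two gaze directions and rounds half away
    from zero to one decimal (the precision of the reported tables).
    """
    sep = 0.5 * (abs(mu_V_left - mu_I_left) + abs(mu_V_right - mu_I_right))
    return round_half_away(sep, 1)


def gaze_bias_summary(fits) -> dict:
    """Mean gaze-relative PSE bias per modality, deg (1 decimal).

    ``fits`` is a DataFrame-like with columns ``modality``, ``gaze`` and
    ``mu`` (one PSE per modality x gaze, or several to be averaged).
    Left-gaze PSEs are negated before averaging so both gaze directions are
    expressed relative to gaze: positive = bias opposite gaze (the visual
    pattern), negative = bias toward gaze (the inertial pattern).

    Raises :class:`IncompleteDesignError` if a modality lacks one of the two
    gaze directions.
    """
    import pandas as pd

    df = pd.DataFrame(fits)
    out = {}
    for modality, grp in df.groupby("modality"):
        gazes = set(grp["gaze"])
        if gazes != {"left", "right"}:
            raise IncompleteDesignError(
                f"modality {modality!r} has gaze directions {sorted(gazes)}; "
                "both 'left' and 'right' are required"
            )
        signed = np.where(grp["gaze"] == "left", -grp["mu"], grp["mu"])
        per_gaze = (
            pd.Series(signed, index=grp.index).groupby(grp["gaze"]).mean()
        )
        out[modality] = round_half_away(float(per_gaze.mean()), 1)
    return out
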