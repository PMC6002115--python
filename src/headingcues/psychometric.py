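"""Maximum-likelihood cumulative-Gaussian psychometric fitting.

The model: on each trial a heading h (deg) is judged "right" with
probability p(h) = Phi((h - mu)/sigma), where mu is the point of subjective
equality (PSE; a nonzero mu is a perceptual bias) and sigma the
discrimination threshold.  Responses are independent Bernoulli draws, so the
exact log-likelihood over trials i with binary responses r_i is

    L(mu, sigma) = sum_i [ r_i*log p(h_i) + (1 - r_i)*log(1 - p(h_i)) ]

Trials at the same heading contribute through the sum, which weights each
heading by its presentation count automatically; grouping identical
headings is a pure speed optimization and never changes the value.

The API follows the model/results idiom: build a
:class:`HeadingPsychometric` model from trial data, call :meth:`fit` to get
a :class:`PsychometricResults` object holding the estimates, then
:meth:`~PsychometricResults.bootstrap` for percentile confidence intervals
from case-resampling at the trial level.  Maximization uses multi-start
Nelder-Mead on (mu, log sigma): random restarts with mu uniform over the
observed heading range and sigma log-uniform over [0.25, 50] deg, plus one
deterministic start at (median heading, interquartile range).  Adaptively
placed (staircase) trials are treated as independent Bernoulli trials, the
standard practice; the adaptive placement biases sigma-hat slightly
downward, which the recovery tests quantify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

from .exceptions import DegenerateDataError, UnidentifiableFitError

__all__ = [
    "HeadingPsychometric",
    "PsychometricResults",
    "negative_log_likelihood",
    "fit_ml",
    "bootstrap_fit",
    "FIT_COLUMNS",
]

#: Probability clip guarding log(0) at extreme parameter values.
P_CLIP = 1e-9
#: Sigma range (deg) for random starts and the grid oracle.
SIGMA_START_RANGE = (0.25, 50.0)

#: Fixed column order of fit-table CSVs.
FIT_COLUMNS = [
    "subject_id",
    "block_id",
    "modality",
    "vibration_amplitude",
    "gaze",
    "pooled_gaze",
    "mu",
    "mu_lo",
    "mu_hi",
    "sigma",
    "sigma_lo",
    "sigma_hi",
    "n_trials",
    "n_boot",
]


def _as_binary(responses) -> np.ndarray:
    arr = np.asarray(responses)
    if arr.dtype.kind in "UOS":
        out = np.where(arr == "right", 1, np.where(arr == "left", 0, -1))
        if (out < 0).any():
            bad = arr[out < 0][0]
            raise ValueError(f"responses must be 'left'/'right' or 0/1, got {bad!r}")
        return out.astype(np.int64)
    out = arr.astype(np.int64)
    if not np.isin(out, (0, 1)).all():
        raise ValueError("numeric responses must be 0 (left) or 1 (right)")
    return out


class HeadingPsychometric:
    """Cumulative-Gaussian psychometric model for binary heading judgments.

    Parameters
    ----------
    headings : array-like of float
        Stimulus headings in degrees (positive = rightward).
    responses : array-like
        Binary responses: "left"/"right" strings or 0/1 (1 = rightward).
    lapse : float, optional
        Fixed lapse rate; when nonzero the response probability becomes
        lapse/2 + (1 - lapse)*Phi((h - mu)/sigma).  Not fitted.  Default 0.
    """

    def __init__(self, headings, responses, lapse: float = 0.0):
        self.headings = np.asarray(headings, dtype=float)
        self.responses = _as_binary(responses)
        if self.headings.shape != self.responses.shape or self.headings.ndim != 1:
            raise ValueError("headings and responses must be equal-length 1-D arrays")
        if self.headings.size == 0:
            raise ValueError("no trials")
        if not (0 <= lapse < 0.5):
            raise ValueError(f"lapse must be in [0, 0.5), got {lapse}")
        self.lapse = lapse
        # Grouped sufficient statistics: unique headings, rightward counts, totals.
        self._h, inv = np.unique(self.headings, return_inverse=True)
        self._n = np.bincount(inv).astype(float)
        self._k = np.bincount(inv, weights=self.responses).astype(float)

    @classmethod
    def from_trials(cls, trials: Sequence, **kw) -> "HeadingPsychometric":
        """Build from a sequence of TrialRecord-like objects."""
        return cls([t.heading for t in trials], [t.response for t in trials], **kw)

    @classmethod
    def from_dataframe(
        cls, df, heading_col: str = "heading", response_col: str = "response", **kw
    ) -> "HeadingPsychometric":
        return cls(df[heading_col].to_numpy(), df[response_col].to_numpy(), **kw)

    @property
    def nobs(self) -> int:
        return self.headings.size

    def predict(self, mu: float, sigma: float, headings=None) -> np.ndarray:
        """P(right) at the given headings under (mu, sigma)."""
        h = self.headings if headings is None else np.asarray(headings, dtype=float)
        p = ndtr((h - mu) / sigma)
        return self.lapse / 2.0 + (1.0 - self.lapse) * p

    def nloglik(self, mu, sigma) -> float:
        """Exact Bernoulli negative log-likelihood at (mu, sigma).

        Vectorized over broadcastable mu/sigma arrays (used by the grid
        oracle in the test suite); probabilities are clipped to
        [1e-9, 1 - 1e-9] before the log.
        """
        mu = np.asarray(mu, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        if (np.asarray(sigma) <= 0).any():
            raise ValueError("sigma must be positive")
        z = (self._h - mu[..., None]) / sigma[..., None]
        p = self.lapse / 2.0 + (1.0 - self.lapse) * ndtr(z)
        p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
        nll = -(self._k * np.log(p) + (self._n - self._k) * np.log1p(-p)).sum(axis=-1)
        return float(nll) if nll.ndim == 0 else nll

    def _objective(self):
        """Fast scalar objective in (mu, log sigma) over grouped counts."""
        h, k = self._h, self._k
        nk = self._n - k
        lapse = self.lapse

        def f(x):
            sigma = np.exp(x[1])
            p = ndtr((h - x[0]) / sigma)
            if lapse:
                p = lapse / 2.0 + (1.0 - lapse) * p
            np.clip(p, P_CLIP, 1.0 - P_CLIP, out=p)
            return -(k * np.log(p) + nk * np.log1p(-p)).sum()

        return f

    def _check_identifiable(self) -> None:
        k = self._k.sum()
        if k == 0 or k == self._n.sum():
            raise UnidentifiableFitError(
                "all responses identical; sigma is unbounded and the fit is unidentifiable"
            )
        if self._h.size < 2:
            raise UnidentifiableFitError(
                "fewer than 2 distinct headings; mu and sigma are not jointly identifiable"
            )

    def _starts(self, n_starts: int, rng) -> list:
        h = self.headings
        lo, hi = float(h.min()), float(h.max())
        q25, q50, q75 = np.percentile(h, [25, 50, 75])
        starts = [(float(q50), max(float(q75 - q25), 1.0))]
        log_lo, log_hi = np.log(SIGMA_START_RANGE)
        for _ in range(max(n_starts - 1, 0)):
            starts.append(
                (float(rng.uniform(lo, hi)), float(np.exp(rng.uniform(log_lo, log_hi))))
            )
        return starts

    def fit(
        self,
        n_starts: int = 20,
        seed=None,
        extra_starts: Sequence = (),
        options: Optional[dict] = None,
    ) -> "PsychometricResults":
        """Maximize the likelihood by multi-start Nelder-Mead.

        Parameters
        ----------
        n_starts : int
            Total number of starts (one deterministic + n_starts-1 random).
        seed : int or numpy Generator, optional
            Seeds the random starts; the local searches are deterministic.
        extra_starts : sequence of (mu, sigma), optional
            Additional warm starts (used by the bootstrap to restart from
            the original MLE).
        options : dict, optional
            Nelder-Mead options override (the bootstrap uses a looser,
            faster profile; see :meth:`PsychometricResults.bootstrap`).

        Raises
        ------
        UnidentifiableFitError
            If all responses are identical or fewer than two distinct
            headings were presented.
        """
        self._check_identifiable()
        rng = np.random.default_rng(seed)
        best = None
        converged = False
        starts = list(extra_starts) + self._starts(n_starts, rng)
        objective = self._objective()
        nm_options = {"xatol": 1e-6, "fatol": 1e-9, "maxiter": 600}
        if options:
            nm_options.update(options)
        for mu0, sigma0 in starts:
            res = minimize(
                objective,
                x0=np.array([mu0, np.log(sigma0)]),
                method="Nelder-Mead",
                options=nm_options,
            )
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success)
        mu_hat = float(best.x[0])
        sigma_hat = float(np.exp(best.x[1]))
        return PsychometricResults(
            model=self,
            mu=mu_hat,
            sigma=sigma_hat,
            loglik=-float(best.fun),
            converged=converged,
            n_trials=self.nobs,
        )


@dataclass
class PsychometricResults:
    """Fitted PSE and threshold with optional bootstrap confidence intervals."""

    model: HeadingPsychometric
    mu: float
    sigma: float
    loglik: float
    converged: bool
    n_trials: int
    ci_mu: Optional[tuple] = None
    ci_sigma: Optional[tuple] = None
    n_boot: int = 0
    n_redrawn: int = 0
    boot_samples: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.mu, self.sigma])

    def predict(self, headings) -> np.ndarray:
        """Fitted P(right) at the given headings."""
        return self.model.predict(self.mu, self.sigma, headings)

    def bootstrap(
        self,
        n_boot: int = 2000,
        seed=None,
        n_starts: int = 1,
        ci_percentiles=(2.5, 97.5),
    ) -> np.ndarray:
        """Case-resampling bootstrap at the trial level.

        Resamples the trials with replacement ``n_boot`` times and refits
        each replicate.  Refits are warm-started at the original MLE (plus
        ``n_starts - 1`` random restarts if requested) with a slightly
        looser Nelder-Mead tolerance of 1e-4 on the parameters — far below
        the percentile-interval resolution.  Unidentifiable resamples are redrawn and counted
        in ``n_redrawn``; if identifiable resamples cannot be obtained within
        twice the budget (i.e. more than half fail), a
        :class:`DegenerateDataError` is raised.  Sets ``ci_mu``/``ci_sigma``
        to the percentile interval (default 2.5th-97.5th) and returns the
        (n_boot, 2) array of resampled (mu, sigma) pairs for downstream
        weight-CI propagation.  Deterministic under ``seed``.
        """
        rng = np.random.default_rng(seed)
        m = self.model
        n = m.nobs
        pairs = np.empty((n_boot, 2))
        got = 0
        attempts = 0
        max_attempts = 2 * n_boot
        while got < n_boot:
            if attempts >= max_attempts:
                raise DegenerateDataError(
                    f"only {got} of {n_boot} bootstrap resamples identifiable "
                    f"after {attempts} draws (> 50% degenerate)"
                )
            attempts += 1
            idx = rng.integers(0, n, n)
            rep = HeadingPsychometric(m.headings[idx], m.responses[idx], lapse=m.lapse)
            try:
                res = rep.fit(
                    n_starts=n_starts,
                    seed=rng,
                    extra_starts=[(self.mu, self.sigma)],
                    options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 300},
                )
            except UnidentifiableFitError:
                continue
            pairs[got] = (res.mu, res.sigma)
            got += 1
        self.n_redrawn = attempts - n_boot
        self.n_boot = n_boot
        lo, hi = ci_percentiles
        self.ci_mu = (
            float(np.percentile(pairs[:, 0], lo)),
            float(np.percentile(pairs[:, 0], hi)),
        )
        self.ci_sigma = (
            float(np.percentile(pairs[:, 1], lo)),
            float(np.percentile(pairs[:, 1], hi)),
        )
        self.boot_samples = pairs
        return pairs

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "Cumulative-Gaussian psychometric fit",
            "------------------------------------",
            f"n trials     : {self.n_trials}",
            f"log-lik      : {self.loglik:.4f}",
            f"converged    : {self.converged}",
            f"PSE mu       : {self.mu:8.3f} deg"
            + (
                f"   95% CI [{self.ci_mu[0]:.3f}, {self.ci_mu[1]:.3f}]"
                if self.ci_mu
                else ""
            ),
            f"sigma        : {self.sigma:8.3f} deg"
            + (
                f"   95% CI [{self.ci_sigma[0]:.3f}, {self.ci_sigma[1]:.3f}]"
                if self.ci_sigma
                else ""
            ),
        ]
        if self.n_boot:
            lines.append(f"bootstrap    : {self.n_boot} resamples ({self.n_redrawn} redrawn)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional front-ends over the model/results objects.


def negative_log_likelihood(mu: float, sigma: float, trials: Sequence) -> float:
    """Exact Bernoulli negative log-likelihood of (mu, sigma) on trial records."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    return HeadingPsychometric.from_trials(trials).nloglik(mu, sigma)


def fit_ml(trials: Sequence, n_starts: int = 20, seed=None) -> PsychometricResults:
    """Fit the psychometric function to trial records by multi-start ML."""
    return HeadingPsychometric.from_trials(trials).fit(n_starts=n_starts, seed=seed)


def bootstrap_fit(trials: Sequence, n_boot: int = 2000, seed=None, n_starts: int = 20):
    """Fit, then bootstrap trial-level resamples for percentile CIs.

    Returns ``(results, pairs)`` where ``results`` is the
    :class:`PsychometricResults` with CIs populated and ``pairs`` the
    (n_boot, 2) array of resampled (mu, sigma) estimates.
    """
    rng = np.random.default_rng(seed)
    res = HeadingPsychometric.from_trials(trials).fit(n_starts=n_starts, seed=rng)
    pairs = res.bootstrap(n_boot=n_boot, seed=rng)
    return res, pairs
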