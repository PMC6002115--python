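"""End-to-end orchestration of the in-silico heading experiment.

One experiment is, per subject, 9 trial blocks in subject-randomized order:

* 4 inertial-only blocks at vertical-vibration amplitudes 0, 0.10, 0.15,
  0.20 cm (peak-to-peak, 6 Hz);
* 4 combined visual-inertial blocks at the same amplitudes with 50%
  coherence visual motion;
* 1 visual-only block.

Each block runs four interleaved 20-trial staircases (80 trials), so a
subject contributes 720 trials.  ``run_experiment`` produces the trial log,
``analyze`` produces per-subject/condition/gaze psychometric fits, cue
weights per vibration amplitude, and group summaries (gaze-relative biases,
the visual-inertial PSE separation, mean weights).

Reproducibility: every random draw derives from the master seed through
``numpy.random.SeedSequence`` entropy tuples — block content from
(master, subject_index, block_index) with block_index indexing the
*canonical* block list, block order from (master, subject_index, 10000),
and the cohort from (master, 20000).  Any subject or block can therefore be
regenerated in isolation, and block order never affects block content.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import observer as obs_mod
from .exceptions import IncompleteDesignError
from .integration import (
    empirical_weights,
    gaze_bias_summary,
    optimal_weights,
    separation_statistic,
    weight_cis,
)
from .observer import ConditionSpec, ObserverParams
from .psychometric import FIT_COLUMNS, HeadingPsychometric
from .staircase import StaircaseConfig, records_to_dataframe, run_block

__all__ = [
    "ExperimentConfig",
    "canonical_blocks",
    "run_experiment",
    "analyze",
    "paired_t",
    "WEIGHT_COLUMNS",
]

logger = logging.getLogger("headingcues")

#: Fixed column order of weight-table CSVs.
WEIGHT_COLUMNS = [
    "subject_id",
    "vibration_amplitude",
    "w_I_opt",
    "w_I_opt_lo",
    "w_I_opt_hi",
    "w_I_emp",
    "w_I_emp_lo",
    "w_I_emp_hi",
    "out_of_range",
]

VIBRATION_AMPLITUDES = (0.0, 0.10, 0.15, 0.20)


@dataclass
class ExperimentConfig:
    """Full configuration of one simulated experiment."""

    n_subjects: int = 5
    cohort_ranges: Optional[dict] = None
    observers: Optional[Sequence[ObserverParams]] = None
    vibration_amplitudes: tuple = VIBRATION_AMPLITUDES
    coherence: float = 0.5
    staircase: StaircaseConfig = field(
        default_factory=lambda: StaircaseConfig(start_heading=50.0)
    )
    n_boot: int = 2000
    seed: int = 0
    out_dir: Optional[str] = None

    def resolve_cohort(self) -> list:
        """The cohort: explicit observers if given, else a seeded draw."""
        if self.observers is not None:
            return list(self.observers)
        cohort_seed = np.random.SeedSequence((self.seed, 20_000))
        return obs_mod.make_cohort(
            self.n_subjects, self.cohort_ranges, seed=cohort_seed
        )

    # -- flat YAML round trip ------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "experiment": {
                "n_subjects": self.n_subjects,
                "vibration_amplitudes": list(self.vibration_amplitudes),
                "coherence": self.coherence,
                "n_boot": self.n_boot,
                "seed": self.seed,
                "out_dir": self.out_dir,
            },
            "staircase": dataclasses.asdict(self.staircase),
            "cohort_ranges": self.cohort_ranges,
            "observers": (
                [dataclasses.asdict(o) for o in self.observers]
                if self.observers is not None
                else None
            ),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        exp = doc.get("experiment", {})
        sc = doc.get("staircase")
        # gaze/start are per-track and set by run_block; keep only block-level knobs
        if sc is not None:
            sc = StaircaseConfig(**sc)
        observers = doc.get("observers")
        if observers is not None:
            observers = [ObserverParams(**o) for o in observers]
        kw = dict(
            n_subjects=exp.get("n_subjects", 5),
            vibration_amplitudes=tuple(exp.get("vibration_amplitudes", VIBRATION_AMPLITUDES)),
            coherence=exp.get("coherence", 0.5),
            n_boot=exp.get("n_boot", 2000),
            seed=exp.get("seed", 0),
            out_dir=exp.get("out_dir"),
            cohort_ranges=doc.get("cohort_ranges"),
            observers=observers,
        )
        if sc is not None:
            kw["staircase"] = sc
        return cls(**kw)


def canonical_blocks(config: ExperimentConfig) -> list:
    """The 9 block conditions in canonical (pre-randomization) order."""
    blocks = []
    for amp in config.vibration_amplitudes:
        blocks.append(
            (f"inertial_v{amp:.2f}", ConditionSpec("inertial", amp, config.coherence))
        )
    for amp in config.vibration_amplitudes:
        blocks.append(
            (f"combined_v{amp:.2f}", ConditionSpec("combined", amp, config.coherence))
        )
    blocks.append(("visual", ConditionSpec("visual", 0.0, config.coherence)))
    return blocks


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Simulate the full experiment; returns the trial log as a DataFrame."""
    cohort = config.resolve_cohort()
    blocks = canonical_blocks(config)
    all_records = []
    for si, subject in enumerate(cohort):
        order_rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, si, 10_000))
        )
        order = order_rng.permutation(len(blocks))
        logger.info(
            "subject %s block order: %s", subject.subject_id,
            [blocks[j][0] for j in order],
        )
        for bj in order:
            block_id, condition = blocks[bj]
            block_seed = np.random.SeedSequence((config.seed, si, int(bj)))
            all_records.extend(
                run_block(
                    subject,
                    condition,
                    seed=block_seed,
                    staircase=config.staircase,
                    subject_id=subject.subject_id,
                    block_id=block_id,
                )
            )
    return records_to_dataframe(all_records)


def _fit_cell(df_cell: pd.DataFrame, n_boot: int, seed_seq, n_starts: int = 20):
    """Fit one subject x block x gaze cell; bootstrap if n_boot > 0."""
    model = HeadingPsychometric.from_dataframe(df_cell)
    res = model.fit(n_starts=n_starts, seed=np.random.default_rng(seed_seq))
    pairs = None
    if n_boot > 0:
        pairs = res.bootstrap(n_boot=n_boot, seed=np.random.default_rng(seed_seq.spawn(1)[0]))
    return res, pairs


def analyze(
    trials: pd.DataFrame,
    config: ExperimentConfig,
    n_boot: Optional[int] = None,
    pool_gaze: bool = False,
) -> dict:
    """Fit psychometric functions and compute cue weights and group summaries.

    Parameters
    ----------
    trials : DataFrame
        Trial log from :func:`run_experiment` (or real data in the same
        schema).
    config : ExperimentConfig
        Supplies n_boot default and the seed for bootstrap reproducibility.
    n_boot : int, optional
        Override the config's bootstrap count; 0 skips all CIs.
    pool_gaze : bool
        If True, additionally fit each block with the two gaze directions
        pooled (fits are per-gaze by default, since gaze shifts the PSE).

    Returns
    -------
    dict with keys ``fits`` (DataFrame), ``weights`` (DataFrame),
    ``summary`` (dict of group-level statistics).
    """
    n_boot = config.n_boot if n_boot is None else n_boot
    fit_rows = []
    boot_store: dict = {}
    point_store: dict = {}

    group_cols = ["subject_id", "block_id", "modality", "vibration_amplitude"]
    cells = sorted(trials.groupby(group_cols + ["gaze"]).groups)
    for ci, key in enumerate(cells):
        subject_id, block_id, modality, vib, gaze = key
        cell = trials.groupby(group_cols + ["gaze"]).get_group(key)
        seed_seq = np.random.SeedSequence((config.seed, 30_000, ci))
        res, pairs = _fit_cell(cell, n_boot, seed_seq)
        point_store[(subject_id, block_id, gaze)] = (res.mu, res.sigma)
        if pairs is not None:
            boot_store[(subject_id, block_id, gaze)] = pairs
        fit_rows.append(
            dict(
                subject_id=subject_id,
                block_id=block_id,
                modality=modality,
                vibration_amplitude=vib,
                gaze=gaze,
                pooled_gaze=False,
                mu=res.mu,
                mu_lo=res.ci_mu[0] if res.ci_mu else np.nan,
                mu_hi=res.ci_mu[1] if res.ci_mu else np.nan,
                sigma=res.sigma,
                sigma_lo=res.ci_sigma[0] if res.ci_sigma else np.nan,
                sigma_hi=res.ci_sigma[1] if res.ci_sigma else np.nan,
                n_trials=res.n_trials,
                n_boot=res.n_boot,
            )
        )
    if pool_gaze:
        pooled = sorted(trials.groupby(group_cols).groups)
        for ci, key in enumerate(pooled):
            subject_id, block_id, modality, vib = key
            cell = trials.groupby(group_cols).get_group(key)
            seed_seq = np.random.SeedSequence((config.seed, 40_000, ci))
            res, _ = _fit_cell(cell, n_boot, seed_seq)
            fit_rows.append(
                dict(
                    subject_id=subject_id,
                    block_id=block_id,
                    modality=modality,
                    vibration_amplitude=vib,
                    gaze="both",
                    pooled_gaze=True,
                    mu=res.mu,
                    mu_lo=res.ci_mu[0] if res.ci_mu else np.nan,
                    mu_hi=res.ci_mu[1] if res.ci_mu else np.nan,
                    sigma=res.sigma,
                    sigma_lo=res.ci_sigma[0] if res.ci_sigma else np.nan,
                    sigma_hi=res.ci_sigma[1] if res.ci_sigma else np.nan,
                    n_trials=res.n_trials,
                    n_boot=res.n_boot,
                )
            )
    fits = pd.DataFrame(fit_rows, columns=["subject_id", "block_id"] + FIT_COLUMNS[2:])

    weights = _compute_weights(fits, point_store, boot_store, config)
    summary = _summaries(fits, weights, trials)
    return {"fits": fits, "weights": weights, "summary": summary}


def _compute_weights(fits, point_store, boot_store, config) -> pd.DataFrame:
    """Per subject x vibration amplitude: optimal and empirical weights.

    Empirical weights are computed per gaze direction (where the unisensory
    PSEs are dissociated) and averaged over the two gazes; optimal weights
    use gaze-averaged sigmas.  Bootstrap CIs pair resamples by index within
    gaze and average the two per-gaze weight draws per index.
    """
    per_gaze = fits[~fits["pooled_gaze"]]
    rows = []
    for wi, ((subject_id, vib), _) in enumerate(
        sorted(per_gaze[per_gaze["modality"] == "combined"]
               .groupby(["subject_id", "vibration_amplitude"]).groups.items())
    ):
        vis_block = "visual"
        ine_block = f"inertial_v{vib:.2f}"
        com_block = f"combined_v{vib:.2f}"
        try:
            pts = {
                (blk, gz): point_store[(subject_id, blk, gz)]
                for blk in (vis_block, ine_block, com_block)
                for gz in ("left", "right")
            }
        except KeyError as exc:
            raise IncompleteDesignError(
                f"subject {subject_id}: missing fit for {exc.args[0]}; cannot "
                f"compute weights at vibration {vib}"
            ) from exc

        sigma_V = np.mean([pts[(vis_block, g)][1] for g in ("left", "right")])
        sigma_I = np.mean([pts[(ine_block, g)][1] for g in ("left", "right")])
        w_V_opt, w_I_opt = optimal_weights(sigma_V, sigma_I)

        emp = [
            empirical_weights(
                pts[(vis_block, g)][0], pts[(ine_block, g)][0], pts[(com_block, g)][0]
            )
            for g in ("left", "right")
        ]
        w_I_emp = float(np.mean([e.w_I for e in emp]))
        out_of_range = not (0.0 <= w_I_emp <= 1.0)

        ci_opt = ci_emp = (np.nan, np.nan)
        if boot_store:
            per_gaze_est = []
            for g in ("left", "right"):
                est = weight_cis(
                    boot_store[(subject_id, vis_block, g)],
                    boot_store[(subject_id, ine_block, g)],
                    boot_store[(subject_id, com_block, g)],
                    seed=np.random.SeedSequence((config.seed, 50_000, wi)),
                )
                per_gaze_est.append(est)
            # average the two gaze draws per resample index
            n = min(e.n_resamples for e in per_gaze_est)
            boots = []
            for g in ("left", "right"):
                bV = boot_store[(subject_id, vis_block, g)]
                bI = boot_store[(subject_id, ine_block, g)]
                bVI = boot_store[(subject_id, com_block, g)]
                w_emp_g = (bVI[:, 0] - bV[:, 0]) / (bI[:, 0] - bV[:, 0])
                w_opt_g = bV[:, 1] ** 2 / (bV[:, 1] ** 2 + bI[:, 1] ** 2)
                boots.append((w_emp_g, w_opt_g))
            w_emp_draws = 0.5 * (boots[0][0] + boots[1][0])
            w_opt_draws = 0.5 * (boots[0][1] + boots[1][1])
            keep = np.isfinite(w_emp_draws) & np.isfinite(w_opt_draws)
            ci_emp = (
                float(np.percentile(w_emp_draws[keep], 5)),
                float(np.percentile(w_emp_draws[keep], 95)),
            )
            ci_opt = (
                float(np.percentile(w_opt_draws[keep], 5)),
                float(np.percentile(w_opt_draws[keep], 95)),
            )
        rows.append(
            dict(
                subject_id=subject_id,
                vibration_amplitude=vib,
                w_I_opt=w_I_opt,
                w_I_opt_lo=ci_opt[0],
                w_I_opt_hi=ci_opt[1],
                w_I_emp=w_I_emp,
                w_I_emp_lo=ci_emp[0],
                w_I_emp_hi=ci_emp[1],
                out_of_range=out_of_range,
            )
        )
    return pd.DataFrame(rows, columns=WEIGHT_COLUMNS)


def _summaries(fits, weights, trials) -> dict:
    """Group-level statistics mirroring the report tables."""
    per_gaze = fits[~fits["pooled_gaze"]]
    summary: dict = {}

    # mean sigma per modality x vibration amplitude (averaged over gaze, subjects)
    sig = (
        per_gaze.groupby(["modality", "vibration_amplitude"])["sigma"].mean().round(6)
    )
    summary["mean_sigma"] = {f"{m}_v{v:.2f}": float(s) for (m, v), s in sig.items()}
    ine = per_gaze[per_gaze["modality"] == "inertial"]
    with_vib = ine[ine["vibration_amplitude"] > 0]["sigma"]
    no_vib = ine[ine["vibration_amplitude"] == 0]["sigma"]
    if len(no_vib):
        summary["mean_sigma_inertial_no_vibration"] = float(no_vib.mean())
    if len(with_vib):
        summary["mean_sigma_inertial_vibration"] = float(with_vib.mean())

    # gaze-relative biases per modality (averaged over subjects and amplitudes)
    bias_rows = per_gaze[["modality", "gaze", "mu"]]
    try:
        summary["gaze_bias"] = gaze_bias_summary(bias_rows)
    except IncompleteDesignError:
        summary["gaze_bias"] = None

    # visual-inertial separation from group-mean PSEs (no-vibration inertial)
    try:
        mu = (
            per_gaze.groupby(["modality", "vibration_amplitude", "gaze"])["mu"].mean()
        )
        summary["separation_deg"] = separation_statistic(
            mu_V_left=mu[("visual", 0.0, "left")],
            mu_V_right=mu[("visual", 0.0, "right")],
            mu_I_left=mu[("inertial", 0.0, "left")],
            mu_I_right=mu[("inertial", 0.0, "right")],
        )
    except KeyError:
        summary["separation_deg"] = None

    if len(weights):
        no_vib_w = weights[weights["vibration_amplitude"] == 0]
        vib_w = weights[weights["vibration_amplitude"] > 0]
        summary["mean_w_I_opt_no_vibration"] = (
            float(no_vib_w["w_I_opt"].mean()) if len(no_vib_w) else None
        )
        summary["mean_w_I_emp_no_vibration"] = (
            float(no_vib_w["w_I_emp"].mean()) if len(no_vib_w) else None
        )
        summary["mean_w_I_opt_vibration"] = (
            float(vib_w["w_I_opt"].mean()) if len(vib_w) else None
        )
        summary["mean_w_I_emp_vibration"] = (
            float(vib_w["w_I_emp"].mean()) if len(vib_w) else None
        )
    summary["n_trials"] = int(len(trials))
    summary["n_subjects"] = int(trials["subject_id"].nunique())
    return summary


def paired_t(values_a, values_b) -> tuple:
    """Classical paired t-test on per-subject paired measurements.

    Returns (t, two-sided p).  Zero-variance differences are handled
    explicitly: identical vectors give (0.0, 1.0); a constant nonzero
    difference gives (+/-inf, 0.0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, d[0]), 0.0
    from scipy.stats import ttest_rel

    t, p = ttest_rel(a, b)
    return float(t), float(p)
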