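"""Synthetic-cohort generator: parameters, behaviour, questionnaires.

Generates complete synthetic studies end-to-end so the whole pipeline runs
without any participant download: per-participant model parameters drawn
with the same non-centered scheme the fitting pipeline assumes (group mean +
group SD x standard-normal error on the sampling scale, then transformed),
BART behaviour simulated generatively from the four-parameter model in both
blocks, and questionnaire total scores tied to a designated parameter
through a Gaussian copula with a configurable latent correlation.

Default group-level values were calibrated once so that the simulated main
study reproduces the printed task behaviour (low-cost non-burst mean pumps
around 8.4 with between-participant spread around 2); see docs/methods.md.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm, pearsonr

from .model_family import (
    EPS_BELIEF,
    PARAM_NAMES,
    ParticipantParams,
    initial_state,
    optimal_pumps,
)
from .task_engine import BLOCKS, HC, LC, TaskConfig, TrialRecord, trials_to_frame

__all__ = [
    "CohortConfig",
    "QuestionnaireScores",
    "INSTRUMENT_RANGES",
    "phi_approx",
    "phi_approx_inv",
    "transform_params",
    "sample_participants",
    "simulate_participant",
    "simulate_block_matrix",
    "sample_questionnaires",
    "simulate_study",
    "StudyData",
]

#: published total-score ranges per instrument (CQ range set by config;
#: default assumes 24 items scored 0-4)
INSTRUMENT_RANGES = {
    "cq_total": (0, 96),
    "gad7_total": (0, 21),
    "stai_t_total": (20, 80),
    "pswq_total": (16, 80),
    "phq8_total": (0, 24),
}

# generation means/SDs for the questionnaire latents (total-score scale)
_INSTRUMENT_MOMENTS = {
    "cq_total": (40.0, 15.0),
    "gad7_total": (6.0, 4.5),
    "stai_t_total": (45.0, 10.0),
    "pswq_total": (48.0, 12.0),
    "phq8_total": (7.0, 5.0),
}


def phi_approx(x):
    """Logistic approximation to the standard-normal CDF.

    ``inv_logit(0.07056 x^3 + 1.5976 x)`` — the approximation used by the
    Stan ecosystem's ``Phi_approx`` — mapping the sampling scale to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    out = expit(0.07056 * x**3 + 1.5976 * x)
    return float(out) if out.ndim == 0 else out


def phi_approx_inv(p):
    """Numerical inverse of :func:`phi_approx` (monotone cubic + logistic)."""
    y = logit(np.asarray(p, dtype=float))
    # solve 0.07056 x^3 + 1.5976 x = y for each y (unique real root)
    y = np.atleast_1d(y)
    roots = np.empty_like(y)
    for i, yi in enumerate(y):
        r = np.roots([0.07056, 0.0, 1.5976, -yi])
        real = r[np.abs(r.imag) < 1e-9].real
        roots[i] = real[np.argmin(np.abs(real))] if real.size else np.nan
    return float(roots[0]) if roots.size == 1 else roots


def transform_params(raw: np.ndarray, phi: str = "approx") -> np.ndarray:
    """Sampling scale -> natural scale for the canonical parameter order.

    Learning rate through the (approximate or exact) Phi transform to
    [0, 1]; the other three parameters through ``exp`` to (0, inf).
    ``raw`` has shape (..., 4).
    """
    raw = np.clip(np.asarray(raw, dtype=float), -300.0, 300.0)  # overflow guard
    out = np.empty_like(raw)
    out[..., 0] = np.exp(raw[..., 0])
    if phi == "approx":
        out[..., 1] = phi_approx(raw[..., 1])
    elif phi == "exact":
        out[..., 1] = norm.cdf(raw[..., 1])
    else:
        raise ValueError("phi must be 'approx' or 'exact'")
    out[..., 2] = np.exp(raw[..., 2])
    out[..., 3] = np.exp(raw[..., 3])
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Design of one synthetic study.

    Group means and SDs are on the sampling (untransformed) scale of the
    non-centered scheme.  ``questionnaire_link`` sets the latent Pearson
    correlation between the CQ total and the designated parameter's raw
    value; the other questionnaires correlate with the CQ latent by
    ``secondary_link``.  ``block_effect`` optionally shifts group means
    (sampling scale) in one block, e.g. a lower risk-taking mean under the
    high burst penalty.
    """

    n_participants: int = 263
    group_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "prior_belief": -0.16,
            "learning_rate": -0.9,
            "risk_taking": -0.6,
            "inverse_temperature": 0.7,
        }
    )
    group_sds: Mapping[str, float] = field(
        default_factory=lambda: {
            "prior_belief": 0.12,
            "learning_rate": 0.6,
            "risk_taking": 0.4,
            "inverse_temperature": 0.3,
        }
    )
    questionnaire_link: Mapping[str, object] = field(
        default_factory=lambda: {"target_param": "risk_taking", "correlation": -0.3}
    )
    secondary_link: float = 0.5
    score_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(INSTRUMENT_RANGES)
    )
    block_effect: Mapping[str, Mapping[str, float]] | None = field(
        default_factory=lambda: {HC: {"risk_taking": -0.2}}
    )
    phi: str = "approx"
    evidence_window: str = "cumulative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        rho = float(self.questionnaire_link["correlation"])
        if not -1.0 <= rho <= 1.0:
            raise ValueError("questionnaire link correlation must lie in [-1, 1]")
        if self.questionnaire_link["target_param"] not in PARAM_NAMES:
            raise ValueError("unknown questionnaire target parameter")
        for p in PARAM_NAMES:
            if p not in self.group_means or p not in self.group_sds:
                raise ValueError(f"group moments missing for {p}")
            if self.group_sds[p] < 0:
                raise ValueError("group SDs must be non-negative")

    def mean_vector(self, block: str | None = None) -> np.ndarray:
        mu = np.array([self.group_means[p] for p in PARAM_NAMES], dtype=float)
        if block is not None and self.block_effect and block in self.block_effect:
            for p, shift in self.block_effect[block].items():
                mu[PARAM_NAMES.index(p)] += shift
        return mu

    def sd_vector(self) -> np.ndarray:
        return np.array([self.group_sds[p] for p in PARAM_NAMES], dtype=float)


@dataclass(frozen=True)
class QuestionnaireScores:
    """Total scores on the five self-report instruments."""

    participant_id: str
    cq_total: int
    gad7_total: int
    stai_t_total: int
    pswq_total: int
    phq8_total: int


def sample_participants(
    config: CohortConfig, block: str | None = None, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[ParticipantParams]]:
    """Draw per-participant parameters with the non-centered scheme.

    Returns the (N, 4) sampling-scale matrix (mean + sd * error) and the
    natural-scale :class:`ParticipantParams`.  Deterministic given the
    config seed (or an explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    mu = config.mean_vector(block)
    sd = config.sd_vector()
    errors = rng.standard_normal((config.n_participants, 4))
    raw = mu[None, :] + sd[None, :] * errors
    natural = transform_params(raw, config.phi)
    params = [
        ParticipantParams(*natural[i]) for i in range(config.n_participants)
    ]
    return raw, params


def simulate_block_matrix(
    natural: np.ndarray,
    thresholds: np.ndarray,
    rng: np.random.Generator,
    evidence_window: str = "cumulative",
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one block for a whole cohort (vectorized over participants).

    ``natural`` is (N, 4) natural-scale parameters; ``thresholds`` is
    (N, T).  Within a trial the agent pumps sequentially: at opportunity
    ``l`` it pumps with probability ``sigmoid(-beta (l - number_t))`` until
    it stops or reaches the threshold; the belief updates between trials.
    Returns ``(n_pumps, burst)`` arrays of shape (N, T).
    """
    natural = np.asarray(natural, dtype=float)
    thresholds = np.asarray(thresholds, dtype=int)
    N, T = thresholds.shape
    pb, lr, rt, beta = natural.T
    cp = np.zeros(N)
    cs = np.zeros(N)
    n_pumps = np.zeros((N, T), dtype=int)
    burst = np.zeros((N, T), dtype=bool)
    for t in range(T):
        p_belief = np.clip(
            1.0 - (pb + lr * cs) / (1.0 + lr * cp), EPS_BELIEF, 1.0 - EPS_BELIEF
        )
        number_t = -rt / np.log1p(-p_belief)
        K = thresholds[:, t]
        Kmax = int(K.max())
        opp = np.arange(1, Kmax + 1, dtype=float)
        p_pump = expit(-beta[:, None] * (opp[None, :] - number_t[:, None]))
        pump = rng.random((N, Kmax)) < p_pump
        declined = ~pump
        any_decline = declined.any(axis=1)
        first_decline = np.argmax(declined, axis=1)  # 0-based opportunity - 1
        n_raw = np.where(any_decline, first_decline, Kmax)
        b = n_raw >= K
        n = np.where(b, K, n_raw)
        n_pumps[:, t] = n
        burst[:, t] = b
        if evidence_window == "cumulative":
            cp += n
            cs += n - b.astype(int)
        elif evidence_window == "last_trial":
            cp = n.astype(float)
            cs = (n - b.astype(int)).astype(float)
        else:
            raise ValueError("evidence_window must be 'cumulative' or 'last_trial'")
    return n_pumps, burst


def simulate_participant(
    params: ParticipantParams,
    block_config: TaskConfig,
    seed: int = 0,
    block: str = LC,
    participant_id: str = "p0",
    thresholds: Sequence[int] | None = None,
    evidence_window: str = "cumulative",
) -> list[TrialRecord]:
    """Simulate one participant's block and return scored trial records."""
    rng = np.random.default_rng(seed)
    if thresholds is None:
        thr = block_config.participant_thresholds(seed)
    else:
        thr = np.asarray(thresholds, dtype=int)
    n, b = simulate_block_matrix(
        params.as_array()[None, :], thr[None, :], rng, evidence_window
    )
    records = []
    for t in range(thr.size):
        rec = TrialRecord(
            participant_id=participant_id,
            block=block,
            trial_index=t + 1,
            n_pumps=int(n[0, t]),
            burst=bool(b[0, t]),
            burst_threshold=int(thr[t]),
            points_earned=(
                -block_config.penalty(block)
                if b[0, t]
                else int(n[0, t]) * block_config.points_per_pump
            ),
        )
        rec.validate(block_config.points_per_pump)
        records.append(rec)
    return records


def sample_questionnaires(
    raw_target: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    participant_ids: Sequence[str] | None = None,
) -> list[QuestionnaireScores]:
    """Questionnaire totals with a latent link to the target parameter.

    A Gaussian copula on the sampling scale: the CQ latent is built with the
    configured correlation to the standardized raw target parameter, the
    other instruments correlate with the CQ latent by ``secondary_link``;
    totals are then rescaled, rounded and clipped to each instrument's
    range.  If discretization makes the achieved correlation miss the
    target by more than 0.1 a warning reports the achieved value.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    raw_target = np.asarray(raw_target, dtype=float)
    n = raw_target.size
    rho = float(config.questionnaire_link["correlation"])
    s = raw_target.std()
    if s < 1e-12:
        if rho != 0.0:
            warnings.warn(
                "target parameter has zero variance; questionnaire link unachievable"
            )
        z = np.zeros(n)
        rho = 0.0
    else:
        z = (raw_target - raw_target.mean()) / s
    z_cq = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    latents = {"cq_total": z_cq}
    for name in ("gad7_total", "stai_t_total", "pswq_total", "phq8_total"):
        r2 = config.secondary_link
        latents[name] = r2 * z_cq + np.sqrt(max(0.0, 1.0 - r2**2)) * rng.standard_normal(n)

    totals: dict[str, np.ndarray] = {}
    for name, lat in latents.items():
        mean, sd = _INSTRUMENT_MOMENTS[name]
        lo, hi = config.score_ranges[name]
        totals[name] = np.clip(np.round(mean + sd * lat), lo, hi).astype(int)

    if n >= 3 and rho != 0.0:
        achieved = pearsonr(raw_target, totals["cq_total"])[0]
        if abs(achieved - rho) > 0.1 and n >= 30:
            warnings.warn(
                f"questionnaire link after discretization: achieved r = "
                f"{achieved:.3f} vs target {rho:.3f}"
            )
    ids = (
        [f"p{i:03d}" for i in range(n)]
        if participant_ids is None
        else [str(p) for p in participant_ids]
    )
    return [
        QuestionnaireScores(
            ids[i],
            int(totals["cq_total"][i]),
            int(totals["gad7_total"][i]),
            int(totals["stai_t_total"][i]),
            int(totals["pswq_total"][i]),
            int(totals["phq8_total"][i]),
        )
        for i in range(n)
    ]


@dataclass
class StudyData:
    """One complete synthetic study, plus the generating ground truth."""

    trials: pd.DataFrame
    questionnaires: pd.DataFrame
    raw_params: dict[str, np.ndarray]  # block -> (N, 4) sampling-scale truth
    natural_params: dict[str, np.ndarray]
    cohort_config: CohortConfig
    task_config: TaskConfig

    def participant_ids(self) -> list[str]:
        return sorted(self.trials["participant_id"].unique())


def simulate_study(
    cohort: CohortConfig,
    task: TaskConfig | None = None,
    blocks: Sequence[str] = BLOCKS,
) -> StudyData:
    """Simulate a full study: both blocks plus questionnaires.

    The same participant-level error vector is used in every block (the
    person is the same person); ``block_effect`` shifts only group means.
    """
    if task is None:
        task = TaskConfig.preset("main", shuffle_seed=cohort.seed)
    N = cohort.n_participants
    ids = [f"p{i:03d}" for i in range(N)]
    rng_err = np.random.default_rng(np.random.SeedSequence([cohort.seed, 1]))
    errors = rng_err.standard_normal((N, 4))
    sd = cohort.sd_vector()

    raw_params: dict[str, np.ndarray] = {}
    natural_params: dict[str, np.ndarray] = {}
    all_records: list[TrialRecord] = []
    for b_i, block in enumerate(blocks):
        mu = cohort.mean_vector(block)
        raw = mu[None, :] + sd[None, :] * errors
        natural = transform_params(raw, cohort.phi)
        raw_params[block] = raw
        natural_params[block] = natural
        thresholds = np.stack(
            [task.participant_thresholds(1000 * b_i + i) for i in range(N)]
        )
        rng_beh = np.random.default_rng(np.random.SeedSequence([cohort.seed, 3, b_i]))
        n, burst = simulate_block_matrix(
            natural, thresholds, rng_beh, cohort.evidence_window
        )
        for i in range(N):
            for t in range(task.n_trials_per_block):
                all_records.append(
                    TrialRecord(
                        participant_id=ids[i],
                        block=block,
                        trial_index=t + 1,
                        n_pumps=int(n[i, t]),
                        burst=bool(burst[i, t]),
                        burst_threshold=int(thresholds[i, t]),
                        points_earned=(
                            -task.penalty(block)
                            if burst[i, t]
                            else int(n[i, t]) * task.points_per_pump
                        ),
                    )
                )

    target = str(cohort.questionnaire_link["target_param"])
    link_block = blocks[0]
    raw_target = raw_params[link_block][:, PARAM_NAMES.index(target)]
    scores = sample_questionnaires(raw_target, cohort, participant_ids=ids)
    qdf = pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "cq_total": s.cq_total,
                "gad7_total": s.gad7_total,
                "stai_t_total": s.stai_t_total,
                "pswq_total": s.pswq_total,
                "phq8_total": s.phq8_total,
            }
            for s in scores
        ]
    )
    return StudyData(
        trials=trials_to_frame(all_records),
        questionnaires=qdf,
        raw_params=raw_params,
        natural_params=natural_params,
        cohort_config=cohort,
        task_config=task,
    )


def write_study(study: StudyData, outdir: str | Path) -> dict[str, Path]:
    """Write trials CSV, questionnaires CSV and a provenance JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trials": outdir / "trials.csv",
        "questionnaires": outdir / "questionnaires.csv",
        "provenance": outdir / "provenance.json",
    }
    study.trials.to_csv(paths["trials"], index=False)
    study.questionnaires.to_csv(paths["questionnaires"], index=False)
    prov = {
        "seed": study.cohort_config.seed,
        "n_participants": study.cohort_config.n_participants,
        "group_means": dict(study.cohort_config.group_means),
        "group_sds": dict(study.cohort_config.group_sds),
        "questionnaire_link": dict(study.cohort_config.questionnaire_link),
        "task_config": study.task_config.to_dict(),
    }
    paths["provenance"].write_text(json.dumps(prov, indent=2))
    return paths
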