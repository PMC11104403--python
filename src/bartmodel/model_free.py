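"""Model-free statistical pipeline.

Summary measure: each participant's mean number of pumps per balloon over
the trials in which the balloon did *not* burst (burst trials truncate the
pump count at the hidden threshold, so they are excluded from the mean).

Skewed variables are square-root transformed before correlation: negative
skew uses ``sqrt(max(x) - x)`` — note this reverses the order, which the
transform label records so the sign of downstream correlations stays
interpretable — and positive skew uses ``sqrt(x + c)`` with ``c`` the
smallest scalar making all values non-negative.  Correlations are Pearson
with ``df = n - 2``; when a Shapiro-Wilk check on the residuals fails, a
rank-based (Spearman) fallback is used and recorded.

Mixed models (the cost-moderation contract and the trial-level
previous-burst post-hoc analysis) are ordinary linear mixed models with a
random intercept per participant, delegated to statsmodels MixedLM; the
interaction is reported as a Wald F with a residual-df approximation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "participant_summaries",
    "skew_transform",
    "correlate",
    "block_difference_analysis",
    "cost_moderation",
    "previous_burst_analysis",
    "analyze_study",
    "SKEW_THRESHOLD",
]

#: |sample skewness| beyond which the square-root transform is applied
SKEW_THRESHOLD = 0.5


def participant_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x block mean pumps on non-burst trials.

    Participants with zero non-burst trials in a block get ``NaN`` with
    ``n_nonburst_trials = 0`` (flagged, not silently dropped).
    """
    df = trials.copy()
    df["burst"] = df["burst"].astype(bool)
    grouped = df.groupby(["participant_id", "block"], sort=True)
    rows = []
    for (pid, block), sub in grouped:
        nb = sub[~sub["burst"]]
        rows.append(
            {
                "participant_id": str(pid),
                "block": block,
                "mean_pumps_nonburst": (
                    float(nb["n_pumps"].mean()) if len(nb) else np.nan
                ),
                "n_nonburst_trials": int(len(nb)),
            }
        )
    return pd.DataFrame(rows)


def skew_transform(
    x: Sequence[float], threshold: float = SKEW_THRESHOLD
) -> tuple[np.ndarray, dict]:
    """Square-root transform toward symmetry, with a bookkeeping label.

    Returns ``(y, label)`` where the label records the rule applied
    (``"identity"``, ``"sqrt_reflect"`` — order-reversing — or ``"sqrt"``),
    any scalar shift, and the input skewness.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    skew = float(stats.skew(x, bias=False)) if x.size > 2 and np.std(x) > 0 else 0.0
    if skew < -threshold:
        y = np.sqrt(np.max(x) - x)
        label = {
            "transform": "sqrt_reflect",
            "order_reversing": True,
            "shift": float(np.max(x)),
            "skewness": skew,
        }
    elif skew > threshold:
        c = float(max(0.0, -np.min(x)))
        y = np.sqrt(x + c)
        label = {
            "transform": "sqrt",
            "order_reversing": False,
            "shift": c,
            "skewness": skew,
        }
    else:
        y = x.copy()
        label = {
            "transform": "identity",
            "order_reversing": False,
            "shift": 0.0,
            "skewness": skew,
        }
    return y, label


def correlate(
    a: Sequence[float],
    b: Sequence[float],
    shapiro_alpha: float = 0.05,
) -> dict:
    """Correlation with df and two-sided p; Pearson unless residual
    diagnostics fail, in which case a Spearman fallback is recorded.

    Pairs with missing values are dropped (pairwise-complete).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("input vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("constant vector: correlation undefined")
    # residuals of the least-squares fit of b on a
    slope, intercept = np.polyfit(a, b, 1)
    resid = b - (slope * a + intercept)
    sw_p = float(stats.shapiro(resid)[1]) if 3 <= n <= 4999 else 1.0
    if sw_p >= shapiro_alpha:
        r, p = stats.pearsonr(a, b)
        method = "pearson"
    else:
        r, p = stats.spearmanr(a, b)
        method = "spearman"
    return {
        "r": float(r),
        "df": int(n - 2),
        "p": float(p),
        "method": method,
        "n": int(n),
        "shapiro_p": sw_p,
    }


def _merge_blocks(summaries: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    wide = summaries.pivot(
        index="participant_id", columns="block", values="mean_pumps_nonburst"
    ).reset_index()
    return wide.merge(
        scores[["participant_id", "cq_total"]], on="participant_id", how="inner"
    )


def block_correlations(
    summaries: pd.DataFrame, scores: pd.DataFrame
) -> dict[str, dict]:
    """Transformed mean pumps vs CQ totals, one correlation per block."""
    out = {}
    merged = summaries.merge(
        scores[["participant_id", "cq_total"]], on="participant_id"
    )
    for block, sub in merged.groupby("block"):
        sub = sub.dropna(subset=["mean_pumps_nonburst"])
        y, label = skew_transform(sub["mean_pumps_nonburst"].to_numpy())
        res = correlate(y, sub["cq_total"].to_numpy())
        res["pumps_transform"] = label
        out[str(block)] = res
    return out


def block_difference_analysis(
    summaries: pd.DataFrame, scores: pd.DataFrame
) -> dict:
    """Correlation of the transformed per-participant LC-HC pump difference
    with CQ totals, over participants present in both blocks."""
    wide = _merge_blocks(summaries, scores).dropna()
    if wide.empty or not {"LC", "HC"} <= set(wide.columns):
        raise ValueError("no participants with both blocks present")
    diff = (wide["LC"] - wide["HC"]).to_numpy()
    if np.std(diff) == 0:
        raise ValueError("zero-variance block difference: correlation undefined")
    y, label = skew_transform(diff)
    res = correlate(y, wide["cq_total"].to_numpy())
    res["difference_transform"] = label
    return res


def _wald_f(result, term: str, df_denom: int) -> dict:
    coef = float(result.params[term])
    se = float(result.bse[term])
    z = coef / se
    f = z**2
    p = float(stats.f.sf(f, 1, df_denom))
    return {
        "term": term,
        "coef": coef,
        "se": se,
        "F": float(f),
        "df_num": 1,
        "df_denom": int(df_denom),
        "p": p,
        "df_method": "residual-approximation (Wald)",
    }


def cost_moderation(
    summaries: pd.DataFrame,
    scores: pd.DataFrame,
    transform_pumps: bool = False,
) -> dict:
    """Is the burst cost a moderator of the pumps-catastrophizing relation?

    Linear mixed model on the per-participant block means:
    ``pumps ~ cq * cost`` with a random intercept per participant; the
    ``cost x CQ`` interaction is the moderation term.
    """
    merged = summaries.merge(
        scores[["participant_id", "cq_total"]], on="participant_id"
    ).dropna(subset=["mean_pumps_nonburst"])
    both = merged.groupby("participant_id")["block"].nunique()
    keep = both[both == 2].index
    merged = merged[merged["participant_id"].isin(keep)].copy()
    if merged["participant_id"].nunique() < 2:
        raise ValueError("need at least two participants with both blocks")
    y = merged["mean_pumps_nonburst"].to_numpy()
    label = {"transform": "identity"}
    if transform_pumps:
        y, label = skew_transform(y)
    merged["pumps"] = y
    merged["cost"] = (merged["block"] == "HC").astype(float)
    # centred CQ: main effects are then evaluated at the mean score
    merged["cq"] = merged["cq_total"].astype(float) - merged["cq_total"].mean()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("pumps ~ cq * cost", merged, groups=merged["participant_id"])
        result = model.fit(reml=True)
    n_obs = len(merged)
    df_denom = n_obs - 4 - merged["participant_id"].nunique() + 1
    report = _wald_f(result, "cq:cost", max(df_denom, 1))
    report["pumps_transform"] = label
    report["n_participants"] = int(merged["participant_id"].nunique())
    report["singular"] = bool(
        getattr(result, "converged", True) is False
        or np.isnan(result.cov_re.to_numpy()).any()
    )
    return report


def previous_burst_analysis(
    trials: pd.DataFrame, scores: pd.DataFrame
) -> dict[str, dict]:
    """Per-block trial-level mixed models of pumps on previous-burst x CQ.

    The first trial of each block has no previous outcome and is excluded;
    the random intercept absorbs between-participant pump differences.
    Reports main effects and the interaction per block.
    """
    df = trials.merge(scores[["participant_id", "cq_total"]], on="participant_id")
    df["burst"] = df["burst"].astype(bool)
    out = {}
    for block, sub in df.groupby("block"):
        sub = sub.sort_values(["participant_id", "trial_index"]).copy()
        sub["prev_burst"] = (
            sub.groupby("participant_id")["burst"].shift(1).astype(float)
        )
        sub = sub.dropna(subset=["prev_burst"])
        sub["cq"] = sub["cq_total"].astype(float) - sub["cq_total"].mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "n_pumps ~ prev_burst * cq", sub, groups=sub["participant_id"]
            )
            result = model.fit(reml=True)
        n_obs = len(sub)
        df_denom = max(n_obs - 4 - sub["participant_id"].nunique() + 1, 1)
        out[str(block)] = {
            "n_obs": int(n_obs),
            "prev_burst": _wald_f(result, "prev_burst", df_denom),
            "cq": _wald_f(result, "cq", df_denom),
            "interaction": _wald_f(result, "prev_burst:cq", df_denom),
        }
    return out


def analyze_study(
    trials: pd.DataFrame,
    scores: pd.DataFrame,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full model-free pipeline and optionally write the report.

    Produces the per-block CQ correlations, the block-difference
    correlation, the cost-moderation mixed model and the previous-burst
    post-hoc models, plus a tidy per-participant table suitable for
    external SEM tooling.
    """
    summaries = participant_summaries(trials)
    report: dict = {"block_correlations": block_correlations(summaries, scores)}
    try:
        report["block_difference"] = block_difference_analysis(summaries, scores)
    except ValueError as exc:
        report["block_difference"] = {"error": str(exc)}
    try:
        report["cost_moderation"] = cost_moderation(summaries, scores)
    except ValueError as exc:
        report["cost_moderation"] = {"error": str(exc)}
    report["previous_burst"] = previous_burst_analysis(trials, scores)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summaries.to_csv(outdir / "summaries.csv", index=False)
        tidy = summaries.pivot(
            index="participant_id", columns="block", values="mean_pumps_nonburst"
        ).reset_index().merge(scores, on="participant_id", how="left")
        tidy.to_csv(outdir / "participant_table.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
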