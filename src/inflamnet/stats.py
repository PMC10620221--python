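"""Condition comparisons for secretion and barrier-function readouts.

Implements the statistics applied to quantified cytokine concentrations and
trans-endothelial electrical resistance (TEER):

* normalization of each measurement to the mean of an on-plate control
  (LPS or media) within its analyte × experiment cell,
* log fold change of a condition's secretion profile against a baseline
  (conditioned-media) profile, exported in a pathway-tool-ready format,
* per-analyte Pearson correlation of secretion against the effector:target
  dose,
* a normality-gated group comparison: Shapiro–Wilk per group, one-way ANOVA
  with Tukey HSD post-hoc (Bonferroni-scaled across the analyte family) when
  every group passes, otherwise Kruskal–Wallis with Dunn post-hoc,
* TEER normalization to the media control.

Significance stars follow the conventional thresholds:
* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MissingControlError

logger = logging.getLogger(__name__)

ALPHA = 0.05
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    for cut, label in STAR_THRESHOLDS:
        if p < cut:
            return label
    return "ns"


def et_ratio_to_dose(ratio: str) -> float:
    """Numeric dose from an effector:target ratio string ('5:1' -> 5.0)."""
    eff, tgt = ratio.split(":")
    return float(eff) / float(tgt)


# ------------------------------------------------------------ normalization


def normalize_to_control(
    data: pd.DataFrame,
    control_condition: str,
    value_col: str = "concentration",
    condition_col: str = "condition",
    group_cols: tuple[str, ...] = ("analyte", "experiment"),
) -> pd.DataFrame:
    """Divide each value by the mean control value of its group.

    Each (analyte, experiment) cell must contain the control condition;
    control values map to mean 1 by construction.  Returns a copy with
    ``value_col`` replaced by the normalized value and the raw value kept as
    ``{value_col}_raw``.
    """
    df = data.copy()
    ctrl = df[df[condition_col] == control_condition]
    if ctrl.empty:
        raise MissingControlError(
            f"control condition {control_condition!r} absent from dataset"
        )
    group_cols = [c for c in group_cols if c in df.columns]
    means = ctrl.groupby(list(group_cols))[value_col].mean()
    orphans = set(map(tuple, df[group_cols].drop_duplicates().values)) - set(
        means.index if len(group_cols) > 1 else [(i,) for i in means.index]
    )
    if orphans:
        raise MissingControlError(
            f"no {control_condition!r} control for group(s): "
            f"{sorted(orphans)[:5]} (group columns {group_cols})"
        )
    keys = list(map(tuple, df[group_cols].values))
    denom = np.array([
        means[k if len(group_cols) > 1 else k[0]] for k in keys
    ], dtype=float)
    if (denom == 0).any():
        bad = {k for k, d in zip(keys, denom) if d == 0}
        raise MissingControlError(f"zero-mean control in group(s): {sorted(bad)[:5]}")
    df[f"{value_col}_raw"] = df[value_col]
    df[value_col] = df[value_col].to_numpy(dtype=float) / denom
    return df


def normalize_teer(
    resistances: pd.DataFrame,
    media_condition: str = "media",
    value_col: str = "resistance",
    condition_col: str = "condition",
    group_cols: tuple[str, ...] = ("experiment",),
) -> pd.DataFrame:
    """Normalize barrier resistance readings to the media control per experiment."""
    return normalize_to_control(
        resistances, media_condition,
        value_col=value_col, condition_col=condition_col, group_cols=group_cols,
    )


# ----------------------------------------------------------- fold changes


def default_pseudocount(values: np.ndarray) -> float:
    """Half the smallest nonzero value (0 when everything is zero)."""
    nz = values[values > 0]
    return float(nz.min()) / 2.0 if nz.size else 0.0


def log_fold_change(
    data: pd.DataFrame,
    baseline_condition: str,
    pseudocount: float | None = None,
    base: float = 2.0,
    value_col: str = "concentration",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Per-analyte log fold change of each condition against a baseline.

    LFC = log_base((mean_condition + eps) / (mean_baseline + eps)), with eps
    defaulting to half the smallest nonzero value in the dataset.  Returns a
    tidy frame (analyte, condition, lfc) covering every non-baseline
    condition.
    """
    df = data.copy()
    if baseline_condition not in set(df[condition_col]):
        raise MissingControlError(
            f"baseline condition {baseline_condition!r} absent from dataset"
        )
    values = df[value_col].to_numpy(dtype=float)
    eps = default_pseudocount(values) if pseudocount is None else float(pseudocount)
    means = df.groupby(["analyte", condition_col])[value_col].mean()
    rows = []
    conditions = sorted(c for c in df[condition_col].unique())
    for analyte in sorted(df["analyte"].unique()):
        if (analyte, baseline_condition) not in means.index:
            raise MissingControlError(
                f"baseline {baseline_condition!r} missing for analyte {analyte!r}"
            )
        base_mean = means[(analyte, baseline_condition)]
        if base_mean + eps == 0:
            raise ValueError(
                f"{analyte}: all-zero baseline with zero pseudocount; "
                "supply a positive pseudocount"
            )
        for cond in conditions:
            if cond == baseline_condition or (analyte, cond) not in means.index:
                continue
            lfc = math.log((means[(analyte, cond)] + eps) / (base_mean + eps), base)
            rows.append({"analyte": analyte, "condition": cond, "lfc": lfc})
    return pd.DataFrame(rows, columns=["analyte", "condition", "lfc"])


def export_lfc(lfc: pd.DataFrame, condition: str, path) -> None:
    """Write a two-column (analyte, LFC) table for pathway-analysis import."""
    sub = lfc[lfc["condition"] == condition][["analyte", "lfc"]]
    sub.to_csv(path, sep="\t", index=False, header=False)


# ------------------------------------------------------------ dose response


def dose_response_correlation(
    data: pd.DataFrame,
    dose_col: str = "dose",
    value_col: str = "concentration",
) -> pd.DataFrame:
    """Pearson correlation of concentration against numeric dose, per analyte.

    Requires at least three distinct doses.  Zero variance in either variable
    yields a flagged row (``undefined=True``) rather than NaN propagation.
    """
    rows = []
    for analyte, sub in data.groupby("analyte"):
        x = sub[dose_col].to_numpy(dtype=float)
        y = sub[value_col].to_numpy(dtype=float)
        if len(np.unique(x)) < 3:
            raise ValueError(
                f"{analyte}: dose-response correlation needs >=3 distinct doses"
            )
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"analyte": analyte, "r": np.nan, "p": np.nan,
                         "n": len(x), "undefined": True})
            continue
        r, p = sps.pearsonr(x, y)
        rows.append({"analyte": analyte, "r": float(r), "p": float(p),
                     "n": len(x), "undefined": False})
    return pd.DataFrame(rows).sort_values("analyte").reset_index(drop=True)


# -------------------------------------------------------- group comparison


@dataclass(frozen=True)
class StatResult:
    """One test outcome: omnibus or pairwise post-hoc."""

    analyte: str
    comparison: str
    test: str
    statistic: float
    p: float
    p_adjusted: float
    stars: str
    flagged: bool = False
    note: str = ""


def _dunn_test(groups: dict[str, np.ndarray]) -> list[tuple[str, str, float, float]]:
    """Dunn's post-hoc z-tests on pooled ranks with tie correction.

    Returns (g1, g2, z, two-sided p) per pair.  Implemented directly from the
    standard formulas (no post-hoc library ships Dunn in this environment):
    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tied value multiplicities t.
    """
    names = sorted(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        size = len(groups[g])
        mean_ranks[g] = float(ranks[start:start + size].mean())
        sizes[g] = size
        start += size
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_corr
    out = []
    for g1, g2 in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        if se == 0:
            out.append((g1, g2, 0.0, 1.0))
            continue
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append((g1, g2, float(z), float(p)))
    return out


def compare_groups(
    data: pd.DataFrame,
    group_col: str = "condition",
    value_col: str = "concentration",
    alpha: float = ALPHA,
    bonferroni_posthoc: bool = True,
) -> list[StatResult]:
    """Normality-gated multi-group comparison, per analyte.

    For each analyte: Shapiro–Wilk on every group; if all groups pass at
    ``alpha`` the parametric branch runs (one-way ANOVA, Tukey HSD post-hoc),
    otherwise the nonparametric branch (Kruskal–Wallis, Dunn post-hoc).
    Post-hoc p-values are additionally Bonferroni-scaled by the number of
    post-hoc comparisons in the analyte family (``min(1, m * p)``); set
    ``bonferroni_posthoc=False`` for plain Tukey/Dunn.  Groups that are
    entirely constant cannot be tested for normality and route the analyte to
    the nonparametric branch; an analyte with zero variance everywhere is
    returned flagged.
    """
    results: list[StatResult] = []
    for analyte in sorted(data["analyte"].unique()):
        sub = data[data["analyte"] == analyte]
        groups = {
            str(g): grp[value_col].to_numpy(dtype=float)
            for g, grp in sub.groupby(group_col)
        }
        if len(groups) < 2:
            raise ValueError(f"{analyte}: need >=2 groups")
        for g, v in groups.items():
            if len(v) < 3:
                raise ValueError(f"{analyte}/{g}: need >=3 observations per group")
        names = sorted(groups)
        if all(np.ptp(groups[g]) == 0 for g in names) and (
            len({groups[g][0] for g in names}) == 1
        ):
            results.append(StatResult(
                analyte, " vs ".join(names), "one-way ANOVA",
                float("nan"), 1.0, 1.0, "ns", flagged=True,
                note="zero variance in every group",
            ))
            continue

        normal = True
        for g in names:
            v = groups[g]
            if np.ptp(v) == 0:
                normal = False  # constant group: Shapiro undefined
                break
            if sps.shapiro(v).pvalue < alpha:
                normal = False
                break

        m = len(names) * (len(names) - 1) // 2
        scale = m if bonferroni_posthoc else 1

        if normal:
            stat, p = sps.f_oneway(*(groups[g] for g in names))
            results.append(StatResult(
                analyte, " vs ".join(names), "one-way ANOVA",
                float(stat), float(p), float(p), stars(p),
            ))
            tukey = sps.tukey_hsd(*(groups[g] for g in names))
            for i, j in itertools.combinations(range(len(names)), 2):
                praw = float(tukey.pvalue[i, j])
                padj = min(1.0, scale * praw)
                results.append(StatResult(
                    analyte, f"{names[i]} vs {names[j]}", "Tukey HSD",
                    float(tukey.statistic[i, j]), praw, padj, stars(padj),
                ))
        else:
            stat, p = sps.kruskal(*(groups[g] for g in names))
            results.append(StatResult(
                analyte, " vs ".join(names), "Kruskal-Wallis",
                float(stat), float(p), float(p), stars(p),
            ))
            for g1, g2, z, praw in _dunn_test(groups):
                padj = min(1.0, scale * praw)
                results.append(StatResult(
                    analyte, f"{g1} vs {g2}", "Dunn",
                    z, praw, padj, stars(padj),
                ))
    return results


def results_to_frame(results: list[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"analyte": r.analyte, "comparison": r.comparison, "test": r.test,
         "statistic": r.statistic, "p": r.p, "p_adjusted": r.p_adjusted,
         "stars": r.stars, "flagged": r.flagged, "note": r.note}
        for r in results
    ])
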