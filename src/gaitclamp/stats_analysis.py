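"""Pooled regressions, R-squared strength labels, and the 2x5 repeated-measures ANOVA.

Operates on the long-format trial summary table (one row per participant x
clamp type x intensity).  Associations are squared Pearson correlations with
OLS slope/intercept per clamp type; the "average" R^2 is the arithmetic mean
of the two clamp-specific values.  The two-way within-subject ANOVA (clamp
type x intensity) reports F, p, and partial eta squared per effect, with
Tukey post-hoc comparisons (studentized range on the effect's own error MS)
against the Norm condition and paired clamp contrasts at each intensity,
each with paired Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "AssociationResult",
    "EffectResult",
    "PairwiseResult",
    "AnovaResult",
    "association",
    "classify_r2",
    "rm_anova",
    "clamp_offset_percent",
    "speed_variability_check",
    "check_design",
]

ALPHA = 0.05

_R2_BINS = (
    (0.2, "very weak"),
    (0.4, "weak"),
    (0.6, "moderate"),
    (0.8, "strong"),
    (float("inf"), "very strong"),
)


@dataclass(frozen=True)
class AssociationResult:
    x_name: str
    y_name: str
    group: str  # clamp type, "pooled", or "average"
    r2: float
    p: float
    slope: float
    intercept: float
    n: int
    strength_label: str


@dataclass(frozen=True)
class PairwiseResult:
    label: str
    diff: float
    p: float
    cohens_d: float
    significant: bool


@dataclass(frozen=True)
class EffectResult:
    name: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ms_error: float
    posthoc: tuple[PairwiseResult, ...] = field(default=())


@dataclass(frozen=True)
class AnovaResult:
    dv: str
    clamp: EffectResult
    intensity: EffectResult
    interaction: EffectResult


def classify_r2(r2: float) -> str:
    """Strength label for a squared Pearson correlation.

    Boundary values go to the lower bin's upper label (0.8 -> "strong",
    0.2 -> "very weak").
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must be in [0, 1]")
    for upper, label in _R2_BINS:
        if r2 <= upper:
            return label
    raise AssertionError("unreachable")


def _fit(x: np.ndarray, y: np.ndarray, x_name: str, y_name: str, group: str) -> AssociationResult:
    if len(x) < 3:
        raise ValueError(f"need >= 3 paired observations in group '{group}'")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError(f"zero variance in {x_name} or {y_name} (group '{group}')")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    return AssociationResult(
        x_name=x_name, y_name=y_name, group=group, r2=r2, p=float(res.pvalue),
        slope=float(res.slope), intercept=float(res.intercept), n=len(x),
        strength_label=classify_r2(min(r2, 1.0)),
    )


def association(
    table: pd.DataFrame,
    x: str,
    y: str,
    grouping: str | None = "clamp_type",
) -> dict[str, AssociationResult]:
    """Per-clamp and clamp-averaged squared Pearson correlation of y on x.

    Returns a mapping of group name -> result, with an extra ``"average"``
    entry (mean of the group R^2 values, pooled n) when grouping is used,
    or a single ``"pooled"`` entry when ``grouping`` is None.
    """
    out: dict[str, AssociationResult] = {}
    if grouping is None:
        out["pooled"] = _fit(table[x].to_numpy(float), table[y].to_numpy(float), x, y, "pooled")
        return out
    for g, sub in table.groupby(grouping, sort=True):
        out[str(g)] = _fit(sub[x].to_numpy(float), sub[y].to_numpy(float), x, y, str(g))
    groups = [v for k, v in out.items()]
    mean_r2 = float(np.mean([v.r2 for v in groups]))
    out["average"] = AssociationResult(
        x_name=x, y_name=y, group="average", r2=mean_r2,
        p=float(max(v.p for v in groups)), slope=float(np.mean([v.slope for v in groups])),
        intercept=float(np.mean([v.intercept for v in groups])),
        n=int(sum(v.n for v in groups)), strength_label=classify_r2(min(mean_r2, 1.0)),
    )
    return out


def check_design(table: pd.DataFrame) -> None:
    """Require a complete, balanced participant x clamp x intensity design."""
    counts = table.groupby(["participant_id", "clamp_type", "intensity"]).size()
    if (counts != 1).any():
        bad = counts[counts != 1]
        raise ValueError(f"design not complete/balanced; offending cells:\n{bad}")
    n_cells = table.groupby(["clamp_type", "intensity"]).ngroups
    per_subject = table.groupby("participant_id").size()
    if (per_subject != n_cells).any():
        raise ValueError("missing cells for some participants")


def _tukey_vs_reference(
    wide: pd.DataFrame, ms_error: float, df_error: int, reference, k: int
) -> list[PairwiseResult]:
    """Tukey HSD of each level against a reference level on subject means.

    ``wide`` is subjects x levels.  q = |diff| / sqrt(MS_err / n) with the
    studentized range on (k, df_error); Cohen's d is the paired d.
    """
    n = wide.shape[0]
    se = np.sqrt(ms_error / n)
    out = []
    ref = wide[reference]
    for level in wide.columns:
        if level == reference:
            continue
        diff = wide[level] - ref
        q = abs(diff.mean()) / se if se > 0 else np.inf
        p = float(sps.studentized_range.sf(q, k, df_error))
        d = float(diff.mean() / diff.std(ddof=1)) if diff.std(ddof=1) > 0 else np.inf
        out.append(PairwiseResult(
            label=f"{level} vs {reference}", diff=float(diff.mean()), p=p,
            cohens_d=d, significant=p < ALPHA,
        ))
    return out


def _paired_contrasts(table: pd.DataFrame, dv: str) -> list[PairwiseResult]:
    """fp-clamp vs speed-clamp paired t-test at each intensity (k=2 family)."""
    out = []
    for inten, sub in table.groupby("intensity", sort=True):
        wide = sub.pivot(index="participant_id", columns="clamp_type", values=dv)
        diff = wide["fp"] - wide["speed"]
        t, p = sps.ttest_rel(wide["fp"], wide["speed"])
        d = float(diff.mean() / diff.std(ddof=1)) if diff.std(ddof=1) > 0 else np.inf
        out.append(PairwiseResult(
            label=f"fp vs speed @ {inten:+.0%}", diff=float(diff.mean()),
            p=float(p), cohens_d=d, significant=float(p) < ALPHA,
        ))
    return out


def rm_anova(table: pd.DataFrame, dv: str, alpha: float = ALPHA) -> AnovaResult:
    """Two-way repeated-measures ANOVA of ``dv`` on clamp type x intensity.

    Partial eta squared is computed as F*df1 / (F*df1 + df2), which equals
    SS_effect / (SS_effect + SS_error); post-hocs are attached only to
    significant effects.
    """
    check_design(table)
    aov = pg.rm_anova(
        data=table, dv=dv, within=["clamp_type", "intensity"],
        subject="participant_id", detailed=True,
    )
    effects = {}
    for _, row in aov.iterrows():
        f, df1, df2 = float(row["F"]), int(row["ddof1"]), int(row["ddof2"])
        np2 = f * df1 / (f * df1 + df2)
        ms_error = float(row["MS"]) / f if f > 0 else float("nan")
        effects[row["Source"]] = EffectResult(
            name=str(row["Source"]), F=f, df1=df1, df2=df2, p=float(row["p_unc"]),
            partial_eta_sq=float(np2), ss_effect=float(row["SS"]), ms_error=ms_error,
        )
    clamp = effects["clamp_type"]
    intensity = effects["intensity"]
    interaction = effects["clamp_type * intensity"]
    norm = 0.0
    if intensity.p < alpha:
        means = table.groupby(["participant_id", "intensity"])[dv].mean().unstack()
        ph = _tukey_vs_reference(means, intensity.ms_error, intensity.df2, norm,
                                 k=means.shape[1])
        intensity = EffectResult(**{**intensity.__dict__, "posthoc": tuple(ph)})
    if clamp.p < alpha or interaction.p < alpha:
        ph = _paired_contrasts(table, dv)
        clamp = EffectResult(**{**clamp.__dict__, "posthoc": tuple(ph)})
    return AnovaResult(dv=dv, clamp=clamp, intensity=intensity, interaction=interaction)


def clamp_offset_percent(table: pd.DataFrame, dv: str) -> float:
    """Grand-mean fp-clamp value relative to speed clamp, in percent.

    Mirrors the main-effect summary "the F_P clamp elicited X% higher ..."
    across all condition intensities.
    """
    m = table.groupby("clamp_type")[dv].mean()
    return float((m["fp"] / m["speed"] - 1.0) * 100.0)


def speed_variability_check(table: pd.DataFrame) -> dict[str, AssociationResult]:
    """Association of within-trial speed SD with net power and CoT (fp clamp)."""
    fp = table[table["clamp_type"] == "fp"]
    if fp.empty:
        raise ValueError("no fp-clamp trials in table")
    out = {}
    for dv in ("net_power", "cot"):
        out[dv] = _fit(
            fp["speed_sd_within"].to_numpy(float), fp[dv].to_numpy(float),
            "speed_sd_within", dv, "fp",
        )
    return out
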