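"""Mixed-design ANOVA with partial eta squared, and two-sample t-tests.

The designs supported are the split-plot layouts of a two-group
between-subjects factor (unequal n allowed) crossed with one or two
two-level within-subjects factors: 2x2 (group x picture) and 2x2x2
(group x picture x part of speech). With all within factors at two
levels, sphericity holds trivially and no correction is needed.

Sums of squares use the classical univariate decomposition with
subjects nested in group. The between-subjects effect is the one-way
ANOVA on subject means (its F equals the squared pooled t on those
means). Each within-subject effect family — a main effect or a pure
within interaction, together with its group interaction — lives in
the subspace of one per-subject contrast score and is tested against
its own factor-by-subject(group) error stratum with N - 2 df. Group
means are observation-weighted, which makes the full decomposition
exact: the stratum sums of squares add up to the total sum of squares
(see docs/methods.md for the unequal-n discussion).

Partial eta squared is SS_effect / (SS_effect + SS_error); for a
1-df effect this equals F / (F + df_error), the identity used to
recover effect sizes from printed F statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError, ValidationError


@dataclass(frozen=True)
class AnovaEffect:
    """One row of an ANOVA table, carrying its own error stratum."""

    name: str
    ss_effect: float
    df_effect: int
    ss_error: float
    df_error: int
    F: float
    p: float
    partial_eta_sq: float

    def format(self) -> str:
        if math.isnan(self.F):
            return f"{self.name}: F undefined (degenerate data)"
        p_txt = "< 0.001" if self.p < 0.001 else f"= {self.p:.3f}"
        return (
            f"{self.name}: F({self.df_effect},{self.df_error}) = {self.F:.3f}, "
            f"p {p_txt}, ηp² = {self.partial_eta_sq:.3f}"
        )


@dataclass(frozen=True)
class AnovaTable:
    """An ordered collection of ANOVA effects for one dependent measure."""

    dv: str
    effects: tuple[AnovaEffect, ...]

    def __getitem__(self, name: str) -> AnovaEffect:
        for effect in self.effects:
            if effect.name == name:
                return effect
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dv": self.dv,
                    "effect": e.name,
                    "ss_effect": e.ss_effect,
                    "df_effect": e.df_effect,
                    "ss_error": e.ss_error,
                    "df_error": e.df_error,
                    "F": e.F,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                }
                for e in self.effects
            ]
        )

    def report(self) -> str:
        lines = [f"ANOVA for {self.dv}:"]
        lines += [f"  {e.format()}" for e in self.effects]
        return "\n".join(lines)


def partial_eta_from_F(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValidationError(f"F must be >= 0, got {F}")
    if df1 <= 0 or df2 <= 0:
        raise ValidationError("degrees of freedom must be positive")
    return F * df1 / (F * df1 + df2)


def _effect_row(name: str, ss: float, ss_err: float, df_err: int) -> AnovaEffect:
    if ss_err <= 0:
        if ss <= 0:
            F = p = eta = math.nan
        else:
            F, p, eta = math.inf, 0.0, 1.0
    else:
        F = (ss / 1.0) / (ss_err / df_err)
        p = float(sps.f.sf(F, 1, df_err))
        eta = ss / (ss + ss_err)
    return AnovaEffect(
        name=name,
        ss_effect=ss,
        df_effect=1,
        ss_error=ss_err,
        df_error=df_err,
        F=F,
        p=p,
        partial_eta_sq=eta,
    )


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    between: str = "group",
    subject: str = "participant_id",
) -> AnovaTable:
    """Mixed-design ANOVA for one between and one or two within factors.

    ``data`` is long format: one row per subject x within-cell, with
    the dependent variable in column ``dv``. All factors must have
    exactly two levels and every subject must supply every within
    cell (incomplete subjects are named in the error).
    """
    within = list(within)
    if not 1 <= len(within) <= 2:
        raise DesignError("supported designs have one or two within factors")
    for col in [dv, between, subject, *within]:
        if col not in data.columns:
            raise DesignError(f"column {col!r} missing from data")
    if data[dv].isna().any():
        raise DesignError(f"dv {dv!r} contains missing values")

    levels = {f: sorted(data[f].unique()) for f in [between, *within]}
    for factor, lv in levels.items():
        if len(lv) != 2:
            raise DesignError(
                f"unsupported design: factor {factor!r} has {len(lv)} levels, need 2"
            )

    # one group per subject
    group_of = data.groupby(subject)[between].agg(lambda s: s.unique())
    for subj, gs in group_of.items():
        if len(gs) != 1:
            raise DesignError(f"subject {subj!r} appears in several groups")
    group_of = group_of.map(lambda g: g[0])

    # complete within-subject crossing, one observation per cell
    cells = list(product(*(levels[f] for f in within)))
    pivot = data.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="count", fill_value=0
    )
    for subj, row in pivot.iterrows():
        if not (row == 1).all():
            raise DesignError(
                f"subject {subj!r} has an incomplete or duplicated within-subject cell"
            )

    values = data.pivot_table(index=subject, columns=within, values=dv)
    if len(within) == 1:
        matrix = values[[c[0] for c in cells]].to_numpy(dtype=float)
    else:
        matrix = values[cells].to_numpy(dtype=float)
    subjects = values.index.to_numpy()
    groups = group_of.loc[subjects].to_numpy()
    n_cells = matrix.shape[1]
    n_subjects = matrix.shape[0]
    if n_subjects < 3:
        raise DesignError("need at least 3 subjects")
    df_error = n_subjects - 2

    group_levels = levels[between]
    masks = [groups == g for g in group_levels]
    n_per_group = [int(m.sum()) for m in masks]
    if min(n_per_group) < 2:
        raise DesignError("each group needs at least 2 subjects")

    def one_way_ss(scores: np.ndarray, scale: float) -> tuple[float, float, float]:
        """Weighted (grand mean, group, residual) SS of scores, scaled."""
        grand = scores.mean()
        ss_grand = len(scores) * grand**2
        ss_group = sum(
            m.sum() * (scores[m].mean() - grand) ** 2 for m in masks
        )
        ss_resid = sum(((scores[m] - scores[m].mean()) ** 2).sum() for m in masks)
        return scale * ss_grand, scale * ss_group, scale * ss_resid

    effects: list[AnovaEffect] = []

    # between-subjects stratum: subject means
    subject_means = matrix.mean(axis=1)
    _, ss_group, ss_subj = one_way_ss(subject_means, scale=float(n_cells))
    effects.append(_effect_row(between, ss_group, ss_subj, df_error))

    # within-subject strata: one contrast family per nonempty factor subset
    signs_by_factor = []
    for k, factor in enumerate(within):
        sign = np.array([1.0 if cell[k] == levels[factor][1] else -1.0 for cell in cells])
        signs_by_factor.append(sign)

    families: list[tuple[str, np.ndarray]] = []
    if len(within) == 1:
        families.append((within[0], signs_by_factor[0]))
    else:
        families.append((within[0], signs_by_factor[0]))
        families.append((within[1], signs_by_factor[1]))
        families.append(
            (f"{within[0]}:{within[1]}", signs_by_factor[0] * signs_by_factor[1])
        )

    for name, sign in families:
        weights = sign / (n_cells / 2.0)  # mean-difference contrast
        scores = matrix @ weights
        ss_main, ss_inter, ss_err = one_way_ss(scores, scale=n_cells / 4.0)
        effects.append(_effect_row(name, ss_main, ss_err, df_error))
        effects.append(_effect_row(f"{name}:{between}", ss_inter, ss_err, df_error))

    return AnovaTable(dv=dv, effects=tuple(effects))


@dataclass(frozen=True)
class TTestResult:
    """Independent two-sample t-test result."""

    t: float
    df: float
    p: float
    pooled: bool

    def format(self) -> str:
        if math.isnan(self.t):
            return "t undefined (zero variance, equal means)"
        p_txt = "< 0.001" if self.p < 0.001 else f"= {self.p:.3f}"
        return f"t({self.df:.3f}) = {self.t:.3f}, p {p_txt}"


def two_sample_t(
    x: Sequence[float], y: Sequence[float], pooled: bool = True
) -> TTestResult:
    """Independent-samples t-test, pooled or Welch (unequal-variance).

    Pooled df is n1 + n2 - 2; the Welch df follows Satterthwaite.
    Zero variance in both samples with equal means leaves the statistic
    undefined and is reported as missing (NaN), not as an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        df = len(x) + len(y) - 2 if pooled else math.nan
        if x.mean() == y.mean():
            return TTestResult(t=math.nan, df=df, p=math.nan, pooled=pooled)
        return TTestResult(t=math.inf if x.mean() > y.mean() else -math.inf,
                           df=df, p=0.0, pooled=pooled)
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue), pooled=pooled)


def melt_pos(
    frame: pd.DataFrame, kind: str, subject: str = "participant_id"
) -> pd.DataFrame:
    """Long-format noun/verb measure for the 2x2x2 ANOVA.

    ``kind`` is ``"token"`` or ``"type"``; returns columns
    [subject, group, picture_id, pos, value] with pos in
    {"noun", "verb"}.
    """
    if kind not in ("token", "type"):
        raise ValidationError("kind must be 'token' or 'type'")
    cols = {
        f"nouns_{kind}_per_utt": "noun",
        f"verbs_{kind}_per_utt": "verb",
    }
    out = frame.melt(
        id_vars=[subject, "group", "picture_id"],
        value_vars=list(cols),
        var_name="pos",
        value_name="value",
    )
    out["pos"] = out["pos"].map(cols)
    return out
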