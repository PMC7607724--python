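"""Repeated-measures statistics for the 2x2 Clarity x Ambiguity design.

Everything here reduces, by design, to contrast scores. For a 2x2
within-subject design each effect (two main effects and the interaction)
has one degree of freedom, so its F statistic equals the squared paired /
one-sample t statistic on the per-participant contrast scores:

    F = SS_effect / (SS_error / (n - 1)),   SS_effect = n * mean(s)^2,
    SS_error = sum((s_i - mean(s))^2),      partial eta^2 = SS_e/(SS_e+SS_err)

with s_i the participant's contrast score. Contrast coefficients use
level-mean differences, signed so that positive means "larger at low SNR"
(Clarity) and "larger for high-ambiguity sentences" (Ambiguity).

The pooled two-experiment design is a split-plot: Experiment is a
between-subjects factor tested against between-subject error, and each
within effect plus its Experiment crossing is tested via a two-parameter
regression of the contrast scores on an (intercept, effect-coded group)
design, giving df_den = N - 2 and Type III sums of squares that remain
correct with unequal group sizes.

No sphericity correction is applied anywhere: every within factor has two
levels, where sphericity holds trivially.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import CELL_LABELS, ConditionTable

__all__ = [
    "AnovaResult",
    "PartialCorrelationResult",
    "rmanova_2x2",
    "simple_effect",
    "pooled_mixed_anova",
    "effect_magnitude_contrast",
    "partial_correlation",
]

logger = logging.getLogger(__name__)

# contrast coefficients over (LA_high, HA_high, LA_low, HA_low):
# difference of level means; interaction = difference of ambiguity effects
# across clarity levels
_CONTRASTS = {
    "Clarity": {"LA_high": -0.5, "HA_high": -0.5,
                "LA_low": 0.5, "HA_low": 0.5},
    "Ambiguity": {"LA_high": -0.5, "HA_high": 0.5,
                  "LA_low": -0.5, "HA_low": 0.5},
    "Clarity x Ambiguity": {"LA_high": 1.0, "HA_high": -1.0,
                            "LA_low": -1.0, "HA_low": 1.0},
}


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float


@dataclass
class PartialCorrelationResult:
    r: float
    p: float
    df: int


def _check_table(values: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_LABELS if c not in values.columns]
    if missing:
        raise ValueError(f"condition table is missing cells: {missing}")
    values = values[list(CELL_LABELS)]
    if values.isna().any().any():
        bad = values[values.isna().any(axis=1)]
        pid = bad.index[0]
        cell = bad.columns[bad.loc[pid].isna()][0]
        raise ValueError(
            f"incomplete condition table: participant {pid!r} has no value "
            f"in cell {cell!r}")
    if len(values) < 2:
        raise ValueError(f"need at least 2 participants, have {len(values)}")
    return values


def _one_sample_f(scores: np.ndarray, effect: str) -> AnovaResult:
    """F(1, n-1) test of mean(scores) = 0, the paired-t-squared identity."""
    n = scores.size
    m = float(np.mean(scores))
    ss_effect = n * m * m
    ss_error = float(np.sum((scores - m) ** 2))
    df_den = n - 1
    if ss_error == 0.0:
        if ss_effect == 0.0:
            logger.warning("degenerate zero-variance, zero-mean contrast for "
                           "%s; reporting F=0, p=1", effect)
            return AnovaResult(effect, 0.0, 1, df_den, 1.0, 0.0)
        return AnovaResult(effect, math.inf, 1, df_den, 0.0, 1.0)
    F = ss_effect / (ss_error / df_den)
    p = float(sps.f.sf(F, 1, df_den))
    eta = ss_effect / (ss_effect + ss_error)
    return AnovaResult(effect, float(F), 1, df_den, p, float(eta))


def rmanova_2x2(table: ConditionTable) -> list[AnovaResult]:
    """2x2 repeated-measures ANOVA: Clarity, Ambiguity and their interaction.

    Each effect's F(1, n-1) is computed from per-participant contrast
    scores and equals the corresponding squared paired t statistic.
    Zero-variance degenerate tables report F=0, p=1 with a logged warning.
    """
    values = _check_table(table.values)
    out = []
    for effect, coef in _CONTRASTS.items():
        scores = sum(w * values[c].to_numpy() for c, w in coef.items())
        out.append(_one_sample_f(np.asarray(scores), effect))
    return out


def simple_effect(
    table: ConditionTable,
    fixed_factor: str,
    fixed_level: str,
    tested_factor: str,
) -> AnovaResult:
    """One-factor rmANOVA on the two cells at a fixed level of the other
    factor; F(1, n-1) equals the squared paired t on the cell difference.

    ``fixed_factor`` is 'clarity' or 'ambiguity'; ``fixed_level`` one of
    its levels ('high_snr'/'low_snr' or 'LA'/'HA').
    """
    values = _check_table(table.values)
    if fixed_factor == "clarity":
        suffix = "high" if fixed_level == "high_snr" else "low"
        hi, lo = f"HA_{suffix}", f"LA_{suffix}"  # tested: Ambiguity (HA-LA)
        label = f"Ambiguity @ {fixed_level}"
    elif fixed_factor == "ambiguity":
        hi, lo = f"{fixed_level}_low", f"{fixed_level}_high"  # Clarity
        label = f"Clarity @ {fixed_level}"
    else:
        raise ValueError(f"unknown factor {fixed_factor!r}")
    if tested_factor not in ("clarity", "ambiguity") or \
            tested_factor == fixed_factor:
        raise ValueError("tested_factor must be the non-fixed factor")
    scores = values[hi].to_numpy() - values[lo].to_numpy()
    return _one_sample_f(scores, label)


def _regression_f(y: np.ndarray, g: np.ndarray, effect_intercept: str,
                  effect_slope: str) -> tuple[AnovaResult, AnovaResult]:
    """OLS of y on (1, effect-coded group); F tests of each coefficient.

    With g coded +/-1/2 the intercept is the unweighted mean of group means
    (Type III), and each coefficient's squared t is an F(1, N-2).
    """
    n = y.size
    X = np.column_stack([np.ones(n), g])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    df = n - 2
    XtX_inv = np.linalg.inv(XtX)
    results = []
    for k, effect in ((0, effect_intercept), (1, effect_slope)):
        ss_hyp = beta[k] ** 2 / XtX_inv[k, k]
        if sse == 0.0:
            if ss_hyp == 0.0:
                logger.warning("degenerate zero-variance term for %s; "
                               "reporting F=0, p=1", effect)
                results.append(AnovaResult(effect, 0.0, 1, df, 1.0, 0.0))
            else:
                results.append(AnovaResult(effect, math.inf, 1, df, 0.0, 1.0))
            continue
        F = ss_hyp / (sse / df)
        p = float(sps.f.sf(F, 1, df))
        eta = ss_hyp / (ss_hyp + sse)
        results.append(AnovaResult(effect, float(F), 1, df, p, float(eta)))
    return results[0], results[1]


def pooled_mixed_anova(tables: list[ConditionTable]) -> list[AnovaResult]:
    """Split-plot ANOVA pooling two experiments (Experiment between-subjects).

    Returns seven effects: Experiment; Clarity, Ambiguity, Clarity x
    Ambiguity; and each within effect crossed with Experiment. All are
    F(1, N-2) where N is the pooled participant count.
    """
    if len(tables) != 2:
        raise ValueError(
            f"pooled design supports exactly 2 groups, got {len(tables)}")
    frames = []
    groups = []
    for gi, tab in enumerate(tables):
        v = _check_table(tab.values)
        frames.append(v)
        groups.append(np.full(len(v), -0.5 if gi == 0 else 0.5))
    values = pd.concat(frames, axis=0)
    g = np.concatenate(groups)
    if len(values) < 3:
        raise ValueError("pooled design needs at least 3 participants")

    out: list[AnovaResult] = []
    # between-subjects factor: test on per-participant means across cells
    subj_means = values.mean(axis=1).to_numpy()
    _, exp_res = _regression_f(subj_means, g, "(grand mean)", "Experiment")
    out.append(exp_res)
    # within effects and their Experiment crossings: contrast scores
    for effect, coef in _CONTRASTS.items():
        scores = np.asarray(
            sum(w * values[c].to_numpy() for c, w in coef.items()))
        main, inter = _regression_f(scores, g, effect,
                                    f"{effect} x Experiment")
        out.append(main)
        out.append(inter)
    return out


def effect_magnitude_contrast(
    tables: ConditionTable | list[ConditionTable],
    use_abs: bool = False,
) -> AnovaResult:
    """Test whether the Clarity effect exceeds the Ambiguity effect.

    Per participant, d_C = mean(low-SNR cells) - mean(high-SNR cells) and
    d_A = mean(HA cells) - mean(LA cells); the null mean(d_C - d_A) = 0 is
    tested by a one-sample F(1, n-1) (squared one-sample t). With
    ``use_abs``, absolute per-participant effects are compared instead.
    Multiple tables (e.g. two experiments) are pooled by concatenating
    participants.
    """
    if isinstance(tables, ConditionTable):
        tables = [tables]
    values = pd.concat([_check_table(t.values) for t in tables], axis=0)
    d_c = (values[["LA_low", "HA_low"]].mean(axis=1)
           - values[["LA_high", "HA_high"]].mean(axis=1)).to_numpy()
    d_a = (values[["HA_high", "HA_low"]].mean(axis=1)
           - values[["LA_high", "LA_low"]].mean(axis=1)).to_numpy()
    if use_abs:
        d_c, d_a = np.abs(d_c), np.abs(d_a)
    return _one_sample_f(d_c - d_a, "Clarity vs Ambiguity magnitude")


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariate: np.ndarray,
) -> PartialCorrelationResult:
    """Pearson correlation of x and y with one covariate partialed out.

    Both variables are residualized on (1, covariate) by least squares;
    the correlation of residuals is tested with t = r*sqrt(df/(1-r^2)),
    df = n - 3, two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    n = x.size
    if y.size != n or z.size != n:
        raise ValueError("x, y and covariate must have equal length")
    if n < 4:
        raise ValueError(f"need at least 4 observations, have {n}")
    if np.ptp(z) == 0:
        raise ValueError("constant covariate: use a plain correlation")
    X = np.column_stack([np.ones(n), z])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    r = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 3
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrelationResult(r=r, p=p, df=df)
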