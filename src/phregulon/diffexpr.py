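"""Moderated-t differential expression, dual-threshold selection and the
pH-response classifier.

The statistic is the empirical-Bayes moderated t: per-gene residual
variances :math:`s_g^2` (pooled two-sample, ``df = n_a + n_b - 2``) are
shrunk toward a prior variance :math:`s_0^2` with prior degrees of freedom
:math:`d_0`,

.. math:: \\tilde{s}_g^2 = \\frac{d_0 s_0^2 + df \\, s_g^2}{d_0 + df},

and the t-statistic :math:`\\tilde{t}_g = \\Delta_g / (\\tilde{s}_g
\\sqrt{1/n_a + 1/n_b})` is referred to a t distribution with
:math:`d_0 + df` degrees of freedom. The hyperparameters are estimated
across genes by a method-of-moments fit on :math:`\\log s_g^2`, using the
fact that marginally :math:`s_g^2 \\sim s_0^2 F_{df, d_0}` so that

.. math:: \\operatorname{Var}[\\log s_g^2] = \\psi'(df/2) + \\psi'(d_0/2),

with :math:`\\psi'` the trigamma function; :math:`d_0` is recovered by
inverting the trigamma and :math:`s_0^2` from the mean of the log
variances. A variance spread no wider than sampling noise implies
:math:`d_0 = \\infty`; every gene then uses :math:`s_0^2` with normal
p-values.

Selection applies the study's dual threshold — |log2 fold change| strictly
greater than 0.4 and p strictly below 0.01 — independently at each of the
two sampled time points, and calls a gene only when both time points pass
with a consistent sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

PH_CATEGORIES = ("high_up", "low_up", "peak", "dip", "flat")


@dataclass(frozen=True)
class Contrast:
    """A two-cell comparison at one time point.

    ``group_a`` and ``group_b`` are ``(strain, ph)`` cells; the effect is
    reported as ``mean_a - mean_b`` on the log2 scale.
    """

    name: str
    group_a: tuple
    group_b: tuple
    time_point: str

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise ValueError(f"contrast {self.name}: group_a equals group_b")


@dataclass(frozen=True)
class SelectionThresholds:
    """Dual selection thresholds; both inequalities are strict."""

    min_abs_log2fc: float = 0.4
    max_p: float = 0.01
    require_both_time_points: bool = True
    consistent_sign: bool = True

    def __post_init__(self):
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if not (0 < self.max_p <= 1):
            raise ValueError("max_p must be in (0, 1]")


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Returns ``inf`` for y <= 0 (no finite solution).
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    ``s2`` are per-gene residual variances with ``df`` degrees of freedom
    each. Genes with zero variance are excluded from the fit (log undefined)
    but still receive shrinkage downstream.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero; cannot fit prior")
    z = np.log(s2[ok])
    e = z - special.polygamma(0, df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    if len(e) < 2:
        return math.inf, float(np.exp(e_mean))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return math.inf, float(np.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(e_var)
    s0_2 = float(
        np.exp(e_mean + special.polygamma(0, d0 / 2.0) - math.log(d0 / 2.0))
    )
    return d0, s0_2


def moderated_t(
    log2fc: np.ndarray,
    s2: np.ndarray,
    df: float,
    stdev_unscaled: float,
    d0: float | None = None,
    s0_2: float | None = None,
) -> pd.DataFrame:
    """Shrink variances and compute moderated t with p-values.

    ``stdev_unscaled`` is sqrt(1/n_a + 1/n_b). Passing ``d0=0`` recovers the
    classical pooled t exactly. ``d0``/``s0_2`` default to the
    method-of-moments fit across genes.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if d0 is None or s0_2 is None:
        d0_fit, s0_fit = fit_variance_prior(s2, df)
        d0 = d0_fit if d0 is None else d0
        s0_2 = s0_fit if s0_2 is None else s0_2
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = math.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / (np.sqrt(s2_post) * stdev_unscaled)
    # identical groups with zero residual variance: no evidence either way
    t_mod = np.where((log2fc == 0) & ~np.isfinite(t_mod), 0.0, t_mod)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "s2": s2,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "p": p,
        }
    ).assign(df=df, df_total=df_total, d0=d0, s0_2=s0_2)


def _cell_columns(design: pd.DataFrame, cell: tuple, time_point) -> list:
    strain, ph = cell
    mask = (
        (design["strain"] == strain)
        & (np.isclose(design["ph"].astype(float), float(ph)))
        & (design["time_point"].astype(str) == str(time_point))
    )
    return design.loc[mask, "sample_id"].tolist()


def fit_contrast(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    contrast: Contrast,
    d0: float | None = None,
    s0_2: float | None = None,
) -> pd.DataFrame:
    """Fit a two-sample moderated-t contrast within one time point.

    Returns a per-gene frame (indexed by gene id) with columns ``log2fc,
    s2, s2_post, t_mod, p, q, df, df_total, d0, s0_2``; ``q`` is the
    Benjamini-Hochberg adjusted p, reported for transparency but unused by
    the selection rules.
    """
    cols_a = _cell_columns(design, contrast.group_a, contrast.time_point)
    cols_b = _cell_columns(design, contrast.group_b, contrast.time_point)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"contrast {contrast.name} at {contrast.time_point}: needs >=2 "
            f"replicates per cell (got {len(cols_a)} vs {len(cols_b)})"
        )
    if matrix.shape[0] == 0:
        raise ValueError("empty gene set")
    a = matrix[cols_a].to_numpy(dtype=float)
    b = matrix[cols_b].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    df = n_a + n_b - 2
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df
    if (s2 == 0).all():
        raise ValueError("zero residual variance in every gene (degenerate input)")
    stdev_unscaled = math.sqrt(1.0 / n_a + 1.0 / n_b)
    res = moderated_t(log2fc, s2, df, stdev_unscaled, d0=d0, s0_2=s0_2)
    res.index = matrix.index
    res.index.name = "gene_id"
    res["q"] = bh_adjust(res["p"].to_numpy())
    return res


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def select_de(
    results_t1: pd.DataFrame,
    results_t2: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.Series:
    """Dual-threshold selection across the two time points.

    Returns a per-gene categorical Series with values ``up_in_a``,
    ``up_in_b`` or ``not_de``. A gene is ``up_in_a`` iff at both time points
    log2fc > min_abs_log2fc (strict) and p < max_p (strict); ``up_in_b``
    symmetrically with log2fc < -min_abs_log2fc. With ``consistent_sign``
    (default) a gene significant with opposite signs at the two time points
    is ``not_de``.
    """
    if not results_t1.index.equals(results_t2.index):
        raise ValueError("gene universes differ between the two time points")
    thr = thresholds

    def _calls(res):
        sig = res["p"].to_numpy() < thr.max_p
        up = sig & (res["log2fc"].to_numpy() > thr.min_abs_log2fc)
        down = sig & (res["log2fc"].to_numpy() < -thr.min_abs_log2fc)
        return up, down

    up1, down1 = _calls(results_t1)
    up2, down2 = _calls(results_t2)
    if thr.require_both_time_points:
        up = up1 & up2
        down = down1 & down2
    else:
        up = up1 | up2
        down = down1 | down2
        if thr.consistent_sign:
            conflict = (up1 | up2) & (down1 | down2)
            up &= ~conflict
            down &= ~conflict
    decision = np.where(up, "up_in_a", np.where(down, "up_in_b", "not_de"))
    return pd.Series(decision, index=results_t1.index, name="decision")


def classify_ph_response(
    dec_6v3: pd.Series, dec_6v45: pd.Series, dec_45v3: pd.Series
) -> pd.Series:
    """Classify genes into pH-response categories from the three pH contrasts.

    Decisions are oriented higher-pH-vs-lower-pH (``up_in_a`` = up at the
    higher pH). Categories:

    * ``high_up`` — significant increase toward higher pH in at least one
      comparison and no significant decrease in any;
    * ``low_up`` — the mirror image;
    * ``peak`` — up in 4.5v3 and down in 6v4.5 (maximal at the middle pH);
    * ``dip`` — the reverse;
    * ``flat`` — no significant comparison, or irreconcilable patterns.

    A gene is pH-responsive iff its category is not ``flat``.
    """
    if not (dec_6v3.index.equals(dec_6v45.index) and dec_6v3.index.equals(dec_45v3.index)):
        raise ValueError("gene universes differ across the three pH comparisons")
    up = {
        "6v3": dec_6v3 == "up_in_a",
        "6v45": dec_6v45 == "up_in_a",
        "45v3": dec_45v3 == "up_in_a",
    }
    down = {
        "6v3": dec_6v3 == "up_in_b",
        "6v45": dec_6v45 == "up_in_b",
        "45v3": dec_45v3 == "up_in_b",
    }
    any_up = up["6v3"] | up["6v45"] | up["45v3"]
    any_down = down["6v3"] | down["6v45"] | down["45v3"]
    peak = up["45v3"] & down["6v45"]
    dip = down["45v3"] & up["6v45"]
    high_up = any_up & ~any_down
    low_up = any_down & ~any_up
    cat = np.select(
        [peak.to_numpy(), dip.to_numpy(), high_up.to_numpy(), low_up.to_numpy()],
        ["peak", "dip", "high_up", "low_up"],
        default="flat",
    )
    return pd.Series(cat, index=dec_6v3.index, name="ph_category")


def standard_ph_contrasts(parent: str, time_points) -> dict:
    """The study's pH contrast structure, oriented higher vs lower pH."""
    contrasts = {}
    for tp in time_points:
        contrasts[("6v3", tp)] = Contrast("6v3", (parent, 6.0), (parent, 3.0), tp)
        contrasts[("6v45", tp)] = Contrast("6v45", (parent, 6.0), (parent, 4.5), tp)
        contrasts[("45v3", tp)] = Contrast("45v3", (parent, 4.5), (parent, 3.0), tp)
    return contrasts


def run_ph_analysis(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    parent: str = "parent",
    deletion: str = "deletion",
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> dict:
    """Fit the full study contrast set and classify pH responses.

    Fits the three pH contrasts in the parent strain plus the
    deletion-vs-parent contrast at pH 6, each at both time points, applies
    dual-threshold selection, and classifies pH-response categories.

    Returns a dict with ``fits`` ((name, tp) -> frame), ``decisions``
    (name -> Series), ``ph_category`` (Series) and ``thresholds``.
    """
    time_points = sorted(design["time_point"].astype(str).unique())
    if len(time_points) != 2:
        raise ValueError(f"expected exactly 2 time points, got {time_points}")
    contrasts = standard_ph_contrasts(parent, time_points)
    for tp in time_points:
        contrasts[("del_v_parent_ph6", tp)] = Contrast(
            "del_v_parent_ph6", (deletion, 6.0), (parent, 6.0), tp
        )
    fits = {key: fit_contrast(matrix, design, c) for key, c in contrasts.items()}
    t1, t2 = time_points
    decisions = {
        name: select_de(fits[(name, t1)], fits[(name, t2)], thresholds)
        for name in ("6v3", "6v45", "45v3", "del_v_parent_ph6")
    }
    ph_category = classify_ph_response(
        decisions["6v3"], decisions["6v45"], decisions["45v3"]
    )
    return {
        "fits": fits,
        "decisions": decisions,
        "ph_category": ph_category,
        "thresholds": thresholds,
        "time_points": time_points,
    }
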