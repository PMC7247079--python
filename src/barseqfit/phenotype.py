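"""Per-strain fitness and survival estimation from relative-abundance time courses.

A strain's phenotype in a given cellular state is the slope of its
reference-normalized (log-scale) abundance against scaled time:

* fitness ``F_Pro`` — slope during the proliferative phase,
* survival ``S_Qui`` — the same slope during starvation-induced quiescence,
  when no cell division occurs.

Time is rescaled per phase to a common dimensionless unit (uncentered RMS
scaling with an ``n - 1`` denominator) so slopes from phases sampled on very
different spans (hours of growth vs. weeks of starvation) are comparable,
and so the quiescence-minus-proliferation contrast from a single ANCOVA
model is meaningful.

All replicates enter one ordinary-least-squares fit per strain as
independent observations. The fits are computed with closed-form
simple-regression algebra, vectorized over strains, which is what makes
genome-scale simulation studies cheap; the single-strain results agree
exactly with a general OLS solver.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "scale_times",
    "fit_phenotypes",
    "whole_course_fitness",
    "phase_difference",
    "classify_qs_genes",
]

PROLIFERATION = "proliferation"
QUIESCENCE = "quiescence"


def scale_times(times_h: np.ndarray | list[float]) -> np.ndarray:
    """Scale a phase's time points to a common dimensionless unit.

    Uncentered root-mean-square scaling: each time is divided by
    ``sqrt(sum(t_i^2) / (n - 1))``.  The scaled vector has RMS 1 (n-1
    convention), preserves ratios of raw times, and is invariant to
    multiplying all raw times by a positive constant.  For the canonical
    proliferative sampling grid (0, 9, 14, 18, 24) h this yields
    (0, 0.5246676, 0.8161497, 1.0493353, 1.3991137).

    Parameters
    ----------
    times_h
        Raw times within one phase, at least two points, not all zero.
    """
    t = np.asarray(times_h, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need a 1-D vector of at least two time points")
    denom = np.sqrt((t**2).sum() / (t.size - 1))
    if denom == 0:
        raise ValueError("all time points are zero; cannot scale")
    return t / denom


def _ols_slopes(Y: np.ndarray, x: np.ndarray) -> dict[str, np.ndarray]:
    """Closed-form simple OLS of each row of Y on x (with intercept).

    Returns slope, intercept, RSS, Sxx, residual dof per row.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if Y.shape[-1] != n:
        raise ValueError("observation count mismatch")
    xm = x.mean()
    xc = x - xm
    sxx = float((xc**2).sum())
    if sxx == 0:
        raise ValueError("zero variance in the time covariate")
    ym = Y.mean(axis=-1)
    slope = Y @ xc / sxx
    intercept = ym - slope * xm
    resid = Y - (intercept[..., None] + slope[..., None] * x)
    rss = (resid**2).sum(axis=-1)
    return {
        "slope": slope,
        "intercept": intercept,
        "rss": rss,
        "sxx": sxx,
        "dof": n - 2,
        "n": n,
        "yscale": np.abs(Y).max(axis=-1),
    }


def _finish_fit(parts: Mapping[str, np.ndarray]) -> pd.DataFrame:
    dof = parts["dof"]
    s2 = parts["rss"] / dof
    se = np.sqrt(s2 / parts["sxx"])
    # snap slopes indistinguishable from floating-point noise to exact zero
    # (a perfectly constant series must give f = 0, p = 1, not a spurious t)
    noise_floor = 1e-10 * (parts.get("yscale", 0.0) + 1.0)
    slope = np.where(np.abs(parts["slope"]) < noise_floor, 0.0, parts["slope"])
    parts = {**parts, "slope": slope}
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, parts["slope"] / se, np.inf * np.sign(parts["slope"]))
        tstat = np.where(parts["slope"] == 0, 0.0, tstat)
    p = 2 * stats.t.sf(np.abs(tstat), dof)
    halfwidth = stats.t.ppf(0.975, dof) * se
    return pd.DataFrame(
        {
            "slope": parts["slope"],
            "se": se,
            "n": parts["n"],
            "ci_lo": parts["slope"] - halfwidth,
            "ci_hi": parts["slope"] + halfwidth,
            "t": tstat,
            "p": p,
            "residual_sd": np.sqrt(s2),
        }
    )


def _phase_design(samples: pd.DataFrame, phase: str,
                  condition: str | None, library: str | None) -> pd.DataFrame:
    sel = samples["phase"] == phase
    if condition is not None:
        sel &= samples["condition"] == condition
    if library is not None:
        sel &= samples["library"] == library
    sub = samples.loc[sel]
    if sub.empty:
        raise ValueError(f"no samples for phase={phase!r}")
    return sub


def fit_phenotypes(
    rel: pd.DataFrame,
    samples: pd.DataFrame,
    phase: str,
    condition: str | None = None,
    library: str | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Fit per-strain slopes of relative abundance on scaled time.

    Parameters
    ----------
    rel
        Reference-normalized abundance, strains x samples (log-difference
        scale; see :mod:`barseqfit.normalize`).
    samples
        Sample sheet indexed by sample id with at least ``time_h`` and
        ``phase`` columns (``condition`` / ``library`` if filtering).
    phase
        ``"proliferation"`` or ``"quiescence"``; only that phase's samples
        enter the fit.  Scaled time is computed from the phase's unique
        time points and mapped onto replicate observations.
    adjust
        Add a ``p_adj`` column (Benjamini-Hochberg across strains).

    Returns
    -------
    DataFrame indexed by strain: slope, se, n, ci_lo, ci_hi, t, p,
    residual_sd (and p_adj).
    """
    sub = _phase_design(samples, phase, condition, library)
    uniq = np.sort(sub["time_h"].unique())
    if uniq.size < 2:
        raise ValueError("need at least two distinct time points per phase")
    scaled = dict(zip(uniq, scale_times(uniq)))
    x = sub["time_h"].map(scaled).to_numpy(dtype=float)
    Y = rel.loc[:, sub.index].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least three observations")
    out = _finish_fit(_ols_slopes(Y, x))
    out.index = rel.index
    out.index.name = "strain"
    out["phase"] = phase
    if condition is not None:
        out["condition"] = condition
    if library is not None:
        out["library"] = library
    if adjust:
        out["p_adj"] = adjust_bh(out["p"].to_numpy())
    return out


def whole_course_fitness(
    rel: pd.DataFrame,
    samples: pd.DataFrame,
    condition: str | None = None,
    library: str | None = None,
) -> pd.DataFrame:
    """Fitness over the entire culturing period, time measured in raw days.

    Used for full-cycle mutant profiles spanning both growth and
    starvation; time is *not* RMS-scaled here, so the slope has units of
    change in log2 relative abundance per day.
    """
    sel = np.ones(len(samples), dtype=bool)
    if condition is not None:
        sel &= (samples["condition"] == condition).to_numpy()
    if library is not None:
        sel &= (samples["library"] == library).to_numpy()
    sub = samples.loc[sel]
    x = sub["time_h"].to_numpy(dtype=float) / 24.0
    Y = rel.loc[:, sub.index].to_numpy(dtype=float)
    out = _finish_fit(_ols_slopes(Y, x))
    out.index = rel.index
    out.index.name = "strain"
    return out


def ancova_slope_contrast(
    Y1: np.ndarray, x1: np.ndarray, Y2: np.ndarray, x2: np.ndarray
) -> pd.DataFrame:
    """Interaction coefficient of the two-group ANCOVA, vectorized.

    Fits ``y ~ x * group`` for each row pair (Y1[i], Y2[i]).  Because the
    model is saturated in the group factor, the interaction coefficient
    equals the difference of the two separately fitted slopes
    (group2 - group1); its standard error uses the pooled residual
    variance with ``n1 + n2 - 4`` degrees of freedom.  This is the exact
    OLS result, not an approximation.
    """
    f1 = _ols_slopes(np.atleast_2d(Y1), x1)
    f2 = _ols_slopes(np.atleast_2d(Y2), x2)
    n1, n2 = x1.size, x2.size
    dof = n1 + n2 - 4
    if dof < 1:
        raise ValueError("too few observations for the two-group model")
    diff = f2["slope"] - f1["slope"]
    s2 = (f1["rss"] + f2["rss"]) / dof
    se = np.sqrt(s2 * (1.0 / f1["sxx"] + 1.0 / f2["sxx"]))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, diff / se, 0.0)
    p = 2 * stats.t.sf(np.abs(tstat), dof)
    halfwidth = stats.t.ppf(0.975, dof) * se
    return pd.DataFrame(
        {
            "diff": diff,
            "se": se,
            "dof": dof,
            "t": tstat,
            "p": p,
            "ci_lo": diff - halfwidth,
            "ci_hi": diff + halfwidth,
            "slope1": f1["slope"],
            "slope2": f2["slope"],
        }
    )


def phase_difference(
    rel: pd.DataFrame,
    samples: pd.DataFrame,
    condition: str | None = None,
    library: str | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Quiescence-minus-proliferation contrast (S_Qui - F_Pro) per strain.

    One ANCOVA per strain with scaled time, growth stage, and their
    interaction; the interaction coefficient estimates the survival
    slope minus the fitness slope and its t-test gives the phenotypic
    difference p-value, BH-adjusted across strains.
    """
    sub_p = _phase_design(samples, PROLIFERATION, condition, library)
    sub_q = _phase_design(samples, QUIESCENCE, condition, library)

    def scaled_x(sub: pd.DataFrame) -> np.ndarray:
        uniq = np.sort(sub["time_h"].unique())
        return sub["time_h"].map(dict(zip(uniq, scale_times(uniq)))).to_numpy(float)

    x_p, x_q = scaled_x(sub_p), scaled_x(sub_q)
    if x_p.size < 3 or x_q.size < 3:
        raise ValueError("need at least three observations per phase")
    Yp = rel.loc[:, sub_p.index].to_numpy(dtype=float)
    Yq = rel.loc[:, sub_q.index].to_numpy(dtype=float)
    out = ancova_slope_contrast(Yp, x_p, Yq, x_q)
    out = out.rename(
        columns={"diff": "delta", "slope1": "slope_pro", "slope2": "slope_qui"}
    )
    out.index = rel.index
    out.index.name = "strain"
    if adjust:
        out["p_adj"] = adjust_bh(out["p"].to_numpy())
    return out


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def classify_qs_genes(
    fits_by_condition: Mapping[str, Mapping[str, pd.DataFrame]],
    alpha: float = 0.05,
    strict_positive_fitness: bool = False,
) -> dict[str, object]:
    """Classify quiescence-specific (QS) genes per condition and in common.

    A gene is QS in a condition when it is (i) dispensable for
    proliferation, (ii) required for survival of starvation
    (``S_Qui < 0``, significant), and (iii) its survival is significantly
    worse than its fitness (``S_Qui - F_Pro < 0``, significant).

    Parameters
    ----------
    fits_by_condition
        ``{condition: {"fitness": df, "survival": df, "difference": df}}``
        where each df is indexed by strain with ``slope`` (``delta`` for
        the difference) and ``p_adj`` columns.
    strict_positive_fitness
        If True, criterion (i) demands a significantly positive fitness
        estimate; the default reads "dispensable" as *not significantly
        deleterious* (estimate >= 0, or a negative estimate that is not
        significant).

    Returns
    -------
    dict with ``per_condition`` (condition -> set of strains) and
    ``common`` (intersection over conditions, restricted to strains
    scored in every condition).
    """
    per_condition: dict[str, set] = {}
    scored_everywhere: set | None = None
    for cond, tables in fits_by_condition.items():
        fit = tables["fitness"]
        sur = tables["survival"]
        dif = tables["difference"]
        idx = fit.index.intersection(sur.index).intersection(dif.index)
        fit, sur, dif = fit.loc[idx], sur.loc[idx], dif.loc[idx]
        if strict_positive_fitness:
            crit_i = (fit["slope"] >= 0) & (fit["p_adj"] < alpha)
        else:
            crit_i = (fit["slope"] >= 0) | (fit["p_adj"] >= alpha)
        crit_ii = (sur["slope"] < 0) & (sur["p_adj"] < alpha)
        crit_iii = (dif["delta"] < 0) & (dif["p_adj"] < alpha)
        qs = set(idx[crit_i & crit_ii & crit_iii])
        per_condition[cond] = qs
        scored = set(idx)
        scored_everywhere = (
            scored if scored_everywhere is None else scored_everywhere & scored
        )
    common = set.intersection(*per_condition.values()) if per_condition else set()
    if scored_everywhere is not None:
        common &= scored_everywhere
    return {"per_condition": per_condition, "common": common}
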