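"""Genetic interaction scoring: ANCOVA slope contrast and multiplicative epsilon.

Two estimators of the interaction between an array gene *a* and the
query kinase *q*, computed separately per cellular state (fitness in
proliferation, survival in quiescence) and per nutrient condition.

**ANCOVA (GIS).**  Both libraries are normalized by their own reference
(the HO library by the wild-type control, the query library by the query
single mutant), which absorbs the query's global effect.  One model over
both genotypes, ``F_normed ~ T * GT``, then gives the interaction as the
time-by-genotype coefficient, which equals the difference of the two
separately fitted slopes: ``GIS = f_aq - f_a``.  Its t-test provides the
significance, BH-adjusted across array genes.

**Multiplicative (epsilon).**  The classic null model expects the double
mutant's multiplicative fitness to be the product of the singles'.  The
fitted log-scale coefficients are exponentiated to put positive and
negative phenotypes on a common multiplicative scale:

    f_aq_exp = exp(f_a) * exp(f_q)
    epsilon  = exp(f_aq) - f_aq_exp

The standard error of the expectation propagates the single-mutant
errors, ``S_{a+q}^2 = S_a^2 + S_q^2``, and the observed-vs-expected
contrast is tested with a Welch t statistic whose degrees of freedom
come from the Welch-Satterthwaite approximation.  The Welch numerator is
epsilon itself (observed minus expected, both on the exponentiated
scale); a ``literal`` mode retains the scale-mixing contrast
``f_aq - f_aq_exp`` for comparison.  When the query's single-mutant fit
is unavailable (as happens when a query barcode cannot be recovered from
the single-mutant library), multiplicative scores are reported as
missing rather than imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .phenotype import adjust_bh, ancova_slope_contrast, fit_phenotypes, scale_times

__all__ = [
    "gis_ancova",
    "gis_multiplicative",
    "adjust_fdr",
    "call_interactions",
    "interaction_profile",
]

adjust_fdr = adjust_bh


def _scaled_covariate(samples: pd.DataFrame, phase: str, condition: str | None,
                      library: str) -> tuple[pd.Index, np.ndarray]:
    sel = (samples["phase"] == phase) & (samples["library"] == library)
    if condition is not None:
        sel &= samples["condition"] == condition
    sub = samples.loc[sel]
    if sub.empty:
        raise ValueError(f"no samples for library {library!r}, phase {phase!r}")
    uniq = np.sort(sub["time_h"].unique())
    x = sub["time_h"].map(dict(zip(uniq, scale_times(uniq)))).to_numpy(float)
    return sub.index, x


def gis_ancova(
    rel_double: pd.DataFrame,
    rel_single: pd.DataFrame,
    samples: pd.DataFrame,
    phase: str,
    query: str,
    condition: str | None = None,
    single_library: str = "HO",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """ANCOVA genetic interaction scores for one query/condition/state.

    Parameters
    ----------
    rel_double, rel_single
        Reference-normalized abundance (strains x samples) for the
        double-mutant library and the single-mutant (HO) library, each
        normalized by its own reference strain.
    samples
        Combined sample sheet covering both libraries.
    phase
        Cellular state: ``"proliferation"`` or ``"quiescence"``.

    Returns
    -------
    DataFrame indexed by array gene with columns ``gis`` (= f_aq - f_a
    per unit scaled time), ``se``, ``dof``, ``t``, ``p``, ``q``,
    ``f_aq``, ``f_a`` and ``call``.
    """
    cols_d, x_d = _scaled_covariate(samples, phase, condition, query)
    cols_s, x_s = _scaled_covariate(samples, phase, condition, single_library)
    genes = rel_double.index.intersection(rel_single.index)
    genes = genes.drop([g for g in (query, "REF") if g in genes])
    if len(genes) == 0:
        raise ValueError("no common array genes between libraries")
    Yd = rel_double.loc[genes, cols_d].to_numpy(float)
    Ys = rel_single.loc[genes, cols_s].to_numpy(float)
    res = ancova_slope_contrast(Ys, x_s, Yd, x_d)
    out = pd.DataFrame(
        {
            "gis": res["diff"].to_numpy(),
            "se": res["se"].to_numpy(),
            "dof": res["dof"].to_numpy(),
            "t": res["t"].to_numpy(),
            "p": res["p"].to_numpy(),
            "f_aq": res["slope2"].to_numpy(),
            "f_a": res["slope1"].to_numpy(),
        },
        index=genes,
    )
    out.index.name = "gene"
    out["q"] = adjust_fdr(out["p"].to_numpy())
    out["call"] = call_interactions(out["gis"], out["q"], fdr)
    out.attrs.update({"query": query, "condition": condition, "phase": phase})
    return out


def welch_satterthwaite_df(
    s_aq: np.ndarray, n_aq: float, s_sum: np.ndarray, n_sum: float
) -> np.ndarray:
    """Welch-Satterthwaite approximate degrees of freedom."""
    v_aq = s_aq**2 / n_aq
    v_sum = s_sum**2 / n_sum
    num = (v_aq + v_sum) ** 2
    den = v_aq**2 / (n_aq - 1) + v_sum**2 / (n_sum - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def gis_multiplicative(
    fits_double: pd.DataFrame,
    fits_single: pd.DataFrame,
    query: str,
    welch_numerator: str = "epsilon",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Multiplicative-model interaction scores from three sets of fits.

    Parameters
    ----------
    fits_double
        Per-strain fits from the double-mutant library normalized by the
        query (columns ``slope``, ``se``, ``n``), i.e. f_aq.
    fits_single
        Per-strain fits from the single-mutant library normalized by the
        control, supplying f_a for every array gene and f_q for the
        query's own row.
    query
        Strain id of the query gene within ``fits_single``.  If absent,
        all multiplicative fields are returned as NaN (scores are
        impossible without the query's single-mutant phenotype).
    welch_numerator
        ``"epsilon"`` (default) or ``"literal"`` (f_aq - f_aq_exp as
        printed in classic SGA practice, mixing scales).
    """
    genes = fits_double.index.intersection(fits_single.index)
    genes = genes.drop([g for g in (query, "REF") if g in genes])
    out = pd.DataFrame(
        index=genes,
        columns=["epsilon", "f_exp", "se_sum", "welch_t", "welch_df", "p", "q"],
        dtype=float,
    )
    out.index.name = "gene"
    if query not in fits_single.index:
        out["call"] = "none"
        out.attrs["query_missing"] = True
        return out

    f_aq = fits_double.loc[genes, "slope"].to_numpy(float)
    s_aq = fits_double.loc[genes, "se"].to_numpy(float)
    n_aq = float(fits_double.loc[genes, "n"].iloc[0])
    f_a = fits_single.loc[genes, "slope"].to_numpy(float)
    s_a = fits_single.loc[genes, "se"].to_numpy(float)
    n_a = float(fits_single.loc[genes, "n"].iloc[0])
    f_q = float(fits_single.at[query, "slope"])
    s_q = float(fits_single.at[query, "se"])
    n_q = float(fits_single.at[query, "n"])

    f_exp = np.exp(f_a) * np.exp(f_q)
    eps = np.exp(f_aq) - f_exp
    s_sum = np.sqrt(s_a**2 + s_q**2)
    n_sum = min(n_a, n_q)

    if welch_numerator == "epsilon":
        num = eps
    elif welch_numerator == "literal":
        num = f_aq - f_exp
    else:
        raise ValueError(f"unknown welch_numerator {welch_numerator!r}")
    denom = np.sqrt(s_aq**2 / n_aq + s_sum**2 / n_sum)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(denom > 0, num / denom, np.nan)
    df = welch_satterthwaite_df(s_aq, n_aq, s_sum, n_sum)
    p = 2 * stats.t.sf(np.abs(tstat), df)

    out["epsilon"] = eps
    out["f_exp"] = f_exp
    out["se_sum"] = s_sum
    out["welch_t"] = tstat
    out["welch_df"] = df
    out["p"] = p
    out["q"] = adjust_fdr(p)
    out["call"] = call_interactions(out["epsilon"], out["q"], fdr)
    out.attrs.update({"query": query, "n_aq": n_aq, "n_sum": n_sum})
    return out


def call_interactions(score: pd.Series, q: pd.Series, fdr: float = 0.05) -> pd.Series:
    """Label each gene positive / negative / none at the given FDR."""
    call = pd.Series("none", index=score.index)
    sig = q < fdr
    call[sig & (score > 0)] = "positive"
    call[sig & (score < 0)] = "negative"
    return call


def interaction_profile(
    results: pd.DataFrame,
    score_column: str = "gis",
    genes: pd.Index | None = None,
) -> pd.Series:
    """Ordered per-gene score vector for one query/condition/state.

    When ``genes`` is given, the profile is aligned to that order with
    missing genes recorded as NaN (absent, not zero).
    """
    if len(results.index) < 2:
        raise ValueError("need scores for at least two array genes")
    prof = results[score_column].copy()
    if genes is not None:
        prof = prof.reindex(genes)
    prof.name = tuple(
        results.attrs.get(k) for k in ("query", "condition", "phase")
    ) if results.attrs else score_column
    return prof
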