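"""Variance stabilization and reference-strain normalization.

Raw Bar-seq counts have a variance that grows with the mean, and every
sample has its own sequencing depth.  Counts are therefore put on a
log2-like scale after median-of-ratios depth correction:

    value[i, s] = log2(count[i, s] / size_factor[s] + pseudocount)

For counts well above the pseudocount, differences of values approximate
log2 fold-changes, which is the scale on which abundance trajectories
are linear in time and on which regression slopes can be exponentiated
into multiplicative fitness.

Relative abundance divides out everything shared by the pool by
referencing each strain against the library's control at every sample:
the wild-type-like control strain in the single-mutant (HO) library, the
query single mutant in a double-mutant library.  In the default
log-difference mode this is a subtraction on the transformed scale, so
the result is invariant to any per-sample additive shift (hence to
size-factor rescaling in the large-count limit); a literal-ratio mode is
kept for sensitivity analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["size_factors", "vst", "relative_abundance", "pool_reference"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors, geometric mean 1.

    ``factor_s = median_i(count[i, s] / gm_i)`` over strains *i* with no
    zero count anywhere, where ``gm_i`` is the strain's geometric mean
    across samples.  If no strain is zero-free, the ratios fall back to
    each strain's positive entries (with a warning).
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[0] == 0 or mat.shape[1] == 0:
        raise ValueError("empty counts table")
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    zero_free = np.isfinite(logs).all(axis=1)
    if zero_free.any():
        loggeo = logs[zero_free].mean(axis=1)
        logratios = logs[zero_free] - loggeo[:, None]
        factors = np.exp(np.nanmedian(logratios, axis=0))
    else:
        warnings.warn(
            "no strain has nonzero counts in every sample; "
            "computing size factors over positive entries only",
            stacklevel=2,
        )
        loggeo = np.array(
            [row[np.isfinite(row)].mean() if np.isfinite(row).any() else np.nan
             for row in logs]
        )
        logratios = np.ma.masked_invalid(logs - loggeo[:, None])
        med = np.ma.median(logratios, axis=0)
        factors = np.exp(np.ma.filled(med, 0.0))
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def vst(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Depth-corrected log2 transform: ``log2(count / factor + pseudocount)``.

    Strictly monotone in the raw count within a sample; zero counts map
    to the finite value ``log2(pseudocount)``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.columns)
    if (factors <= 0).any() or factors.isna().any():
        raise ValueError("size factors must be strictly positive for every sample")
    return np.log2(counts.div(factors, axis=1) + pseudocount)


def relative_abundance(
    values: pd.DataFrame,
    reference_strain: str,
    mode: str = "log_difference",
) -> pd.DataFrame:
    """Normalize every strain's series by the library reference strain.

    In ``log_difference`` mode (default) the reference row is subtracted
    from every row, so the reference's own series is identically 0 and
    the result is shift-invariant per sample.  ``literal_ratio`` divides
    the transformed values instead (reference series identically 1).
    """
    if reference_strain not in values.index:
        raise KeyError(f"reference strain {reference_strain!r} not in table")
    ref = values.loc[reference_strain]
    bad = ref.isna()
    if bad.any():
        warnings.warn(
            f"reference missing in {int(bad.sum())} sample(s); excluded",
            stacklevel=2,
        )
        values = values.loc[:, ~bad]
        ref = ref[~bad]
    if mode == "log_difference":
        return values.sub(ref, axis=1)
    if mode == "literal_ratio":
        if (ref == 0).any():
            raise ZeroDivisionError("reference value is 0 in literal_ratio mode")
        return values.div(ref, axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def pool_reference(
    counts: pd.DataFrame, control_strains: list[str], name: str = "REF"
) -> pd.DataFrame:
    """Sum several control-colony count rows into one reference strain.

    Replicated control colonies carry distinct barcodes; their counts are
    summed at the counts level (before transformation) and re-inserted
    under ``name``.
    """
    missing = [s for s in control_strains if s not in counts.index]
    if missing:
        raise KeyError(f"control strains not in table: {missing}")
    pooled = counts.loc[control_strains].sum(axis=0)
    out = counts.drop(index=control_strains)
    out.loc[name] = pooled
    return out
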