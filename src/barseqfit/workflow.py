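"""End-to-end orchestration of the simulate -> count -> score pipeline.

Thin compositions of the per-stage modules, used by the command-line
interface, the acceptance script, and calibration tests.  Nothing here
adds statistical behavior of its own.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import interactions, normalize, phenotype
from .barcode_counts import CountsTable, filter_and_merge
from .phenotype import PROLIFERATION
from .simdata import REFERENCE_STRAIN, SimTruth, TimeCourseDesign, simulate_counts

__all__ = ["library_relative_abundance", "score_interaction_library", "simulate_and_score"]


def library_relative_abundance(
    merged: pd.DataFrame,
    samples: pd.DataFrame,
    library: str,
    condition: str | None = None,
    reference_strain: str = REFERENCE_STRAIN,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference-normalized abundance for one library (x condition).

    Size factors and the variance-stabilizing transform are computed
    within the library's own samples, then every strain is normalized by
    the library reference.  Returns (rel, sample subset).
    """
    sel = samples["library"] == library
    if condition is not None:
        sel &= samples["condition"] == condition
    sub = samples.loc[sel]
    counts = merged.loc[:, sub.index]
    values = normalize.vst(counts, pseudocount=pseudocount)
    rel = normalize.relative_abundance(values, reference_strain)
    return rel, sub


def score_interaction_library(
    counts: CountsTable,
    query: str,
    condition: str,
    phase: str = PROLIFERATION,
    single_library: str = "HO",
    reference_strain: str = REFERENCE_STRAIN,
    min_lib_depth: int = 100_000,
    min_cell_count: int = 4,
    min_coverage: int = 3_000,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Filter, normalize, and score one query library against the singles.

    Runs the QC filter, computes each library's reference-normalized
    abundance, fits per-strain slopes, and returns ANCOVA GIS joined
    with multiplicative epsilon per array gene.
    """
    filtered, _ = filter_and_merge(
        counts,
        min_lib_depth=min_lib_depth,
        min_cell_count=min_cell_count,
        min_coverage=min_coverage,
    )
    merged, samples = filtered.merged, filtered.samples

    rel_d, _ = library_relative_abundance(
        merged, samples, query, condition, reference_strain
    )
    rel_s, _ = library_relative_abundance(
        merged, samples, single_library, condition, reference_strain
    )

    anc = interactions.gis_ancova(
        rel_d, rel_s, samples, phase, query,
        condition=condition, single_library=single_library, fdr=fdr,
    )

    fits_d = phenotype.fit_phenotypes(
        rel_d, samples, phase, condition=condition, library=query, adjust=False
    )
    fits_s = phenotype.fit_phenotypes(
        rel_s, samples, phase, condition=condition, library=single_library,
        adjust=False,
    )
    mult = interactions.gis_multiplicative(fits_d, fits_s, query, fdr=fdr)

    out = anc.join(mult, how="left", rsuffix="_mult")
    out.attrs.update(anc.attrs)
    return out


def simulate_and_score(
    truth: SimTruth,
    design: TimeCourseDesign,
    query: str,
    condition: str,
    phase: str = PROLIFERATION,
    seed: int = 0,
    noise_sd: float = 0.1,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Simulate counts for a truth/design and score one query library.

    The returned table joins both estimators with the generative truth
    (``gis_true``, ``epsilon_true``) for recovery analyses.
    """
    counts = simulate_counts(truth, design, seed=seed, noise_sd=noise_sd)
    scores = score_interaction_library(
        counts, query=query, condition=condition, phase=phase, fdr=fdr
    )
    gis_true = truth.gis_true[(query, condition, phase)]
    scores["gis_true"] = gis_true.reindex(scores.index)
    scores["epsilon_true"] = truth.epsilon_true(query, condition, phase).reindex(
        scores.index
    )
    return scores
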