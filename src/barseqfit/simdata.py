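"""Synthetic pooled Bar-seq experiments with known ground truth.

The generator mirrors the design of a pooled quiescence screen: four
double-mutant deletion libraries (a neutral HO control background plus
TOR1, RIM15 and PHO85 kinase query backgrounds) grown in three
nutrient-restricted media (carbon C, nitrogen N, phosphorus P), sampled
at five proliferative and five quiescent time points across biological
replicates, with library composition read out by sequencing strain
barcodes (UPTAG and DNTAG counted separately).

Abundance evolves exponentially on the log scale in phase-scaled time:
the expected relative abundance of strain *i* at scaled time *T* is
proportional to ``initial_freq_i * exp(rate_i * T)`` within each phase,
where ``rate_i`` is the strain's phase/condition effect plus, in a query
library, its interaction with the query.  The regression slope of
log-relative abundance against scaled time therefore equals the true
effect, which is what makes parameter-recovery tests exact.  Observed
counts are multinomial draws at a configurable depth per sample per tag;
optional lognormal per-observation noise emulates biological replicate
variability; optional read simulation with i.i.d. substitution errors
exercises the counting stage.

Quiescent-phase effects are drawn independently of proliferative-phase
effects by default (correlation configurable): the decoupling of fitness
in growth from survival in starvation is precisely the phenomenon the
downstream analysis is built to detect, so the generator must not bake
in a correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .barcode_counts import CountsTable, ReadLayout
from .phenotype import PROLIFERATION, QUIESCENCE, scale_times

__all__ = [
    "BarcodeCatalog",
    "SimTruth",
    "TimeCourseDesign",
    "make_catalog",
    "simulate_truth",
    "simulate_counts",
    "simulate_reads",
    "miss_probability",
]

BASES = np.array(list("ACGT"))
REFERENCE_STRAIN = "REF"
DEFAULT_QUERIES = ("TOR1", "RIM15", "PHO85")


@dataclass(frozen=True)
class TimeCourseDesign:
    """Sampling design of one simulated experiment.

    ``depth`` is reads per sample **per tag**; a sample's merged
    UPTAG + DNTAG depth is twice this.
    """

    times_h: Mapping[str, tuple] = field(
        default_factory=lambda: {
            PROLIFERATION: (0.0, 9.0, 14.0, 18.0, 24.0),
            QUIESCENCE: (32.0, 48.0, 96.0, 187.0, 368.0),
        }
    )
    libraries: tuple = ("HO",) + DEFAULT_QUERIES
    conditions: tuple = ("C", "N", "P")
    n_replicates: int = 3
    depth: int = 1_000_000

    def __post_init__(self):
        seen: list[float] = []
        for phase, times in self.times_h.items():
            t = np.asarray(times, dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"times not strictly increasing in {phase}")
            seen.append(t)
        if len(seen) == 2 and seen[0][-1] >= seen[1][0]:
            raise ValueError("phases overlap in time")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    def sample_sheet(self) -> pd.DataFrame:
        """All (library, condition, replicate, time) samples as a table."""
        rows = []
        for lib in self.libraries:
            for cond in self.conditions:
                for rep in range(1, self.n_replicates + 1):
                    for phase, times in self.times_h.items():
                        for t in times:
                            sid = f"{lib}_{cond}_r{rep}_t{t:g}"
                            rows.append(
                                {
                                    "sample_id": sid,
                                    "library": lib,
                                    "condition": cond,
                                    "replicate": rep,
                                    "time_h": float(t),
                                    "phase": phase,
                                }
                            )
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class BarcodeCatalog:
    """Strain <-> barcode catalog plus the sample-index pool.

    UPTAGs and DNTAGs are drawn from one common set with pairwise
    Levenshtein distance >= 5, so no read tag can sit within the
    matching radius of two catalog entries; sample indices have pairwise
    distance >= 2, making radius-1 index assignment unambiguous for
    substitution errors.
    """

    strains: pd.DataFrame  # index strain_id; columns uptag, dntag
    sample_indices: list[str]
    tag_length: int = 20
    index_length: int = 8

    def barcode_map(self) -> dict[str, tuple[str, str]]:
        out: dict[str, tuple[str, str]] = {}
        for sid, row in self.strains.iterrows():
            out[row["uptag"]] = (sid, "UP")
            out[row["dntag"]] = (sid, "DN")
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.strains.to_csv(path, sep="\t", index_label="strain_id")

    @classmethod
    def from_tsv(cls, path: str | Path, sample_indices=()) -> "BarcodeCatalog":
        strains = pd.read_csv(path, sep="\t", index_col="strain_id")
        return cls(
            strains=strains,
            sample_indices=list(sample_indices),
            tag_length=len(strains["uptag"].iloc[0]),
        )


def _random_distant_set(
    rng: np.random.Generator,
    n: int,
    length: int,
    min_dist: int,
    max_attempts_factor: int = 200,
) -> list[str]:
    """Random DNA sequences with pairwise Levenshtein distance >= min_dist."""
    import edlib

    out: list[str] = []
    attempts = 0
    budget = max_attempts_factor * n
    while len(out) < n:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"barcode space exhausted: could not place {n} sequences of "
                f"length {length} at pairwise distance >= {min_dist}"
            )
        cand = "".join(rng.choice(BASES, size=length))
        ok = True
        for seq in out:
            d = edlib.align(cand, seq, task="distance", k=min_dist - 1)["editDistance"]
            if d >= 0:  # within min_dist - 1
                ok = False
                break
        if ok:
            out.append(cand)
    return out


def default_strain_ids(n_strains: int, queries: Sequence[str] = DEFAULT_QUERIES) -> list[str]:
    """Reference strain, the query genes, then generic array gene ids."""
    ids = [REFERENCE_STRAIN, *queries]
    i = 1
    while len(ids) < n_strains + 1:  # +1: reference on top of the pool
        ids.append(f"G{i:04d}")
        i += 1
    return ids[: n_strains + 1]


def make_catalog(
    n_strains: int,
    seed: int,
    tag_length: int = 20,
    min_tag_dist: int = 5,
    n_indices: int = 120,
    index_length: int = 8,
    min_index_dist: int = 2,
    strain_ids: Sequence[str] | None = None,
) -> BarcodeCatalog:
    """Generate a barcode catalog for ``n_strains`` strains (plus reference).

    Deterministic given ``seed``.  Raises ``RuntimeError`` when the
    requested number of barcodes cannot be placed at the required
    pairwise distance (barcode-space exhaustion).
    """
    if n_strains < 2:
        raise ValueError("need at least two strains (including a reference)")
    if strain_ids is None:
        strain_ids = default_strain_ids(n_strains)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA5C0DE]))
    tags = _random_distant_set(rng, 2 * len(strain_ids), tag_length, min_tag_dist)
    indices = _random_distant_set(rng, n_indices, index_length, min_index_dist)
    strains = pd.DataFrame(
        {
            "uptag": tags[: len(strain_ids)],
            "dntag": tags[len(strain_ids) :],
        },
        index=pd.Index(strain_ids, name="strain_id"),
    )
    return BarcodeCatalog(
        strains=strains,
        sample_indices=indices,
        tag_length=tag_length,
        index_length=index_length,
    )


@dataclass
class SimTruth:
    """Ground-truth effects behind a simulated experiment.

    ``f_pro`` / ``s_qui``: per-strain log-scale proliferative fitness and
    quiescent survival per unit scaled time, per condition (reference
    strain fixed at 0).  ``gis_true`` holds the sparse interaction terms
    that enter a query library's double mutants additively on the
    log-slope: the double mutant's absolute effect is
    ``f_a + f_q + gis``.  On the multiplicative scale this corresponds to
    ``epsilon = exp(f_a + f_q + gis) - exp(f_a) * exp(f_q)``.
    """

    f_pro: pd.DataFrame  # strains x conditions
    s_qui: pd.DataFrame
    gis_true: dict[tuple[str, str, str], pd.Series]  # (query, condition, phase)
    initial_freq: pd.Series
    queries: tuple
    seed: int

    @property
    def strains(self) -> pd.Index:
        return self.f_pro.index

    def effects(self, phase: str) -> pd.DataFrame:
        if phase == PROLIFERATION:
            return self.f_pro
        if phase == QUIESCENCE:
            return self.s_qui
        raise KeyError(phase)

    def epsilon_true(self, query: str, condition: str, phase: str) -> pd.Series:
        """True interaction on the epsilon scale for one query/condition/phase."""
        gis = self.gis_true[(query, condition, phase)]
        f_a = self.effects(phase).loc[gis.index, condition]
        f_q = float(self.effects(phase).at[query, condition])
        return np.exp(f_a + f_q + gis) - np.exp(f_a) * np.exp(f_q)


def simulate_truth(
    n_strains: int = 2_000,
    conditions: Sequence[str] = ("C", "N", "P"),
    queries: Sequence[str] = DEFAULT_QUERIES,
    effect_sd: float = 0.2,
    interaction_fraction: float = 0.1,
    interaction_sd: float = 0.2,
    pro_qui_correlation: float = 0.0,
    query_effect_sd: float = 0.0,
    ref_weight: float = 0.05,
    init_freq_sd: float = 0.5,
    seed: int = 0,
) -> SimTruth:
    """Draw per-strain effects and a sparse interaction structure.

    Effects are Normal(0, effect_sd) on the log scale, independently per
    condition; survival is correlated with fitness only to the extent of
    ``pro_qui_correlation``.  For each (query, condition, phase), exactly
    ``round(interaction_fraction * n_pairs)`` array genes carry a nonzero
    interaction drawn from Normal(0, interaction_sd).  Initial pool
    frequencies are lognormal with the reference strain pinned at
    ``ref_weight`` of the pool (the control is deliberately over-
    represented, as when replicated control colonies are pooled, so its
    sampling noise does not dominate every normalized trajectory).

    The query kinases' own effects are drawn from
    Normal(0, ``query_effect_sd``), a separate knob defaulting to 0:
    queries in a quiescence screen are selected to be dispensable for
    proliferation, and a neutral query keeps the multiplicative
    estimator's expectation on the same scale as the query-normalized
    double-mutant coefficient (with a strongly non-neutral query the
    printed epsilon formula acquires an exp(f_q) bias for
    non-interacting genes; see the methods note).
    """
    if effect_sd < 0:
        raise ValueError("effect_sd must be >= 0")
    if not 0 <= interaction_fraction <= 1:
        raise ValueError("interaction_fraction must lie in [0, 1]")
    if not -1 <= pro_qui_correlation <= 1:
        raise ValueError("pro_qui_correlation must lie in [-1, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7A07]))
    strain_ids = default_strain_ids(n_strains, queries)
    idx = pd.Index(strain_ids, name="strain")
    conds = list(conditions)

    z1 = rng.standard_normal((len(idx), len(conds)))
    z2 = rng.standard_normal((len(idx), len(conds)))
    rho = pro_qui_correlation
    f_pro = pd.DataFrame(effect_sd * z1, index=idx, columns=conds)
    s_qui = pd.DataFrame(
        effect_sd * (rho * z1 + np.sqrt(1 - rho**2) * z2), index=idx, columns=conds
    )
    f_pro.loc[REFERENCE_STRAIN] = 0.0
    s_qui.loc[REFERENCE_STRAIN] = 0.0
    for q in queries:
        f_pro.loc[q] = query_effect_sd * rng.standard_normal(len(conds))
        s_qui.loc[q] = query_effect_sd * rng.standard_normal(len(conds))

    array_genes = idx.drop(REFERENCE_STRAIN)
    gis_true: dict[tuple[str, str, str], pd.Series] = {}
    for query in queries:
        targets = array_genes.drop(query) if query in array_genes else array_genes
        n_hits = round(interaction_fraction * len(targets))
        for cond in conds:
            for phase in (PROLIFERATION, QUIESCENCE):
                vals = pd.Series(0.0, index=targets)
                if n_hits:
                    hit = rng.choice(len(targets), size=n_hits, replace=False)
                    vals.iloc[hit] = rng.normal(0.0, interaction_sd, size=n_hits)
                gis_true[(query, cond, phase)] = vals

    w = np.exp(rng.normal(0.0, init_freq_sd, size=len(array_genes)))
    init = pd.Series(0.0, index=idx)
    init.loc[array_genes] = (1.0 - ref_weight) * w / w.sum()
    init.loc[REFERENCE_STRAIN] = ref_weight

    return SimTruth(
        f_pro=f_pro,
        s_qui=s_qui,
        gis_true=gis_true,
        initial_freq=init,
        queries=tuple(queries),
        seed=seed,
    )


def simulate_counts(
    truth: SimTruth,
    design: TimeCourseDesign,
    seed: int = 0,
    noise_sd: float = 0.1,
    n_ref_colonies: int = 96,
) -> CountsTable:
    """Multinomial Bar-seq counts for every sample in the design.

    Within each phase, strain frequencies follow
    ``initial_freq * exp(rate * T_scaled)`` renormalized over the pool,
    where ``rate`` is the strain's effect relative to the library's
    reference (the query background effect is shared by the whole pool
    and cancels in the renormalization).  ``noise_sd`` adds i.i.d.
    lognormal biological noise per strain per sample, shared between the
    two tags; UPTAG and DNTAG counts are then independent multinomial
    draws of ``design.depth`` reads each.  Deterministic given ``seed``.

    The reference is modeled as a pool of ``n_ref_colonies`` replicated
    control colonies: its biological noise averages down by
    ``sqrt(n_ref_colonies)``.  A noisy reference trajectory would
    otherwise impose a common-mode error on every normalized strain in
    the sample, which is exactly what pooling control colonies guards
    against in the bench protocol.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, seed, 0xC0047]))
    samples = design.sample_sheet()
    strains = truth.strains
    init = truth.initial_freq.loc[strains].to_numpy()

    scaled = {
        phase: dict(zip(times, scale_times(np.asarray(times, dtype=float))))
        for phase, times in design.times_h.items()
    }

    up = np.zeros((len(strains), len(samples)), dtype=np.int64)
    dn = np.zeros_like(up)
    for j, (sid, row) in enumerate(samples.iterrows()):
        phase, cond, lib = row["phase"], row["condition"], row["library"]
        rate = truth.effects(phase)[cond].loc[strains].to_numpy().copy()
        if lib in truth.queries:
            gis = truth.gis_true[(lib, cond, phase)]
            rate += gis.reindex(strains, fill_value=0.0).to_numpy()
        rate[strains.get_loc(REFERENCE_STRAIN)] = 0.0
        t_scaled = scaled[phase][row["time_h"]]
        w = init * np.exp(rate * t_scaled)
        if noise_sd > 0:
            noise = rng.normal(0.0, noise_sd, size=w.size)
            noise[strains.get_loc(REFERENCE_STRAIN)] /= np.sqrt(n_ref_colonies)
            w = w * np.exp(noise)
        p = w / w.sum()
        up[:, j] = rng.multinomial(design.depth, p)
        dn[:, j] = rng.multinomial(design.depth, p)

    return CountsTable(
        up=pd.DataFrame(up, index=strains, columns=samples.index),
        dn=pd.DataFrame(dn, index=strains, columns=samples.index),
        samples=samples,
    )


def assign_sample_indices(samples: pd.DataFrame, catalog: BarcodeCatalog) -> pd.DataFrame:
    """Attach an ``index_seq`` column assigning catalog indices to samples."""
    if len(samples) > len(catalog.sample_indices):
        raise ValueError(
            f"{len(samples)} samples but only {len(catalog.sample_indices)} indices"
        )
    out = samples.copy()
    out["index_seq"] = catalog.sample_indices[: len(samples)]
    return out


def simulate_reads(
    counts: CountsTable,
    catalog: BarcodeCatalog,
    substitution_rate: float = 0.0,
    seed: int = 0,
    out=None,
    layout: ReadLayout | None = None,
) -> tuple[list[str] | None, pd.DataFrame]:
    """Emit one FASTQ read per counted molecule.

    Reads are ``sample_index + flank + tag`` with i.i.d. substitutions at
    ``substitution_rate`` and a uniform placeholder quality.  Returns
    ``(lines, samples)`` where ``samples`` carries the index assignment
    used; if ``out`` is a path or handle the records are written there
    and ``lines`` is None.
    """
    if not 0 <= substitution_rate < 0.25:
        raise ValueError("substitution_rate must lie in [0, 0.25)")
    layout = layout or ReadLayout()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA57]))
    samples = counts.samples
    if "index_seq" not in samples.columns:
        samples = assign_sample_indices(samples, catalog)

    handle = None
    close = False
    lines: list[str] | None = None
    if out is None:
        lines = []
        emit = lines.append
    else:
        if isinstance(out, (str, Path)):
            handle = open(out, "w")
            close = True
        else:
            handle = out
        emit = handle.write

    qual = "I" * layout.read_length
    rid = 0
    try:
        for sid, row in samples.iterrows():
            index_seq = row["index_seq"]
            for tag_name, table in (("UP", counts.up), ("DN", counts.dn)):
                if sid not in table.columns:
                    continue
                col = table[sid]
                for strain, c in col[col > 0].items():
                    tag_seq = catalog.strains.at[strain, f"{tag_name.lower()}tag"]
                    template = np.frombuffer(
                        (index_seq + layout.flank + tag_seq).encode(), dtype="S1"
                    ).astype("U1")
                    reads = np.broadcast_to(template, (int(c), template.size)).copy()
                    if substitution_rate > 0:
                        mask = rng.random(reads.shape) < substitution_rate
                        n_sub = int(mask.sum())
                        if n_sub:
                            # substitute with a uniformly chosen *different* base
                            shift = rng.integers(1, 4, size=n_sub)
                            orig = np.searchsorted(BASES, reads[mask])
                            reads[mask] = BASES[(orig + shift) % 4]
                    for r in range(reads.shape[0]):
                        rid += 1
                        seq = "".join(reads[r])
                        emit(f"@r{rid} {sid} {strain} {tag_name}\n{seq}\n+\n{qual}\n")
    finally:
        if close and handle is not None:
            handle.close()
    return lines, samples


def miss_probability(frequency: float, n_cells: float) -> float:
    """Probability that a genotype at the given pool frequency is absent
    from a random sample of ``n_cells`` cells: ``(1 - f)^n``."""
    if not 0 <= frequency <= 1:
        raise ValueError("frequency must lie in [0, 1]")
    return float((1.0 - frequency) ** n_cells)
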