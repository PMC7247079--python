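"""FASTQ -> strain x sample counts for pooled Bar-seq screens.

Each sequencing read carries a sample index followed by a constant flank
and a strain-identifying deletion-cassette barcode (UPTAG or DNTAG).
Reads are demultiplexed by fuzzy index matching (Levenshtein distance at
most 1; the index set is built with pairwise distance >= 2, so a
single-substitution error is decoded to its true sample or rejected as
a tie, never silently misassigned) and assigned to strains by fuzzy
barcode matching (Levenshtein distance at most 2).
Ambiguous barcode matches — two or more catalog barcodes tied at the
minimal qualifying distance — are discarded rather than assigned
arbitrarily.

Filtering follows the screen's QC rules: per-tag sample libraries below a
total-depth floor are removed, individual low-count cells are zeroed as
likely sequencing-error artifacts, UPTAG and DNTAG counts for the same
strain are merged by summation, and strains with insufficient total
coverage or entirely absent from either tag are dropped.  The filter is
iterated to a fixed point so that re-applying it is a no-op.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import edlib
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadLayout",
    "CountsTable",
    "MatchStatus",
    "match_barcode",
    "match_index",
    "count_reads",
    "filter_and_merge",
]

UNMATCHED = "unmatched"
AMBIGUOUS = "ambiguous"
MATCHED = "matched"
MatchStatus = str


@dataclass(frozen=True)
class ReadLayout:
    """Positions of the index and tag within a read.

    The two-step PCR scheme places the sample index first, then a
    constant flank from the amplification primer, then the 20-nt tag.
    The flank sequence itself is not interrogated during counting.
    """

    index_length: int = 8
    flank: str = "GATGTCCACGAGGTCTCT"
    tag_length: int = 20

    @property
    def tag_start(self) -> int:
        return self.index_length + len(self.flank)

    @property
    def read_length(self) -> int:
        return self.tag_start + self.tag_length

    def index_of(self, read: str) -> str:
        return read[: self.index_length]

    def tag_of(self, read: str) -> str:
        return read[self.tag_start : self.tag_start + self.tag_length]


@dataclass
class CountsTable:
    """Strain x sample read counts with sample metadata.

    ``up`` and ``dn`` hold per-tag counts (strains as rows, sample ids as
    columns); ``merged`` is filled in by :func:`filter_and_merge`.
    ``samples`` is indexed by sample id with columns ``library``,
    ``condition``, ``replicate``, ``time_h`` and ``phase``.
    """

    up: pd.DataFrame
    dn: pd.DataFrame
    samples: pd.DataFrame
    merged: pd.DataFrame | None = None

    def copy(self) -> "CountsTable":
        return CountsTable(
            up=self.up.copy(),
            dn=self.dn.copy(),
            samples=self.samples.copy(),
            merged=None if self.merged is None else self.merged.copy(),
        )

    def to_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.up.to_csv(prefix.with_suffix(".up.tsv"), sep="\t")
        self.dn.to_csv(prefix.with_suffix(".dn.tsv"), sep="\t")
        self.samples.to_csv(prefix.with_suffix(".samples.tsv"), sep="\t")
        if self.merged is not None:
            self.merged.to_csv(prefix.with_suffix(".merged.tsv"), sep="\t")


def _levenshtein(a: str, b: str, k: int | None = None) -> int:
    res = edlib.align(a, b, task="distance", k=-1 if k is None else k)
    return res["editDistance"]


def match_barcode(
    read_tag: str,
    barcodes: Mapping[str, object],
    max_dist: int = 2,
) -> tuple[object | None, MatchStatus]:
    """Assign a read's tag to the unique catalog barcode within distance 2.

    Parameters
    ----------
    read_tag
        The tag portion of the read.
    barcodes
        Mapping from catalog barcode sequence to an arbitrary label
        (typically ``(strain_id, tag_name)``).

    Returns
    -------
    ``(label, "matched")`` for a unique best hit within ``max_dist``,
    ``(None, "unmatched")`` if nothing qualifies, and
    ``(None, "ambiguous")`` when two or more barcodes tie at the minimal
    qualifying distance.
    """
    if not barcodes:
        raise ValueError("empty barcode catalog")
    hit = barcodes.get(read_tag)
    if hit is not None:
        return hit, MATCHED
    best: object | None = None
    best_dist = max_dist + 1
    tied = False
    for seq, label in barcodes.items():
        d = _levenshtein(read_tag, seq, k=max_dist)
        if d < 0:
            continue
        if d < best_dist:
            best, best_dist, tied = label, d, False
        elif d == best_dist:
            tied = True
    if best is None:
        return None, UNMATCHED
    if tied:
        return None, AMBIGUOUS
    return best, MATCHED


def match_index(
    read_index: str,
    index_map: Mapping[str, object],
    max_dist: int = 1,
) -> tuple[object | None, MatchStatus]:
    """Assign a read's sample index within Levenshtein distance 1.

    The index set is constructed with pairwise distance >= 2, so a
    corrupted index can never be decoded to the *wrong* sample: any
    competing index ties at best, and ties are treated as unmatched.
    """
    hit = index_map.get(read_index)
    if hit is not None:
        return hit, MATCHED
    best: object | None = None
    best_dist = max_dist + 1
    tied = False
    for seq, label in index_map.items():
        d = _levenshtein(read_index, seq, k=max_dist)
        if d < 0:
            continue
        if d < best_dist:
            best, best_dist, tied = label, d, False
        elif d == best_dist:
            tied = True
    if best is None or tied:
        return None, UNMATCHED
    return best, MATCHED


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _fastq_records(source) -> Iterator[tuple[str, str, str]]:
    if isinstance(source, (str, Path)):
        with _open_maybe_gzip(source) as handle:
            yield from FastqGeneralIterator(handle)
    else:
        yield from FastqGeneralIterator(source)


def count_reads(
    fastq,
    catalog,
    samples: pd.DataFrame,
    layout: ReadLayout | None = None,
    max_tag_dist: int = 2,
    max_index_dist: int = 1,
) -> tuple[CountsTable, dict]:
    """Tabulate matched (sample, strain) pairs per tag from a FASTQ file.

    Parameters
    ----------
    fastq
        Path (optionally .gz) or open text handle of 4-line FASTQ records.
    catalog
        A :class:`barseqfit.simdata.BarcodeCatalog` (anything exposing
        ``barcode_map()``: sequence -> (strain_id, tag)).
    samples
        Sample sheet indexed by sample id with an ``index_seq`` column
        giving each sample's index sequence.
    layout
        Read layout; defaults to :class:`ReadLayout`.

    Returns
    -------
    (counts, qc) where counts is a per-tag :class:`CountsTable` and qc a
    ledger of reads matched / unmatched / ambiguous.  Malformed FASTQ
    records raise ``ValueError`` with the record number.
    """
    layout = layout or ReadLayout()
    if "index_seq" not in samples.columns:
        raise ValueError("sample sheet must carry an 'index_seq' column")
    barcode_map = catalog.barcode_map()
    index_map = {seq: sid for sid, seq in samples["index_seq"].items()}
    if len(index_map) != len(samples):
        raise ValueError("sample index sequences are not unique")

    strains = pd.Index(catalog.strains.index, name="strain")
    tables = {
        tag: pd.DataFrame(0, index=strains, columns=samples.index, dtype=int)
        for tag in ("UP", "DN")
    }
    qc = {
        "reads_total": 0,
        "matched": 0,
        "unmatched_index": 0,
        "unmatched_tag": 0,
        "ambiguous_tag": 0,
    }
    tag_cache: dict[str, tuple[object | None, str]] = {}
    idx_cache: dict[str, tuple[object | None, str]] = {}

    records = _fastq_records(fastq)
    n = 0
    while True:
        try:
            rec = next(records, None)
        except ValueError as exc:  # malformed record from the FASTQ parser
            raise ValueError(f"malformed FASTQ near record {n + 1}: {exc}") from exc
        if rec is None:
            break
        n += 1
        _, seq, _ = rec
        qc["reads_total"] += 1
        idx_seq = layout.index_of(seq)
        hit = idx_cache.get(idx_seq)
        if hit is None:
            hit = match_index(idx_seq, index_map, max_index_dist)
            idx_cache[idx_seq] = hit
        sample_id, status = hit
        if status != MATCHED:
            qc["unmatched_index"] += 1
            continue
        tag_seq = layout.tag_of(seq)
        hit = tag_cache.get(tag_seq)
        if hit is None:
            hit = match_barcode(tag_seq, barcode_map, max_tag_dist)
            tag_cache[tag_seq] = hit
        label, status = hit
        if status == AMBIGUOUS:
            qc["ambiguous_tag"] += 1
            continue
        if status == UNMATCHED:
            qc["unmatched_tag"] += 1
            continue
        strain_id, tag = label
        tables[tag].at[strain_id, sample_id] += 1
        qc["matched"] += 1

    counts = CountsTable(up=tables["UP"], dn=tables["DN"], samples=samples.copy())
    return counts, qc


def filter_and_merge(
    counts: CountsTable,
    min_lib_depth: int = 100_000,
    min_cell_count: int = 4,
    min_coverage: int = 3_000,
    max_iter: int = 20,
) -> tuple[CountsTable, dict]:
    """Apply the screen's QC filters and merge UPTAG + DNTAG counts.

    Per pass: (1) drop per-tag sample libraries whose total reads fall
    below ``min_lib_depth``; (2) zero count cells <= ``min_cell_count``
    (sequencing-error artifacts); (3) merge the tags by summation;
    (4) drop strains with merged coverage below ``min_coverage`` across
    all retained samples, or with zero total in either tag.  Passes are
    repeated until nothing changes, so the operation is idempotent.

    Returns the filtered table (with ``merged`` set) and a report of
    removals per step.
    """
    up = counts.up.copy()
    dn = counts.dn.copy()
    report: dict = {
        "samples_removed": {"UP": [], "DN": []},
        "cells_zeroed": 0,
        "strains_removed": [],
        "passes": 0,
    }

    for _ in range(max_iter):
        changed = False
        for tag, df in (("UP", up), ("DN", dn)):
            if df.shape[1]:
                low = df.columns[df.sum(axis=0) < min_lib_depth]
                if len(low):
                    report["samples_removed"][tag].extend(map(str, low))
                    df.drop(columns=low, inplace=True)
                    changed = True
        for df in (up, dn):
            mask = (df > 0) & (df <= min_cell_count)
            n_zeroed = int(mask.to_numpy().sum())
            if n_zeroed:
                df[mask] = 0
                report["cells_zeroed"] += n_zeroed
                changed = True

        all_cols = counts.samples.index
        merged = up.reindex(columns=all_cols, fill_value=0).add(
            dn.reindex(columns=all_cols, fill_value=0), fill_value=0
        )
        merged = merged[[c for c in all_cols if c in up.columns or c in dn.columns]]

        drop = merged.sum(axis=1) < min_coverage
        # absence from a tag only counts against a strain if that tag
        # retained any samples at all
        if up.shape[1]:
            drop |= up.sum(axis=1) == 0
        if dn.shape[1]:
            drop |= dn.sum(axis=1) == 0
        if drop.any():
            report["strains_removed"].extend(map(str, merged.index[drop]))
            keep = merged.index[~drop]
            up = up.loc[keep]
            dn = dn.loc[keep]
            merged = merged.loc[keep]
            changed = True
        report["passes"] += 1
        if not changed:
            break

    if merged.empty or merged.shape[1] == 0:
        raise ValueError("no counts survive filtering")

    samples = counts.samples.loc[merged.columns]
    out = CountsTable(
        up=up, dn=dn, samples=samples, merged=merged.astype(int)
    )
    return out, report


def write_qc_report(qc: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(qc), indent=2) + "\n")
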