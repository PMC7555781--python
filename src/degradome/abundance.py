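"""Decay profiles and DPKM/FPKM abundance statistics.

DPKM (decay reads per kilobase per million) applies the familiar
reads-per-kilobase-per-million normalization to 5'-end tag counts summed
over a cDNA; FPKM is the matching statistic for RNA-seq counts. Both are
computed from raw counts with explicit length/total normalization so the
two share a denominator convention and their ratio cancels length
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TranscriptAnnotation
from .kmers import TAG_LEN
from .preprocess import TagTable


@dataclass
class DecayProfile:
    """One transcript's per-position tag abundance vector (a D-plot).

    ``rpm`` and ``raw`` are position-indexed Series (sorted by
    position). ``soa`` is the sum of per-position RPM abundances over the
    transcript.
    """

    transcript_id: str
    length: int
    rpm: pd.Series
    raw: pd.Series
    replicate: int | None = None

    @property
    def soa(self) -> float:
        return float(self.rpm.sum())

    @property
    def total_raw(self) -> int:
        return int(self.raw.sum())


def build_decay_profile(
    table: TagTable,
    transcript_id: str,
    annotations: Mapping[str, TranscriptAnnotation],
) -> DecayProfile:
    """Aggregate a library's records for one transcript into a profile."""
    if transcript_id not in annotations:
        raise KeyError(f"unknown transcript_id: {transcript_id}")
    length = annotations[transcript_id].length
    sub = table.records[table.records["transcript_id"] == transcript_id]
    rpm = sub.groupby("position")["rpm"].sum().sort_index()
    raw = sub.groupby("position")["raw_count"].sum().sort_index()
    if len(rpm) and not (0 <= rpm.index.min() and rpm.index.max() <= length - TAG_LEN):
        raise ValueError(f"{transcript_id}: tag position outside cDNA")
    return DecayProfile(
        transcript_id=transcript_id,
        length=length,
        rpm=rpm,
        raw=raw,
        replicate=table.replicate,
    )


def profiles_from_table(
    table: TagTable, annotations: Mapping[str, TranscriptAnnotation]
) -> dict[str, DecayProfile]:
    """Decay profiles for every annotated transcript (empty ones included)."""
    grouped = table.records.groupby("transcript_id")
    out: dict[str, DecayProfile] = {}
    for tid, annot in annotations.items():
        if tid in grouped.groups:
            sub = grouped.get_group(tid)
            rpm = sub.groupby("position")["rpm"].sum().sort_index()
            raw = sub.groupby("position")["raw_count"].sum().sort_index()
        else:
            rpm = pd.Series(dtype=float)
            raw = pd.Series(dtype="int64")
        out[tid] = DecayProfile(
            transcript_id=tid,
            length=annot.length,
            rpm=rpm,
            raw=raw,
            replicate=table.replicate,
        )
    unknown = set(grouped.groups) - set(annotations)
    if unknown:
        raise KeyError(f"unknown transcript_id: {sorted(unknown)[0]}")
    return out


def compute_dpkm(profile: DecayProfile, total_mapped_reads: int) -> float:
    """DPKM = (sum of raw tag counts) * 1e9 / (length * total mapped reads)."""
    if profile.length <= 0:
        raise ValueError("transcript length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return profile.total_raw * 1e9 / (profile.length * total_mapped_reads)


def compute_fpkm(count: float, length: int, total: int) -> float:
    """FPKM = count * 1e9 / (length * total); same form as DPKM."""
    if length <= 0:
        raise ValueError("transcript length must be positive")
    if total <= 0:
        raise ValueError("total count must be positive")
    return count * 1e9 / (length * total)


def abundance_table(
    pare_tables: Sequence[TagTable],
    rnaseq_counts: pd.DataFrame,
    annotations: Mapping[str, TranscriptAnnotation],
) -> pd.DataFrame:
    """Per-transcript FPKM/DPKM table from two PARE replicates and RNA-seq.

    ``rnaseq_counts`` columns: transcript_id, count_r1, count_r2. The
    result carries raw counts and normalized values per replicate, plus
    library totals in ``DataFrame.attrs``.
    """
    if len(pare_tables) != 2:
        raise ValueError("expected exactly two PARE replicates")
    tids = list(annotations)
    lengths = np.array([annotations[t].length for t in tids])
    out = pd.DataFrame({"transcript_id": tids, "length": lengths})

    rna = rnaseq_counts.set_index("transcript_id")
    rna_totals = []
    for r in (1, 2):
        col = rna[f"count_r{r}"].reindex(tids).fillna(0).to_numpy()
        total = int(col.sum())
        rna_totals.append(total)
        out[f"rna_count_r{r}"] = col.astype(np.int64)
        out[f"fpkm_r{r}"] = col * 1e9 / (lengths * total) if total else 0.0

    pare_totals = []
    for table in pare_tables:
        r = table.replicate
        sums = table.records.groupby("transcript_id")["raw_count"].sum()
        col = sums.reindex(tids).fillna(0).to_numpy()
        pare_totals.append(table.total_mapped_reads)
        out[f"pare_count_r{r}"] = col.astype(np.int64)
        out[f"dpkm_r{r}"] = (
            col * 1e9 / (lengths * table.total_mapped_reads)
            if table.total_mapped_reads
            else 0.0
        )
    out.attrs["rna_totals"] = rna_totals
    out.attrs["pare_totals"] = pare_totals
    return out
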