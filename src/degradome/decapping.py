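"""Cap-position inference and decapped-transcript calling.

Decapping exposes a 5' monophosphate at the transcript's first
nucleotide, so a decapped transcript shows its dominant 5'-end tag
(PARE Max-seq) exactly at the cap. The cap position itself is located
empirically from capped-end (C-PARE) tags projected into a 400-nt frame
around the annotated TSS: 200 nt of upstream genomic sequence
concatenated with the first 200 nt of the cDNA. Offset 0 is the
annotated first transcribed nucleotide; offsets run -200..+199 and
increase 5'->3' along the transcript (minus-strand windows are
reverse-complemented).

Cap calls require three filters on the C-PARE window profiles:
F1 identical Max-seq offset across replicates; F2 Max-seq abundance
> ``rpm_min``; F3 Max-seq share of in-window abundance > ``ratio_min``.
A transcript is called decapped when its PARE window Max-seq (same
three filters) sits at the same offset as its cap call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TranscriptAnnotation, revcomp
from .kmers import TAG_LEN, MismatchIndex, encode_tags

WINDOW_FLANK = 200
DEFAULT_RPM_MIN = 10.0
DEFAULT_RATIO_MIN = 0.2


@dataclass
class CapWindow:
    """The +/-200-nt frame around one transcript's annotated TSS."""

    transcript_id: str
    window_sequence: str
    upstream_len: int  # 200, or less when the contig is too short (flagged)
    truncated: bool

    def offset_of(self, window_pos: int) -> int:
        return window_pos - self.upstream_len


def build_window(
    annotation: TranscriptAnnotation, genome: Mapping[str, str]
) -> CapWindow:
    """200 nt genomic upstream + first 200 nt of the cDNA, strand-correct."""
    contig = genome[annotation.chromosome]
    if annotation.strand == "+":
        lo = max(annotation.tss - WINDOW_FLANK, 0)
        upstream = contig[lo : annotation.tss]
    else:
        hi = min(annotation.tss + 1 + WINDOW_FLANK, len(contig))
        upstream = revcomp(contig[annotation.tss + 1 : hi])
    downstream = annotation.cdna_sequence[:WINDOW_FLANK]
    truncated = len(upstream) < WINDOW_FLANK
    return CapWindow(
        transcript_id=annotation.transcript_id,
        window_sequence=upstream + downstream,
        upstream_len=len(upstream),
        truncated=truncated,
    )


def build_windows(
    annotations: Mapping[str, TranscriptAnnotation], genome: Mapping[str, str]
) -> dict[str, CapWindow]:
    return {t: build_window(a, genome) for t, a in annotations.items()}


def project_tags_to_window(
    tags: pd.DataFrame,
    windows: Mapping[str, CapWindow] | Sequence[CapWindow],
    total_mapped_reads: int,
) -> pd.DataFrame:
    """Project filtered tags onto TSS windows at <=1 mismatch.

    ``tags`` is a collapsed (sequence, count) table; ``total_mapped_reads``
    is the library's normalization denominator, re-used unchanged so that
    window RPM is on the same scale as transcript-wide RPM. Returns a
    (transcript_id, offset, raw_count, rpm) table.
    """
    if not isinstance(windows, Mapping):
        windows = {w.transcript_id: w for w in windows}
    index = MismatchIndex({t: w.window_sequence for t, w in windows.items()})
    codes = encode_tags(tags["sequence"])
    tag_idx, ref_idx, pos, _ = index.query(codes, max_mismatch=1)

    counts = tags["count"].to_numpy()
    names = index.names
    upstream = np.array([windows[n].upstream_len for n in names])
    hits = pd.DataFrame(
        {
            "transcript_id": [names[i] for i in ref_idx],
            "offset": pos - upstream[ref_idx],
            "raw_count": counts[tag_idx],
        }
    )
    profile = (
        hits.groupby(["transcript_id", "offset"], as_index=False)["raw_count"]
        .sum()
        .sort_values(["transcript_id", "offset"], ignore_index=True)
    )
    profile["rpm"] = (
        profile["raw_count"] * 1e6 / total_mapped_reads
        if total_mapped_reads > 0
        else 0.0
    )
    return profile


def _window_max(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript Max-seq offset within the window (5'-most tie-break)."""
    if profile.empty:
        return pd.DataFrame(columns=["transcript_id", "offset", "abundance", "total"])
    df = profile.sort_values(["transcript_id", "offset"])
    agg = df.groupby("transcript_id")["rpm"]
    total = agg.sum()
    idx = agg.idxmax()  # first max in offset order = 5'-most
    best = df.loc[idx]
    return pd.DataFrame(
        {
            "transcript_id": best["transcript_id"].to_numpy(),
            "offset": best["offset"].to_numpy(),
            "abundance": best["rpm"].to_numpy(),
            "total": total.loc[best["transcript_id"]].to_numpy(),
        }
    )


def _filtered_window_max(
    profile_rep1: pd.DataFrame,
    profile_rep2: pd.DataFrame,
    rpm_min: float,
    ratio_min: float,
    per_replicate: bool,
) -> tuple[pd.DataFrame, dict[str, int]]:
    m1 = _window_max(profile_rep1).set_index("transcript_id")
    m2 = _window_max(profile_rep2).set_index("transcript_id")
    shared = m1.index.intersection(m2.index).sort_values()
    m1, m2 = m1.loc[shared], m2.loc[shared]
    cascade = {"input": len(shared)}

    same = m1["offset"].to_numpy() == m2["offset"].to_numpy()
    m1, m2 = m1[same], m2[same]
    cascade["F1_same_offset"] = len(m1)

    def agg(v1: np.ndarray, v2: np.ndarray, threshold: float) -> np.ndarray:
        if per_replicate:
            return (v1 > threshold) & (v2 > threshold)
        return (v1 + v2) / 2 > threshold

    keep = agg(m1["abundance"].to_numpy(), m2["abundance"].to_numpy(), rpm_min)
    m1, m2 = m1[keep], m2[keep]
    cascade["F2_abundance"] = len(m1)

    r1 = m1["abundance"].to_numpy() / m1["total"].to_numpy()
    r2 = m2["abundance"].to_numpy() / m2["total"].to_numpy()
    keep = agg(r1, r2, ratio_min)
    m1, m2 = m1[keep], m2[keep]
    cascade["F3_ratio"] = len(m1)

    calls = pd.DataFrame(
        {
            "transcript_id": m1.index.to_numpy(),
            "offset": m1["offset"].to_numpy(dtype=int),
            "abundance_r1": m1["abundance"].to_numpy(),
            "abundance_r2": m2["abundance"].to_numpy(),
            "ratio_r1": m1["abundance"].to_numpy() / m1["total"].to_numpy(),
            "ratio_r2": m2["abundance"].to_numpy() / m2["total"].to_numpy(),
        }
    )
    return calls.reset_index(drop=True), cascade


def infer_cap_position(
    cpare_profile_rep1: pd.DataFrame,
    cpare_profile_rep2: pd.DataFrame,
    rpm_min: float = DEFAULT_RPM_MIN,
    ratio_min: float = DEFAULT_RATIO_MIN,
    per_replicate: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Empirical cap positions from replicated C-PARE window profiles."""
    calls, cascade = _filtered_window_max(
        cpare_profile_rep1, cpare_profile_rep2, rpm_min, ratio_min, per_replicate
    )
    return calls.rename(columns={"offset": "cap_offset"}), cascade


def call_decapped(
    cap_calls: pd.DataFrame,
    pare_profile_rep1: pd.DataFrame,
    pare_profile_rep2: pd.DataFrame,
    rpm_min: float = DEFAULT_RPM_MIN,
    ratio_min: float = DEFAULT_RATIO_MIN,
    per_replicate: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Decapped calls: cap offset equals the filtered PARE window Max-seq."""
    pare_max, cascade = _filtered_window_max(
        pare_profile_rep1, pare_profile_rep2, rpm_min, ratio_min, per_replicate
    )
    merged = cap_calls.merge(
        pare_max[["transcript_id", "offset", "abundance_r1", "abundance_r2"]],
        on="transcript_id",
        suffixes=("_cpare", "_pare"),
    )
    calls = merged[merged["cap_offset"] == merged["offset"]].copy()
    calls = calls.rename(
        columns={
            "abundance_r1_cpare": "cpare_abundance_r1",
            "abundance_r2_cpare": "cpare_abundance_r2",
            "abundance_r1_pare": "pare_abundance_r1",
            "abundance_r2_pare": "pare_abundance_r2",
        }
    )
    cascade["decapped"] = len(calls)
    cols = [
        "transcript_id",
        "cap_offset",
        "cpare_abundance_r1",
        "cpare_abundance_r2",
        "pare_abundance_r1",
        "pare_abundance_r2",
    ]
    return calls[cols].reset_index(drop=True), cascade


def offset_distribution(
    cap_calls: pd.DataFrame, near: int = 50
) -> tuple[pd.Series, dict[str, float]]:
    """Histogram of cap offsets over -200..+199 plus headline fractions.

    Summary reports the fraction of calls exactly at the annotated TSS
    (offset 0) and within ``near`` nt of it.
    """
    offsets = cap_calls["cap_offset"].to_numpy(dtype=int)
    index = pd.RangeIndex(-WINDOW_FLANK, WINDOW_FLANK, name="offset")
    counts = pd.Series(0, index=index, dtype=int)
    vals, n = np.unique(offsets, return_counts=True)
    counts.loc[vals] = n
    total = len(offsets)
    summary = {
        "n_calls": float(total),
        "frac_at_annotated_tss": float((offsets == 0).sum() / total) if total else float("nan"),
        f"frac_within_{near}nt": float((np.abs(offsets) <= near).sum() / total)
        if total
        else float("nan"),
    }
    return counts, summary
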