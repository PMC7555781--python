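"""Raw tag standardization and filtering.

Raw 5'-end tag reads are reduced to exact 20-nt tags, passed through
three sequence filters (simple sequence repeats, genomic multi-hits,
mitochondrial matches), and mapped to cDNAs at <=1 mismatch to produce a
normalized per-(transcript, position) tag table.

Filter cascade, in order:

1. SSR: discard tags containing a continuous 12-nt stretch with period
   1, 2 or 3 (mononucleotide runs, dinucleotide and trinucleotide
   repeats).
2. Multi-hit: discard tags with more than ``max_genome_hits`` loci in
   the reference genome at <=1 mismatch, counting both strands.
3. Mitochondrial: discard tags exactly matching the mitochondrial
   sequence on either strand.

Surviving tags are mapped to cDNAs allowing one mismatch; a tag hitting
several isoforms contributes its full count to each, while the RPM
denominator counts each distinct read once.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import TranscriptAnnotation
from .kmers import (
    TAG_LEN,
    MismatchIndex,
    encode_tags,
    exact_kmer_hashes,
    full_tag_hashes,
)

logger = logging.getLogger(__name__)

SSR_WINDOW = 12
_VALID_READ = re.compile(r"^[ACGTN]*$")


# ---------------------------------------------------------------------------
# read trimming


def _trim_one(read: str, adapter: str | None, min_overlap: int = 3) -> str:
    if not adapter:
        return read
    # first full occurrence of the adapter, else adapter prefix (>=3 nt)
    # at the read's 3' end
    i = read.find(adapter)
    if i >= 0:
        return read[:i]
    for ov in range(min(len(adapter), len(read)) - 1, min_overlap - 1, -1):
        if read.endswith(adapter[:ov]):
            return read[: len(read) - ov]
    return read


def trim_reads(
    reads: Iterable[str], adapter: str | None = None, min_len: int = TAG_LEN
) -> pd.DataFrame:
    """Adapter-trim, length-standardize and collapse raw reads.

    Reads shorter than ``min_len`` after trimming are discarded; longer
    reads are truncated to their first 20 nt. Returns a collapsed
    (sequence, count) table sorted by sequence.
    """
    counts: dict[str, int] = {}
    n_bad = 0
    for read in reads:
        read = read.upper()
        if not _VALID_READ.match(read):
            n_bad += 1
            continue
        insert = _trim_one(read, adapter)
        if len(insert) < min_len:
            continue
        tag = insert[:TAG_LEN]
        counts[tag] = counts.get(tag, 0) + 1
    if n_bad:
        logger.warning("discarded %d reads with non-ACGTN characters", n_bad)
    df = pd.DataFrame(
        {"sequence": list(counts.keys()), "count": list(counts.values())}
    )
    return df.sort_values("sequence", ignore_index=True)


# ---------------------------------------------------------------------------
# SSR detection


def ssr_mask(tag_codes: np.ndarray, window: int = SSR_WINDOW) -> np.ndarray:
    """Boolean mask of tags containing a period-<=3 repeat of ``window`` nt.

    A window w of length 12 is a repeat of period p iff w[i] == w[i+p]
    for every i with both indices inside the window, i.e. the per-tag
    equality array s[i] == s[i+p] holds on 12-p consecutive positions.
    """
    n, length = tag_codes.shape
    out = np.zeros(n, dtype=bool)
    if length < window:
        return out
    for p in (1, 2, 3):
        eq = tag_codes[:, p:] == tag_codes[:, :-p]
        need = window - p
        if eq.shape[1] < need:
            continue
        runs = np.lib.stride_tricks.sliding_window_view(eq, need, axis=1)
        out |= runs.all(axis=2).any(axis=1)
    return out


def detect_ssr(sequence: str) -> bool:
    """True iff the sequence contains a 12-nt single/double/triple repeat."""
    if len(sequence) < SSR_WINDOW:
        return False
    return bool(ssr_mask(encode_tags([sequence]))[0])


# ---------------------------------------------------------------------------
# filtering and mapping


@dataclass
class PreprocessContext:
    """Reference indexes shared across libraries of one run."""

    genome: Mapping[str, str]
    mito: Mapping[str, str]
    annotations: Mapping[str, TranscriptAnnotation]
    max_genome_hits: int = 20
    genome_index: MismatchIndex = field(init=False, repr=False)
    mito_hashes: np.ndarray = field(init=False, repr=False)
    cdna_index: MismatchIndex = field(init=False, repr=False)

    def __post_init__(self) -> None:
        from .io import revcomp

        both = dict(self.genome)
        both.update({f"{n}__rc": revcomp(s) for n, s in self.genome.items()})
        self.genome_index = MismatchIndex(both)
        self.mito_hashes = exact_kmer_hashes(self.mito)
        self.cdna_index = MismatchIndex(
            {t: a.cdna_sequence for t, a in self.annotations.items()}
        )


def filter_tags(
    tags: pd.DataFrame, ctx: PreprocessContext
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the SSR -> multi-hit -> mitochondrial cascade.

    Returns the retained (sequence, count) table and per-stage survivor
    statistics (counting distinct tag sequences).
    """
    stats = {"input": len(tags)}
    codes = encode_tags(tags["sequence"])

    keep = ~ssr_mask(codes)
    tags, codes = tags[keep].reset_index(drop=True), codes[keep]
    stats["after_ssr"] = len(tags)

    hits = ctx.genome_index.hit_counts(
        codes, max_mismatch=1, cap=ctx.max_genome_hits + 1
    )
    keep = hits <= ctx.max_genome_hits
    tags, codes = tags[keep].reset_index(drop=True), codes[keep]
    stats["after_multihit"] = len(tags)

    if ctx.mito_hashes.size:
        mito_hit = np.isin(full_tag_hashes(codes), ctx.mito_hashes)
        tags = tags[~mito_hit].reset_index(drop=True)
    stats["after_mito"] = len(tags)
    return tags, stats


@dataclass
class TagTable:
    """Normalized per-(transcript, position) tag abundances, one library.

    ``records`` columns: transcript_id, position (0-based cDNA coordinate
    of the tag's 5' end), raw_count, rpm. ``rpm`` is
    raw_count * 1e6 / total_mapped_reads, where the denominator counts
    each distinct mapped read once regardless of isoform multiplicity.
    """

    library_id: str
    library_type: str  # PARE | CPARE | RNASEQ
    replicate: int
    records: pd.DataFrame
    total_mapped_reads: int

    def to_tsv(self, path) -> None:
        df = self.records.copy()
        df.insert(0, "library_id", self.library_id)
        df.insert(1, "type", self.library_type)
        df.insert(2, "replicate", self.replicate)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "TagTable":
        df = pd.read_csv(
            path, sep="\t", dtype={"position": "int64", "raw_count": "int64", "rpm": float}
        )
        if df.empty:
            raise ValueError(f"{path}: empty tag table")
        total = int(round(df["raw_count"].iloc[0] * 1e6 / df["rpm"].iloc[0]))
        return cls(
            library_id=str(df["library_id"].iloc[0]),
            library_type=str(df["type"].iloc[0]),
            replicate=int(df["replicate"].iloc[0]),
            records=df[["transcript_id", "position", "raw_count", "rpm"]].copy(),
            total_mapped_reads=total,
        )


def map_tags(
    tags: pd.DataFrame,
    ctx: PreprocessContext,
    library_id: str,
    library_type: str,
    replicate: int,
) -> TagTable:
    """Map filtered tags to cDNAs at <=1 mismatch and normalize to RPM."""
    codes = encode_tags(tags["sequence"])
    tag_idx, ref_idx, pos, _ = ctx.cdna_index.query(codes, max_mismatch=1)

    counts = tags["count"].to_numpy()
    mapped = np.zeros(len(tags), dtype=bool)
    mapped[tag_idx] = True
    total_mapped = int(counts[mapped].sum())
    n_unmapped = int((~mapped).sum())
    if n_unmapped:
        logger.info(
            "%s: %d distinct tags (%d reads) did not map to any cDNA",
            library_id,
            n_unmapped,
            int(counts[~mapped].sum()),
        )

    names = ctx.cdna_index.names
    hits = pd.DataFrame(
        {
            "transcript_id": [names[i] for i in ref_idx],
            "position": pos,
            "raw_count": counts[tag_idx],
        }
    )
    records = (
        hits.groupby(["transcript_id", "position"], as_index=False)["raw_count"]
        .sum()
        .sort_values(["transcript_id", "position"], ignore_index=True)
    )
    if total_mapped > 0:
        records["rpm"] = records["raw_count"] * 1e6 / total_mapped
    else:
        records["rpm"] = np.zeros(len(records))
    return TagTable(
        library_id=library_id,
        library_type=library_type,
        replicate=replicate,
        records=records,
        total_mapped_reads=total_mapped,
    )


@dataclass
class PreprocessResult:
    table: TagTable
    filtered_tags: pd.DataFrame  # survives all filters; input to window projection
    stats: dict[str, int]


def run_preprocess(
    raw_tags: pd.DataFrame,
    ctx: PreprocessContext,
    library_id: str,
    library_type: str,
    replicate: int,
    adapter: str | None = None,
    min_len: int = TAG_LEN,
) -> PreprocessResult:
    """Full standardization pipeline for one library replicate."""
    if adapter or (raw_tags["sequence"].str.len() != TAG_LEN).any():
        expanded = np.repeat(raw_tags["sequence"].to_numpy(), raw_tags["count"])
        raw_tags = trim_reads(expanded, adapter=adapter, min_len=min_len)
    filtered, stats = filter_tags(raw_tags, ctx)
    table = map_tags(filtered, ctx, library_id, library_type, replicate)
    stats["mapped_reads"] = table.total_mapped_reads
    return PreprocessResult(table=table, filtered_tags=filtered, stats=stats)
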