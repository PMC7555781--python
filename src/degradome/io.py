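"""Sequence, annotation and tag-list input/output.

All internal coordinates are 0-based, half-open. GTF files use the
conventional 1-based inclusive coordinates and are converted at the
boundary. Transcripts are single-exon throughout (sufficient for 5'-end
tag profiling; splicing is out of scope).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptAnnotation:
    """A transcript's coordinate frame.

    ``tss`` is the genomic, 0-based position of the first transcribed
    nucleotide on the transcript's strand. ``start``/``end`` delimit the
    (single-exon) genomic locus, 0-based half-open. ``utr5_end`` and
    ``cds_end`` are cDNA coordinates (0-based, half-open) delimiting the
    5'UTR / CDS / 3'UTR segments.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    cdna_sequence: str
    utr5_end: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.utr5_end <= self.cds_end <= len(self.cdna_sequence)):
            raise ValueError(
                f"{self.transcript_id}: UTR/CDS boundaries out of order"
            )
        if len(self.cdna_sequence) < 20:
            raise ValueError(f"{self.transcript_id}: cDNA shorter than one tag")

    @property
    def length(self) -> int:
        return len(self.cdna_sequence)

    @property
    def tss(self) -> int:
        """Genomic position of the first transcribed nucleotide."""
        return self.start if self.strand == "+" else self.end - 1


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq_sequences(path: str | os.PathLike) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_tags_fastq(tags: pd.DataFrame, path: str | os.PathLike) -> None:
    """Expand a collapsed (sequence, count) table into FASTQ with dummy quality."""
    with open(path, "w") as fh:
        i = 0
        for seq, count in zip(tags["sequence"], tags["count"]):
            for _ in range(int(count)):
                fh.write(f"@tag{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                i += 1


# ---------------------------------------------------------------------------
# Collapsed tag lists (2-column TSV: sequence, count)


def read_tags_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "count": "int64"})
    if list(df.columns) != ["sequence", "count"]:
        raise ValueError(f"{path}: expected columns (sequence, count)")
    return df


def write_tags_tsv(tags: pd.DataFrame, path: str | os.PathLike) -> None:
    tags.loc[:, ["sequence", "count"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF


def write_gtf(annots: Iterable[TranscriptAnnotation], path: str | os.PathLike) -> None:
    """Write transcript/exon/CDS features, 1-based inclusive coordinates."""
    lines = []
    for a in sorted(annots, key=lambda a: (a.chromosome, a.start, a.transcript_id)):
        attrs = f'gene_id "{a.gene_id}"; transcript_id "{a.transcript_id}";'
        for feature, lo, hi in _gtf_features(a):
            lines.append(
                f"{a.chromosome}\tdegradome\t{feature}\t{lo + 1}\t{hi}\t.\t"
                f"{a.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _gtf_features(a: TranscriptAnnotation):
    yield "transcript", a.start, a.end
    yield "exon", a.start, a.end
    # CDS in genomic coordinates: cDNA [utr5_end, cds_end) mapped by strand.
    if a.cds_end > a.utr5_end:
        if a.strand == "+":
            yield "CDS", a.start + a.utr5_end, a.start + a.cds_end
        else:
            yield "CDS", a.end - a.cds_end, a.end - a.utr5_end


def read_gtf(
    path: str | os.PathLike, cdna: Mapping[str, str]
) -> dict[str, TranscriptAnnotation]:
    """Load single-exon transcript annotations from a GTF plus cDNA FASTA."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    annots: dict[str, TranscriptAnnotation] = {}
    for t in db.features_of_type("transcript"):
        tid = t.attributes["transcript_id"][0]
        gid = t.attributes["gene_id"][0]
        start, end = t.start - 1, t.end  # to 0-based half-open
        cds = list(db.children(t, featuretype="CDS"))
        if cds:
            c = cds[0]
            clo, chi = c.start - 1, c.end
            if t.strand == "+":
                utr5_end, cds_end = clo - start, chi - start
            else:
                utr5_end, cds_end = end - chi, end - clo
        else:
            utr5_end = cds_end = 0
        if tid not in cdna:
            raise KeyError(f"transcript {tid} missing from cDNA FASTA")
        annots[tid] = TranscriptAnnotation(
            transcript_id=tid,
            gene_id=gid,
            chromosome=t.seqid,
            strand=t.strand,
            start=start,
            end=end,
            cdna_sequence=cdna[tid],
            utr5_end=utr5_end,
            cds_end=cds_end,
        )
    return annots
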