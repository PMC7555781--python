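"""Synthetic transcriptome, RNA-seq and 5'-end tag library generator.

Emulates the statistical structure of an XRN1-knockdown degradome
experiment at desk scale: two biological replicates each of PARE
(5'-monophosphate decay tags), C-PARE (capped-end tags) and RNA-seq,
over a transcriptome of single-exon transcripts with known, planted
ground truth:

* a stable / unstable / neither stability class per transcript, realized
  as an RNA:PARE intensity ratio of +/- ``stability_log2fc`` (log2);
* an optional endonucleolytic cleavage site, realized as a tag peak
  concentrating ``peak_fraction`` of the transcript's decay tags at one
  cDNA coordinate over a uniform background;
* an optional decap signal, realized as a PARE peak at the planted cap
  position; C-PARE tags always concentrate at the cap (with optional
  integer jitter).

Background decay is uniform over the cDNA -- the correct null for
testing the peak-calling filters. Everything is a deterministic function
of ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .decapping import build_window
from .io import TranscriptAnnotation, revcomp, write_fasta, write_gtf, write_tags_tsv
from .kmers import TAG_LEN

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic run.

    Defaults are the standard fixture: 500 transcripts, 20% planted
    stable and 20% unstable at a true |log2 RNA:PARE ratio| of 4, 10%
    cleaved (peak fraction 0.4) and 10% decapped, replicate libraries of
    10^6 reads with negative-binomial dispersion 0.05 on RNA-seq counts.
    """

    n_transcripts: int = 500
    length_range: tuple[int, int] = (800, 2000)
    tss_upstream_pad: int = 300
    frac_stable: float = 0.2
    frac_unstable: float = 0.2
    frac_cleaved: float = 0.1
    frac_decapped: float = 0.1
    background_decay_tags: float = 2000.0
    peak_fraction: float = 0.4
    cap_jitter_sd: float = 0.0
    cap_offset_range: tuple[int, int] = (0, 0)
    nb_dispersion: float = 0.05
    library_size: int = 1_000_000
    expr_sigma: float = 0.75
    stability_log2fc: float = 4.0
    transcripts_per_contig: int = 25
    mito_length: int = 2000
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_stable", "frac_unstable", "frac_cleaved", "frac_decapped"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_stable + self.frac_unstable > 1.0:
            raise ValueError("frac_stable + frac_unstable must be <= 1")
        lo, hi = self.length_range
        if lo < 500 or hi < lo:
            raise ValueError(
                "length_range minimum must be >= 500 to accommodate the "
                "+200-nt TSS window"
            )
        if self.library_size <= 0 or self.n_transcripts <= 0:
            raise ValueError("n_transcripts and library_size must be positive")
        if self.nb_dispersion < 0 or self.peak_fraction < 0 or self.peak_fraction > 1:
            raise ValueError("nb_dispersion >= 0 and peak_fraction in [0,1] required")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _scrub_ssr(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample bases until no 12-nt period-<=3 repeat remains."""
    window = 12
    while True:
        hit = False
        for p in (1, 2, 3):
            eq = codes[p:] == codes[:-p]
            need = window - p
            if eq.size < need:
                continue
            runs = np.lib.stride_tricks.sliding_window_view(eq, need).all(axis=1)
            starts = np.flatnonzero(runs)
            if starts.size:
                hit = True
                bad = np.unique(
                    (starts[:, None] + np.arange(window)).ravel()
                )
                bad = bad[bad < codes.size]
                codes[bad] = rng.integers(0, 4, size=bad.size).astype(np.uint8)
        if not hit:
            return codes


def _random_seq(n: int, rng: np.random.Generator) -> str:
    codes = rng.integers(0, 4, size=n).astype(np.uint8)
    codes = _scrub_ssr(codes, rng)
    return bytes(_BASES[codes]).decode()


@dataclass
class GroundTruth:
    """Per-transcript planted signals, written as a TSV sidecar."""

    table: pd.DataFrame  # transcript_id, stability_class,
    # planted_cleavage_position (-1 = none), planted_cap_position, is_decapped

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GroundTruth":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class Transcriptome:
    genome: dict[str, str]
    annotations: dict[str, TranscriptAnnotation]


def generate_transcriptome(config: SimConfig) -> Transcriptome:
    """Random SSR-free genome with single-exon transcripts on both strands.

    Each transcript has at least ``tss_upstream_pad`` nt of flanking
    genomic sequence upstream of its TSS on its own strand.
    """
    config.validate()
    rng = _rng(config, 0)
    pad = config.tss_upstream_pad
    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_transcripts)

    genome: dict[str, str] = {}
    annotations: dict[str, TranscriptAnnotation] = {}
    per_contig = config.transcripts_per_contig
    n_contigs = -(-config.n_transcripts // per_contig)
    t = 0
    for c in range(n_contigs):
        n_here = min(per_contig, config.n_transcripts - t)
        contig_lengths = lengths[t : t + n_here]
        contig_len = int(pad + (contig_lengths + pad).sum())
        contig_seq = _random_seq(contig_len, rng)
        name = f"chr{c + 1}"
        genome[name] = contig_seq
        cursor = pad
        for j in range(n_here):
            L = int(contig_lengths[j])
            tid = f"T{t + j:04d}"
            strand = "+" if (t + j) % 2 == 0 else "-"
            start, end = cursor, cursor + L
            seq = contig_seq[start:end]
            if strand == "-":
                seq = revcomp(seq)
            utr5 = max(TAG_LEN, int(0.15 * L))
            cds_end = min(L - TAG_LEN, int(0.85 * L))
            annotations[tid] = TranscriptAnnotation(
                transcript_id=tid,
                gene_id=f"G{t + j:04d}",
                chromosome=name,
                strand=strand,
                start=start,
                end=end,
                cdna_sequence=seq,
                utr5_end=utr5,
                cds_end=cds_end,
            )
            cursor = end + pad
        t += n_here
    genome["chrM"] = _random_seq(config.mito_length, rng)
    return Transcriptome(genome=genome, annotations=annotations)


def assign_truth(config: SimConfig, transcriptome: Transcriptome) -> GroundTruth:
    """Plant stability classes, cleavage sites and decap signals.

    Cleavage and decap plants go to disjoint sets of non-stable
    transcripts (decay peaks mark transcripts under active turnover);
    planted cleavage positions keep >=50 nt clear of both the cap and
    the 3' end so peaks never run off the transcript and stay
    distinguishable from decap signals.
    """
    rng = _rng(config, 1)
    tids = sorted(transcriptome.annotations)
    n = len(tids)
    n_stable = int(round(config.frac_stable * n))
    n_unstable = int(round(config.frac_unstable * n))
    order = rng.permutation(n)
    cls = np.array(["neither"] * n, dtype=object)
    cls[order[:n_stable]] = "stable"
    cls[order[n_stable : n_stable + n_unstable]] = "unstable"

    non_stable = np.flatnonzero(cls != "stable")
    non_stable = non_stable[rng.permutation(non_stable.size)]
    n_cleaved = min(int(round(config.frac_cleaved * n)), non_stable.size)
    cleaved_idx = set(non_stable[:n_cleaved].tolist())
    n_decapped = min(
        int(round(config.frac_decapped * n)), non_stable.size - n_cleaved
    )
    decapped_idx = set(non_stable[n_cleaved : n_cleaved + n_decapped].tolist())

    cleave_pos = np.full(n, -1, dtype=int)
    cap_pos = rng.integers(
        config.cap_offset_range[0], config.cap_offset_range[1] + 1, size=n
    )
    for i in sorted(cleaved_idx):
        L = transcriptome.annotations[tids[i]].length
        cleave_pos[i] = int(rng.integers(50, L - 50))
    table = pd.DataFrame(
        {
            "transcript_id": tids,
            "stability_class": cls,
            "planted_cleavage_position": cleave_pos,
            "planted_cap_position": cap_pos,
            "is_decapped": [i in decapped_idx for i in range(n)],
        }
    )
    return GroundTruth(table)


def _intensities(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-transcript RNA and PARE intensity (arbitrary units)."""
    n = len(truth.table)
    base = config.background_decay_tags * rng.lognormal(
        mean=0.0, sigma=config.expr_sigma, size=n
    )
    delta = np.select(
        [
            truth.table["stability_class"].to_numpy() == "stable",
            truth.table["stability_class"].to_numpy() == "unstable",
        ],
        [config.stability_log2fc, -config.stability_log2fc],
        default=0.0,
    )
    rna = base * 2.0 ** (delta / 2.0)
    pare = base * 2.0 ** (-delta / 2.0)
    return rna, pare


def simulate_rnaseq(truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Two replicates of negative-binomial transcript counts.

    Mean counts scale each transcript's RNA intensity to a library of
    ``library_size`` expected reads; with ``nb_dispersion`` 0 the counts
    are Poisson. Zero intensity gives count 0 exactly.
    """
    rng = _rng(config, 2)
    rna, _ = _intensities(config, truth, rng)
    mu = rna / rna.sum() * config.library_size
    out = pd.DataFrame({"transcript_id": truth.table["transcript_id"]})
    for r in (1, 2):
        out[f"count_r{r}"] = nb_counts(mu, config.nb_dispersion, rng)
    return out


def nb_counts(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """NB(mean mu, dispersion phi) draws; Poisson when phi = 0, 0 when mu = 0."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0.0:
        lam = mu
    else:
        lam = np.where(
            mu > 0, rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu), 0.0
        )
    return np.where(mu > 0, rng.poisson(lam), 0).astype(np.int64)


def _tags_from_positions(
    annot: TranscriptAnnotation,
    window_seq: str,
    upstream_len: int,
    positions: np.ndarray,
    counts: np.ndarray,
    acc: dict[str, int],
) -> None:
    """Accumulate 20-nt tag sequences for cDNA offsets (may be negative)."""
    cdna = annot.cdna_sequence
    for pos, cnt in zip(positions, counts):
        pos = int(pos)
        if pos >= 0:
            seq = cdna[pos : pos + TAG_LEN]
        else:
            w = upstream_len + pos
            seq = window_seq[w : w + TAG_LEN]
        if len(seq) == TAG_LEN:
            acc[seq] = acc.get(seq, 0) + int(cnt)


def _acc_to_df(acc: dict[str, int]) -> pd.DataFrame:
    df = pd.DataFrame(
        {"sequence": list(acc.keys()), "count": list(acc.values())}
    )
    return df.sort_values("sequence", ignore_index=True)


def simulate_pare(
    truth: GroundTruth, config: SimConfig, transcriptome: Transcriptome
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two replicate PARE libraries as collapsed (sequence, count) tables.

    ``library_size`` reads are split multinomially across transcripts by
    decay intensity. Within a transcript, a planted cleavage site (or
    cap position, for decapped transcripts) takes a Binomial
    (n, peak_fraction) share of the reads exactly at the planted
    coordinate; the rest start uniformly over the cDNA.
    """
    rng = _rng(config, 3)
    _, pare = _intensities(config, truth, _rng(config, 2))  # same intensity draw
    weights = pare / pare.sum()
    tt = truth.table
    windows = {
        t: build_window(a, transcriptome.genome)
        for t, a in transcriptome.annotations.items()
    }
    libs = []
    for _rep in (1, 2):
        n_t = rng.multinomial(config.library_size, weights)
        acc: dict[str, int] = {}
        for i, tid in enumerate(tt["transcript_id"]):
            n_reads = int(n_t[i])
            if n_reads == 0:
                continue
            annot = transcriptome.annotations[tid]
            L = annot.length
            peak_pos = None
            if tt["planted_cleavage_position"].iat[i] >= 0:
                peak_pos = int(tt["planted_cleavage_position"].iat[i])
            elif bool(tt["is_decapped"].iat[i]):
                peak_pos = int(tt["planted_cap_position"].iat[i])
            if peak_pos is not None and peak_pos > L - TAG_LEN:
                raise ValueError(
                    f"{tid}: planted peak within {TAG_LEN} nt of the 3' end"
                )
            n_peak = (
                rng.binomial(n_reads, config.peak_fraction)
                if peak_pos is not None
                else 0
            )
            n_bg = n_reads - n_peak
            if n_bg:
                bg_pos = rng.integers(0, L - TAG_LEN + 1, size=n_bg)
                pos, cnt = np.unique(bg_pos, return_counts=True)
                w = windows[tid]
                _tags_from_positions(annot, w.window_sequence, w.upstream_len, pos, cnt, acc)
            if n_peak:
                w = windows[tid]
                _tags_from_positions(
                    annot,
                    w.window_sequence,
                    w.upstream_len,
                    np.array([peak_pos]),
                    np.array([n_peak]),
                    acc,
                )
        libs.append(_acc_to_df(acc))
    return libs[0], libs[1]


def simulate_cpare(
    truth: GroundTruth, config: SimConfig, transcriptome: Transcriptome
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two replicate C-PARE libraries: capped-end tags at the cap position.

    Tag starts are the planted cap offset plus round(Normal(0,
    cap_jitter_sd)); with zero jitter every tag of a transcript shares
    one start. Reads are split across transcripts by RNA intensity.
    """
    rng = _rng(config, 4)
    rna, _ = _intensities(config, truth, _rng(config, 2))
    weights = rna / rna.sum()
    tt = truth.table
    windows = {
        t: build_window(a, transcriptome.genome)
        for t, a in transcriptome.annotations.items()
    }
    libs = []
    for _rep in (1, 2):
        n_t = rng.multinomial(config.library_size, weights)
        acc: dict[str, int] = {}
        for i, tid in enumerate(tt["transcript_id"]):
            n_reads = int(n_t[i])
            if n_reads == 0:
                continue
            annot = transcriptome.annotations[tid]
            cap = int(tt["planted_cap_position"].iat[i])
            if config.cap_jitter_sd > 0:
                jitter = np.rint(
                    rng.normal(0.0, config.cap_jitter_sd, size=n_reads)
                ).astype(int)
                starts = cap + jitter
            else:
                starts = np.full(n_reads, cap)
            w = windows[tid]
            lo, hi = -w.upstream_len, annot.length - TAG_LEN
            starts = np.clip(starts, lo, hi)
            pos, cnt = np.unique(starts, return_counts=True)
            _tags_from_positions(annot, w.window_sequence, w.upstream_len, pos, cnt, acc)
        libs.append(_acc_to_df(acc))
    return libs[0], libs[1]


@dataclass
class SimOutput:
    config: SimConfig
    transcriptome: Transcriptome
    truth: GroundTruth
    rnaseq: pd.DataFrame
    pare: tuple[pd.DataFrame, pd.DataFrame]
    cpare: tuple[pd.DataFrame, pd.DataFrame]


def simulate_all(config: SimConfig) -> SimOutput:
    """Run the full generator (transcriptome, truth, all six libraries)."""
    transcriptome = generate_transcriptome(config)
    truth = assign_truth(config, transcriptome)
    return SimOutput(
        config=config,
        transcriptome=transcriptome,
        truth=truth,
        rnaseq=simulate_rnaseq(truth, config),
        pare=simulate_pare(truth, config, transcriptome),
        cpare=simulate_cpare(truth, config, transcriptome),
    )


def null_config(config: SimConfig) -> SimConfig:
    """The matched null: same conditions, nothing planted."""
    return replace(
        config, frac_stable=0.0, frac_unstable=0.0, frac_cleaved=0.0, frac_decapped=0.0
    )


def write_outputs(sim: SimOutput, outdir: str | Path) -> None:
    """Write genome/cDNA FASTA, GTF, tag TSVs, RNA-seq counts and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.transcriptome.genome, outdir / "genome.fa")
    write_fasta(
        {t: a.cdna_sequence for t, a in sim.transcriptome.annotations.items()},
        outdir / "cdna.fa",
    )
    write_gtf(sim.transcriptome.annotations.values(), outdir / "annotation.gtf")
    sim.truth.to_tsv(outdir / "truth.tsv")
    sim.rnaseq.to_csv(outdir / "rnaseq_counts.tsv", sep="\t", index=False)
    for r, df in zip((1, 2), sim.pare):
        write_tags_tsv(df, outdir / f"pare_rep{r}.tsv")
    for r, df in zip((1, 2), sim.cpare):
        write_tags_tsv(df, outdir / f"cpare_rep{r}.tsv")
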