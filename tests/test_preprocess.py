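"""Tag standardization, SSR/multi-hit/mito filters and cDNA mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degradome.io import revcomp
from degradome.kmers import MismatchIndex, encode_tags
from degradome.preprocess import (
    PreprocessContext,
    TagTable,
    detect_ssr,
    filter_tags,
    map_tags,
    trim_reads,
)

from conftest import make_annotation, random_seq, tags_df

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def brute_force_ssr(seq: str, window: int = 12) -> bool:
    """Independent oracle: enumerate all windows x periods explicitly."""
    for start in range(len(seq) - window + 1):
        w = seq[start : start + window]
        for p in (1, 2, 3):
            if all(w[i] == w[i + p] for i in range(window - p)):
                return True
    return False


class TestTrimReads:
    def test_adapter_trimmed_and_truncated_to_20(self):
        insert = "ACGTGCATCGATTGCAGCATAC"  # 22 nt
        out = trim_reads([insert[:22] + ADAPTER[:8]])
        assert list(out["sequence"]) == [insert[:20]]

    def test_short_insert_discarded(self):
        out = trim_reads(["ACGTGCATCGATTGCAGC" + ADAPTER], adapter=ADAPTER)
        assert out.empty

    def test_identical_reads_collapse(self):
        read = "ACGTGCATCGATTGCAGCATACGGT"  # 25 nt, no adapter
        out = trim_reads([read, read])
        assert list(out["sequence"]) == [read[:20]]
        assert list(out["count"]) == [2]

    def test_non_acgtn_discarded(self):
        out = trim_reads(["ACGTGCATCGATTGCAGCAX" + "A" * 5])
        assert out.empty

    def test_empty_input(self):
        assert trim_reads([]).empty

    def test_adapter_prefix_overlap_at_read_end(self):
        # only the first 4 adapter nt fit on the read; still trimmed
        insert = "ACGTGCATCGATTGCAGCATAC"
        out = trim_reads([insert + ADAPTER[:4]], adapter=ADAPTER)
        assert list(out["sequence"]) == [insert[:20]]


class TestDetectSSR:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAAAAAAAAAAGCGTACGT", True),  # period-1 run of 12
            ("ACACACACACACGTGTCCAA", True),  # period-2 run of 12
            ("ACGTACGTACGTACGTACGT", False),  # period 4 only
            ("GCAGTAGCTAGTCAGTCAGT", False),
            ("GCAGTAGCGTAGTAGTAGTA", True),  # trailing period-3 repeat
        ],
    )
    def test_examples(self, seq, expected):
        assert detect_ssr(seq) is expected
        assert brute_force_ssr(seq) is expected

    def test_short_sequence_is_false(self):
        assert detect_ssr("ACGTACGTAChG"[:11]) is False

    def test_agrees_with_brute_force_on_random_20mers(self):
        rng = np.random.default_rng(11)
        for _ in range(2000):
            seq = random_seq(rng, 20)
            assert detect_ssr(seq) == brute_force_ssr(seq)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=12, max_size=30))
    def test_property_matches_oracle(self, seq):
        assert detect_ssr(seq) == brute_force_ssr(seq)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=8),
           st.integers(min_value=1, max_value=3))
    def test_property_planted_repeat_always_detected(self, flank, period):
        unit = "ACG"[:period]
        repeat = (unit * 12)[:12]
        assert detect_ssr(flank + repeat + flank)


def _context_with_planted(rng):
    """Small genome with a tag planted at 25 loci and a mito contig."""
    repeat_tag = random_seq(rng, 20)
    pieces = []
    for _ in range(25):
        pieces.append(repeat_tag)
        pieces.append(random_seq(rng, 30))
    genome_main = random_seq(rng, 400) + "".join(pieces)
    mito = random_seq(rng, 300)
    cdna = genome_main[50:350]
    annot = make_annotation(cdna, "T0", start=50)
    genome = {"chr1": genome_main, "chrM": mito}
    ctx = PreprocessContext(
        genome=genome, mito={"chrM": mito}, annotations={"T0": annot}
    )
    return ctx, repeat_tag, mito, cdna


class TestFilterTags:
    def test_cascade(self):
        rng = np.random.default_rng(5)
        ctx, repeat_tag, mito, cdna = _context_with_planted(rng)
        good = cdna[40:60]
        mito_tag = mito[100:120]
        ssr_tag = "A" * 12 + random_seq(rng, 8)
        tags = tags_df([(good, 3), (repeat_tag, 1), (mito_tag, 2), (ssr_tag, 5)])
        kept, stats = filter_tags(tags, ctx)
        assert list(kept["sequence"]) == [good]
        assert stats["input"] == 4
        assert stats["after_ssr"] == 3
        assert stats["after_multihit"] == 2
        assert stats["after_mito"] == 1

    def test_mito_reverse_strand_discarded(self):
        rng = np.random.default_rng(6)
        ctx, _, mito, _ = _context_with_planted(rng)
        tags = tags_df([(revcomp(mito[30:50]), 1)])
        kept, _ = filter_tags(tags, ctx)
        assert kept.empty

    def test_cascade_monotone(self):
        rng = np.random.default_rng(8)
        ctx, repeat_tag, mito, cdna = _context_with_planted(rng)
        tags = tags_df(
            [(cdna[i : i + 20], 1) for i in range(0, 200, 7)]
            + [(repeat_tag, 1), (mito[0:20], 1)]
        )
        _, stats = filter_tags(tags, ctx)
        assert (
            stats["input"]
            >= stats["after_ssr"]
            >= stats["after_multihit"]
            >= stats["after_mito"]
        )


def brute_force_map(tag: str, annotations) -> list[tuple[str, int]]:
    """Exhaustive per-position Hamming scan over every cDNA."""
    hits = []
    for tid, annot in annotations.items():
        seq = annot.cdna_sequence
        for pos in range(len(seq) - len(tag) + 1):
            mm = sum(a != b for a, b in zip(tag, seq[pos : pos + len(tag)]))
            if mm <= 1:
                hits.append((tid, pos))
    return sorted(hits)


class TestMapTags:
    def test_exact_hit_recorded(self, small_ctx, small_sim):
        tid, annot = next(iter(small_sim.transcriptome.annotations.items()))
        tag = annot.cdna_sequence[40:60]
        table = map_tags(tags_df([(tag, 5)]), small_ctx, "lib", "PARE", 1)
        hits = table.records
        assert ((hits["transcript_id"] == tid) & (hits["position"] == 40)).any()

    def test_two_mismatches_unmapped(self, small_ctx, small_sim):
        annot = next(iter(small_sim.transcriptome.annotations.values()))
        tag = list(annot.cdna_sequence[40:60])
        for i in (3, 11):
            tag[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tag[i]]
        tag = "".join(tag)
        if brute_force_map(tag, small_sim.transcriptome.annotations):
            pytest.skip("mutated tag accidentally matches elsewhere")
        table = map_tags(tags_df([(tag, 1)]), small_ctx, "lib", "PARE", 1)
        assert table.records.empty
        assert table.total_mapped_reads == 0

    def test_rpm_formula(self, small_ctx, small_sim):
        annots = list(small_sim.transcriptome.annotations.values())
        tags = [(annots[0].cdna_sequence[i * 25 : i * 25 + 20], 100) for i in range(9)]
        tags.append((annots[1].cdna_sequence[40:60], 100))
        table = map_tags(tags_df(tags), small_ctx, "lib", "PARE", 1)
        assert table.total_mapped_reads == 1000
        rec = table.records
        row = rec[(rec["transcript_id"] == annots[1].transcript_id)
                  & (rec["position"] == 40)]
        assert float(row["rpm"].iloc[0]) == pytest.approx(100_000.0)

    def test_agrees_with_exhaustive_hamming_scan(self, small_ctx, small_sim):
        rng = np.random.default_rng(17)
        annotations = small_sim.transcriptome.annotations
        seqs = [a.cdna_sequence for a in annotations.values()]
        tags = []
        for _ in range(30):
            s = seqs[rng.integers(len(seqs))]
            pos = int(rng.integers(0, len(s) - 19))
            tag = list(s[pos : pos + 20])
            if rng.random() < 0.6:  # mutate 0-2 positions
                for i in rng.choice(20, size=rng.integers(1, 3), replace=False):
                    tag[i] = "ACGT"[rng.integers(4)]
            tags.append("".join(tag))
        tags += [random_seq(rng, 20) for _ in range(10)]
        table = map_tags(
            tags_df([(t, 1) for t in set(tags)]), small_ctx, "lib", "PARE", 1
        )
        got = sorted(
            (r.transcript_id, int(r.position))
            for r in table.records.itertuples()
            for _ in range(int(r.raw_count))
        )
        expected = sorted(
            hit for t in set(tags) for hit in brute_force_map(t, annotations)
        )
        assert got == expected

    def test_tagtable_tsv_roundtrip(self, small_ctx, small_sim, tmp_path):
        annot = next(iter(small_sim.transcriptome.annotations.values()))
        table = map_tags(
            tags_df([(annot.cdna_sequence[0:20], 7)]), small_ctx, "lib9", "CPARE", 2
        )
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        back = TagTable.from_tsv(path)
        assert back.library_id == "lib9"
        assert back.library_type == "CPARE"
        assert back.replicate == 2
        assert back.total_mapped_reads == table.total_mapped_reads
        pd.testing.assert_frame_equal(
            back.records.reset_index(drop=True), table.records
        )
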