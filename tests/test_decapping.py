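"""TSS windows, tag projection, cap inference and decap calling."""

import numpy as np
import pandas as pd
import pytest

from degradome.decapping import (
    build_window,
    build_windows,
    call_decapped,
    infer_cap_position,
    offset_distribution,
    project_tags_to_window,
)
from degradome.io import revcomp
from degradome.preprocess import map_tags

from conftest import make_annotation, random_seq, tags_df


@pytest.fixture(scope="module")
def plus_case():
    rng = np.random.default_rng(21)
    contig = random_seq(rng, 11000)
    cdna = contig[10000:10800]
    annot = make_annotation(cdna, "Tplus", strand="+", start=10000)
    return {"chr1": contig}, annot


@pytest.fixture(scope="module")
def minus_case():
    rng = np.random.default_rng(22)
    contig = random_seq(rng, 2000)
    start, end = 500, 1300
    cdna = revcomp(contig[start:end])
    annot = make_annotation(cdna, "Tminus", strand="-", start=start)
    return {"chr1": contig}, annot


class TestBuildWindow:
    def test_plus_strand_construction(self, plus_case):
        genome, annot = plus_case
        w = build_window(annot, genome)
        assert w.window_sequence == genome["chr1"][9800:10000] + annot.cdna_sequence[:200]
        assert w.upstream_len == 200 and not w.truncated

    def test_minus_strand_upstream_is_reverse_complement(self, minus_case):
        genome, annot = minus_case
        w = build_window(annot, genome)
        # TSS of a minus-strand transcript is the locus end; genomic
        # downstream of it, reverse-complemented, is transcript-upstream
        expected_upstream = revcomp(genome["chr1"][1300:1500])
        assert w.window_sequence[:200] == expected_upstream
        assert w.window_sequence[200:] == annot.cdna_sequence[:200]

    def test_concatenation_seam(self, plus_case):
        genome, annot = plus_case
        w = build_window(annot, genome)
        assert w.window_sequence[200] == annot.cdna_sequence[0]

    def test_truncated_window_flagged(self):
        rng = np.random.default_rng(23)
        contig = random_seq(rng, 1000)
        annot = make_annotation(contig[50:850], "Tshort", strand="+", start=50)
        w = build_window(annot, {"chr1": contig})
        assert w.truncated and w.upstream_len == 50
        assert len(w.window_sequence) == 250


def brute_force_project(tag: str, window: str, upstream_len: int) -> list[int]:
    hits = []
    for pos in range(len(window) - len(tag) + 1):
        mm = sum(a != b for a, b in zip(tag, window[pos : pos + len(tag)]))
        if mm <= 1:
            hits.append(pos - upstream_len)
    return hits


class TestProjectTags:
    def test_known_offsets(self, plus_case):
        genome, annot = plus_case
        w = build_window(annot, genome)
        tags = tags_df(
            [(w.window_sequence[190:210], 4), (annot.cdna_sequence[:20], 6)]
        )
        prof = project_tags_to_window(tags, {annot.transcript_id: w}, 10_000)
        got = dict(zip(prof["offset"], prof["raw_count"]))
        assert got[-10] == 4 and got[0] == 6
        rpm = dict(zip(prof["offset"], prof["rpm"]))
        assert rpm[0] == pytest.approx(600.0)

    def test_agrees_with_brute_force_window_scan(self, plus_case):
        rng = np.random.default_rng(30)
        genome, annot = plus_case
        w = build_window(annot, genome)
        tags = []
        for _ in range(25):
            pos = int(rng.integers(0, 381))
            tag = list(w.window_sequence[pos : pos + 20])
            for i in rng.choice(20, size=rng.integers(0, 3), replace=False):
                tag[i] = "ACGT"[rng.integers(4)]
            tags.append("".join(tag))
        tags = sorted(set(tags))
        prof = project_tags_to_window(
            tags_df([(t, 1) for t in tags]), {annot.transcript_id: w}, 10_000
        )
        got = sorted(
            off
            for off, cnt in zip(prof["offset"], prof["raw_count"])
            for _ in range(int(cnt))
        )
        expected = sorted(
            off
            for t in tags
            for off in brute_force_project(t, w.window_sequence, w.upstream_len)
        )
        assert got == expected

    def test_nonnegative_offsets_agree_with_cdna_mapping(self, small_ctx, small_sim):
        tr = small_sim.transcriptome
        windows = build_windows(tr.annotations, tr.genome)
        tags = small_sim.pare[0].head(300)
        table = map_tags(tags, small_ctx, "lib", "PARE", 1)
        prof = project_tags_to_window(tags, windows, table.total_mapped_reads)
        in_range = prof[(prof["offset"] >= 0) & (prof["offset"] <= 180)]
        windowed = {
            (t, int(o)): int(c)
            for t, o, c in zip(
                in_range["transcript_id"], in_range["offset"], in_range["raw_count"]
            )
        }
        rec = table.records
        mapped = {
            (t, int(p)): int(c)
            for t, p, c in zip(rec["transcript_id"], rec["position"], rec["raw_count"])
            if p <= 180
        }
        assert windowed == mapped


def _win_profile(offset_rpm: dict, tid="T0", total=10_000):
    rows = [
        {"transcript_id": tid, "offset": o, "raw_count": int(v * total / 1e6), "rpm": v}
        for o, v in sorted(offset_rpm.items())
    ]
    return pd.DataFrame(rows)


class TestInferCapPosition:
    def test_call_when_filters_pass(self):
        p1 = _win_profile({-3: 40.0, 5: 30.0, 10: 30.0})
        p2 = _win_profile({-3: 35.0, 5: 28.0, 10: 27.0})
        calls, cascade = infer_cap_position(p1, p2)
        assert list(calls["cap_offset"]) == [-3]
        assert cascade["F3_ratio"] == 1

    def test_offset_disagreement_fails_f1(self):
        p1 = _win_profile({-3: 40.0, 1: 30.0})
        p2 = _win_profile({1: 41.0, -3: 30.0})
        calls, cascade = infer_cap_position(p1, p2)
        assert calls.empty and cascade["F1_same_offset"] == 0

    def test_low_ratio_fails_f3(self):
        p1 = _win_profile({-3: 15.0, 5: 40.0 - 15.0, 10: 30.0, 20: 20.0})
        p1.loc[p1["offset"] == -3, "rpm"] = 15.0
        base = {o: 12.0 for o in range(0, 80, 8)}
        base[-3] = 15.0  # ratio 15/(15+120) ~ 0.11
        p1 = _win_profile(base)
        p2 = _win_profile(base)
        calls, cascade = infer_cap_position(p1, p2)
        assert calls.empty and cascade["F2_abundance"] == 1 and cascade["F3_ratio"] == 0


class TestCallDecapped:
    def test_matching_offsets_called(self):
        cap = _win_profile({-10: 50.0, 30: 10.0})
        pare = _win_profile({-10: 45.0, 40: 12.0})
        cap_calls, _ = infer_cap_position(cap, cap)
        decap, cascade = call_decapped(cap_calls, pare, pare)
        assert list(decap["cap_offset"]) == [-10]
        assert cascade["decapped"] == 1

    def test_offset_mismatch_not_called(self):
        cap = _win_profile({-10: 50.0})
        pare = _win_profile({5: 45.0})
        cap_calls, _ = infer_cap_position(cap, cap)
        decap, _ = call_decapped(cap_calls, pare, pare)
        assert decap.empty

    def test_no_cap_call_excluded(self):
        cap_calls = pd.DataFrame(
            columns=["transcript_id", "cap_offset", "abundance_r1", "abundance_r2",
                     "ratio_r1", "ratio_r2"]
        )
        pare = _win_profile({-10: 45.0})
        decap, _ = call_decapped(cap_calls, pare, pare)
        assert decap.empty


class TestOffsetDistribution:
    def _calls(self, offsets):
        return pd.DataFrame(
            {"transcript_id": [f"T{i}" for i in range(len(offsets))],
             "cap_offset": offsets}
        )

    def test_all_at_zero(self):
        hist, summary = offset_distribution(self._calls([0] * 12))
        assert summary["frac_at_annotated_tss"] == 1.0
        assert hist.loc[0] == 12

    def test_uniform_plant_fraction_within_50(self):
        offsets = list(range(-60, 61))
        _, summary = offset_distribution(self._calls(offsets))
        assert summary["frac_within_50nt"] == pytest.approx(101 / 121)

    def test_histogram_conserves_calls(self):
        rng = np.random.default_rng(2)
        offsets = rng.integers(-200, 200, size=57).tolist()
        hist, summary = offset_distribution(self._calls(offsets))
        assert hist.sum() == 57 == summary["n_calls"]
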