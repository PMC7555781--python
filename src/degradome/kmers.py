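"""Vectorized exact / one-mismatch 20-mer matching.

Short 5'-end tags are matched against reference sequences (genome
contigs, cDNAs, or TSS windows) allowing at most one substitution. The
search uses half-and-half seeding: a 20-mer with <=1 mismatch must match
one of its two 10-nt halves exactly, so candidate loci are collected from
a sorted hash table of all reference 10-mers and then verified by a full
Hamming comparison. Everything is batch numpy; per-tag Python loops are
avoided so that libraries with ~10^6 reads collapse to a few array passes.

'N' (or any non-ACGT character) never matches anything, including itself.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

TAG_LEN = 20
_HALF = TAG_LEN // 2

# base-5 encoding: A=0 C=1 G=2 T=3, everything else 4
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _LUT[_b] = _i

_POW5_HALF = 5 ** np.arange(_HALF - 1, -1, -1, dtype=np.int64)
_POW5_FULL = 5 ** np.arange(TAG_LEN - 1, -1, -1, dtype=np.int64)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A0 C1 G2 T3, other 4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_tags(seqs) -> np.ndarray:
    """Encode equal-length tag sequences into an (N, L) uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, TAG_LEN), dtype=np.uint8)
    joined = "".join(seqs)
    arr = _LUT[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    return arr.reshape(len(seqs), -1)


def _rolling_hash(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-5 hash of every k-window of a code array (length n-k+1)."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    return windows.astype(np.int64) @ (5 ** np.arange(k - 1, -1, -1, dtype=np.int64))


def full_tag_hashes(tag_codes: np.ndarray) -> np.ndarray:
    return tag_codes.astype(np.int64) @ _POW5_FULL


def exact_kmer_hashes(seqs: Mapping[str, str], k: int = TAG_LEN) -> np.ndarray:
    """Sorted, unique base-5 hashes of every k-mer on both strands."""
    from .io import revcomp

    hashes = []
    for s in seqs.values():
        for strand_seq in (s, revcomp(s)):
            h = _rolling_hash(encode(strand_seq), k)
            if h.size:
                hashes.append(h)
    if not hashes:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(hashes))


class MismatchIndex:
    """One-mismatch lookup of 20-nt tags over named reference sequences.

    Parameters
    ----------
    refs : mapping of name -> sequence
        References searched on the given strand only. To search both
        strands, include reverse-complement entries explicitly.
    """

    def __init__(self, refs: Mapping[str, str]):
        self.names = list(refs)
        lengths = np.array([len(refs[n]) for n in self.names], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        self.codes = (
            np.concatenate([encode(refs[n]) for n in self.names])
            if self.names
            else np.empty(0, dtype=np.uint8)
        )
        # half-mer hashes at every global position whose window stays
        # within one reference sequence
        hashes = []
        gpos = []
        for i, n in enumerate(self.names):
            h = _rolling_hash(self.codes[self.offsets[i] : self.offsets[i + 1]], _HALF)
            if h.size:
                hashes.append(h)
                gpos.append(np.arange(self.offsets[i], self.offsets[i] + h.size))
        if hashes:
            allh = np.concatenate(hashes)
            allp = np.concatenate(gpos)
            order = np.argsort(allh, kind="stable")
            self._hash = allh[order]
            self._gpos = allp[order]
        else:
            self._hash = np.empty(0, dtype=np.int64)
            self._gpos = np.empty(0, dtype=np.int64)

    def query(
        self, tag_codes: np.ndarray, max_mismatch: int = 1
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Find all reference loci within ``max_mismatch`` of each tag.

        Returns ``(tag_idx, ref_idx, pos, mismatches)`` arrays, one entry
        per (tag, locus) hit, deduplicated.
        """
        if tag_codes.ndim != 2 or tag_codes.shape[1] != TAG_LEN:
            raise ValueError("tag_codes must be (N, 20)")
        n_tags = tag_codes.shape[0]
        if n_tags == 0 or self._hash.size == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e, e, e

        cand_tag = []
        cand_gstart = []
        t64 = tag_codes.astype(np.int64)
        for off in (0, _HALF):
            h = t64[:, off : off + _HALF] @ _POW5_HALF
            lo = np.searchsorted(self._hash, h, side="left")
            hi = np.searchsorted(self._hash, h, side="right")
            counts = hi - lo
            total = int(counts.sum())
            if total == 0:
                continue
            tag_rep = np.repeat(np.arange(n_tags), counts)
            cum = np.cumsum(counts)
            flat = np.arange(total) - np.repeat(cum - counts, counts) + np.repeat(lo, counts)
            cand_tag.append(tag_rep)
            cand_gstart.append(self._gpos[flat] - off)
        if not cand_tag:
            e = np.empty(0, dtype=np.int64)
            return e, e, e, e

        tag_idx = np.concatenate(cand_tag)
        gstart = np.concatenate(cand_gstart)

        # deduplicate (tag, locus) pairs found via both halves
        total_len = int(self.offsets[-1])
        key = tag_idx * (total_len + TAG_LEN) + gstart
        _, keep = np.unique(key, return_index=True)
        tag_idx, gstart = tag_idx[keep], gstart[keep]

        # candidate window must lie within a single reference sequence
        valid = gstart >= 0
        seq_idx = np.searchsorted(self.offsets, gstart, side="right") - 1
        seq_idx = np.clip(seq_idx, 0, len(self.names) - 1)
        valid &= gstart + TAG_LEN <= self.offsets[seq_idx + 1]
        tag_idx, gstart, seq_idx = tag_idx[valid], gstart[valid], seq_idx[valid]
        if tag_idx.size == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e, e, e

        ref_win = self.codes[gstart[:, None] + np.arange(TAG_LEN)]
        tag_win = tag_codes[tag_idx]
        mm = ((ref_win != tag_win) | (ref_win >= 4) | (tag_win >= 4)).sum(axis=1)
        ok = mm <= max_mismatch
        return (
            tag_idx[ok],
            seq_idx[ok],
            (gstart - self.offsets[seq_idx])[ok],
            mm[ok].astype(np.int64),
        )

    def hit_counts(
        self, tag_codes: np.ndarray, max_mismatch: int = 1, cap: int | None = None
    ) -> np.ndarray:
        """Number of reference loci per tag (used by the multi-hit filter)."""
        tag_idx, _, _, _ = self.query(tag_codes, max_mismatch=max_mismatch)
        counts = np.bincount(tag_idx, minlength=tag_codes.shape[0])
        if cap is not None:
            counts = np.minimum(counts, cap)
        return counts
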