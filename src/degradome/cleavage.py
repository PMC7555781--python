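"""Endonucleolytic cleavage calling via the Max-seq filter cascade.

An endonucleolytic cut leaves a discrete 5'-monophosphate end that
accumulates as a dominant tag peak (the Max-seq) on the transcript,
against the diffuse background of exonucleolytic decay intermediates.
Candidates are called with four filters applied in order:

F1  reproducible position: both replicates' Max-seq at the same cDNA
    coordinate;
F2  reliable decay abundance: SOA (sum of tag abundances on the
    transcript, RPM) above ``soa_min``;
F3  Max-seq abundance above ``max_min`` (RPM);
F4  prominence: Max-seq abundance / SOA above ``ratio_min``.

F2-F4 default to the replicate mean; ``per_replicate=True`` requires
each replicate to pass on its own. Thresholds are strict inequalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .abundance import DecayProfile

DEFAULT_SOA_MIN = 50.0
DEFAULT_MAX_MIN = 10.0
DEFAULT_RATIO_MIN = 0.2


@dataclass(frozen=True)
class MaxSeq:
    """The most abundant tag position on one transcript profile."""

    transcript_id: str
    position: int
    abundance: float
    soa: float
    replicate: int | None = None

    @property
    def ratio(self) -> float:
        return self.abundance / self.soa


def find_max_seq(profile: DecayProfile) -> MaxSeq:
    """Maximal-RPM position; ties broken toward the 5'-most coordinate."""
    if len(profile.rpm) == 0:
        raise ValueError(f"{profile.transcript_id}: empty profile has no Max-seq")
    rpm = profile.rpm.sort_index()
    pos = int(rpm.idxmax())  # first occurrence of the max = smallest coordinate
    return MaxSeq(
        transcript_id=profile.transcript_id,
        position=pos,
        abundance=float(rpm.loc[pos]),
        soa=float(rpm.sum()),
        replicate=profile.replicate,
    )


def call_endonucleolytic(
    profiles_rep1: Mapping[str, DecayProfile],
    profiles_rep2: Mapping[str, DecayProfile],
    soa_min: float = DEFAULT_SOA_MIN,
    max_min: float = DEFAULT_MAX_MIN,
    ratio_min: float = DEFAULT_RATIO_MIN,
    per_replicate: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the four-filter cascade over both replicates.

    Returns the calls table (transcript_id, position, per-replicate
    abundance/soa/ratio, length) and the per-filter survivor counts.
    """
    shared = sorted(
        t
        for t in set(profiles_rep1) & set(profiles_rep2)
        if len(profiles_rep1[t].rpm) and len(profiles_rep2[t].rpm)
    )
    cascade = {"input": len(shared)}

    rows = []
    for t in shared:
        m1 = find_max_seq(profiles_rep1[t])
        m2 = find_max_seq(profiles_rep2[t])
        if m1.position != m2.position:
            continue
        rows.append((t, m1, m2))
    cascade["F1_same_position"] = len(rows)

    def agg(v1: float, v2: float, threshold: float) -> bool:
        if per_replicate:
            return v1 > threshold and v2 > threshold
        return (v1 + v2) / 2 > threshold

    rows = [(t, m1, m2) for t, m1, m2 in rows if agg(m1.soa, m2.soa, soa_min)]
    cascade["F2_soa"] = len(rows)
    rows = [
        (t, m1, m2) for t, m1, m2 in rows if agg(m1.abundance, m2.abundance, max_min)
    ]
    cascade["F3_max_abundance"] = len(rows)
    rows = [(t, m1, m2) for t, m1, m2 in rows if agg(m1.ratio, m2.ratio, ratio_min)]
    cascade["F4_ratio"] = len(rows)

    calls = pd.DataFrame(
        [
            {
                "transcript_id": t,
                "position": m1.position,
                "abundance_r1": m1.abundance,
                "abundance_r2": m2.abundance,
                "soa_r1": m1.soa,
                "soa_r2": m2.soa,
                "ratio_r1": m1.ratio,
                "ratio_r2": m2.ratio,
                "length": profiles_rep1[t].length,
            }
            for t, m1, m2 in rows
        ],
        columns=[
            "transcript_id",
            "position",
            "abundance_r1",
            "abundance_r2",
            "soa_r1",
            "soa_r2",
            "ratio_r1",
            "ratio_r2",
            "length",
        ],
    )
    return calls, cascade


def percentile_bin(position: int, length: int) -> int:
    """1..100 bin of a cleavage position along the cDNA (ceil of percent)."""
    b = math.ceil(100 * (position + 1) / length)
    return min(max(b, 1), 100)


def percentile_distribution(calls: pd.DataFrame) -> pd.Series:
    """100-bin histogram of cleavage positions as percentiles of length."""
    bins = [
        percentile_bin(int(p), int(l))
        for p, l in zip(calls["position"], calls["length"])
    ]
    counts = np.bincount(bins, minlength=101)[1:101]
    return pd.Series(counts, index=pd.RangeIndex(1, 101, name="percentile"))
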