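"""Descriptive outputs: D-plots, replicate correlations, run summaries.

Every figure has a TSV twin carrying the plotted series, so numeric
checks never parse images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .abundance import DecayProfile
from .cleavage import find_max_seq
from .io import TranscriptAnnotation


@dataclass
class DPlotData:
    transcript_id: str
    series: pd.DataFrame  # position, rpm per replicate, optional coverage
    region_boundaries: tuple[int, int]  # (utr5_end, cds_end)
    max_positions: dict[int, int | None]  # replicate -> Max-seq position


def make_dplot(
    profiles: dict[int, DecayProfile],
    annotation: TranscriptAnnotation,
    rnaseq_coverage: pd.Series | None = None,
    out_prefix: str | Path | None = None,
) -> DPlotData:
    """Per-position decay plot for one transcript, with TSV twin.

    ``profiles`` maps replicate number to the transcript's decay
    profile. The Max-seq marker is placed per replicate; empty profiles
    plot an empty series.
    """
    positions = pd.RangeIndex(0, annotation.length, name="position")
    series = pd.DataFrame(index=positions)
    max_positions: dict[int, int | None] = {}
    for rep, profile in sorted(profiles.items()):
        col = profile.rpm.reindex(positions, fill_value=0.0)
        series[f"rpm_r{rep}"] = col
        max_positions[rep] = (
            find_max_seq(profile).position if len(profile.rpm) else None
        )
    if rnaseq_coverage is not None:
        series["rnaseq_coverage"] = rnaseq_coverage.reindex(positions, fill_value=0.0)

    data = DPlotData(
        transcript_id=annotation.transcript_id,
        series=series.reset_index(),
        region_boundaries=(annotation.utr5_end, annotation.cds_end),
        max_positions=max_positions,
    )
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        data.series.to_csv(
            f"{out_prefix}.tsv", sep="\t", index=False, float_format="%.10g"
        )
        _render_dplot(data, annotation, f"{out_prefix}.png")
    return data


def _render_dplot(data: DPlotData, annotation: TranscriptAnnotation, path: str) -> None:
    fig, ax = plt.subplots(figsize=(8, 3))
    for col in data.series.columns:
        if col.startswith("rpm_r"):
            ax.vlines(
                data.series["position"],
                0,
                data.series[col],
                label=col,
                alpha=0.6,
            )
    for rep, pos in data.max_positions.items():
        if pos is not None:
            ax.plot(
                pos,
                data.series.set_index("position")[f"rpm_r{rep}"].loc[pos],
                "r*",
                markersize=10,
            )
    u5, cend = data.region_boundaries
    for x in (u5, cend):
        ax.axvline(x, color="grey", linestyle=":", linewidth=0.8)
    ax.set_xlabel("cDNA position (nt)")
    ax.set_ylabel("abundance (RPM)")
    ax.set_title(data.transcript_id)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def replicate_correlation(
    values_rep1, values_rep2, log_transform: bool = False
) -> float:
    """Squared Pearson correlation between paired replicate values.

    With ``log_transform`` the values are log10(x + 1) first (abundance
    scatter plots are conventionally log-scaled).
    """
    x = np.asarray(values_rep1, dtype=float)
    y = np.asarray(values_rep2, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need paired arrays of length >= 2")
    if log_transform:
        x = np.log10(x + 1.0)
        y = np.log10(y + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pct(part: int, whole: int):
    return round(100.0 * part / whole, 1) if whole else "n/a"


def summary_tables(
    stability: pd.DataFrame | None = None,
    cleavage_calls: pd.DataFrame | None = None,
    cap_calls: pd.DataFrame | None = None,
    decap_calls: pd.DataFrame | None = None,
) -> dict:
    """Headline counts and cross-tabulations across the module outputs.

    A pure function of its inputs; missing sections are reported as
    absent rather than failing.
    """
    out: dict = {"absent_sections": []}
    cls = None
    if stability is not None:
        cls = stability.set_index("transcript_id")["class"]
        out["stability"] = {
            "n_transcripts": int(len(stability)),
            "stable": int((cls == "stable").sum()),
            "unstable": int((cls == "unstable").sum()),
            "neither": int((cls == "neither").sum()),
        }
    else:
        out["absent_sections"].append("stability")

    if cleavage_calls is not None:
        sec = {"n_calls": int(len(cleavage_calls))}
        if cls is not None:
            called = cleavage_calls["transcript_id"]
            in_cls = cls.reindex(called).fillna("neither")
            n_unstable = int((in_cls == "unstable").sum())
            n_stable = int((in_cls == "stable").sum())
            sec["cleaved_and_unstable"] = n_unstable
            sec["cleaved_and_unstable_pct"] = _pct(n_unstable, len(cleavage_calls))
            sec["cleaved_and_stable"] = n_stable
        out["cleavage"] = sec
    else:
        out["absent_sections"].append("cleavage")

    if cap_calls is not None:
        out["cap"] = {"n_calls": int(len(cap_calls))}
    else:
        out["absent_sections"].append("cap")

    if decap_calls is not None:
        sec = {"n_calls": int(len(decap_calls))}
        if cls is not None:
            in_cls = cls.reindex(decap_calls["transcript_id"]).fillna("neither")
            n_unstable = int((in_cls == "unstable").sum())
            n_stable = int((in_cls == "stable").sum())
            sec["decapped_and_unstable"] = n_unstable
            sec["decapped_and_unstable_pct"] = _pct(n_unstable, len(decap_calls))
            sec["decapped_and_stable"] = n_stable
            sec["decapped_and_stable_pct"] = _pct(n_stable, len(decap_calls))
        out["decap"] = sec
    else:
        out["absent_sections"].append("decap")
    return out


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
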