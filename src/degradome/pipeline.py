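"""End-to-end driver: simulate -> preprocess -> classify -> call -> summarize.

Used by the analysis scripts and the acceptance machinery; each stage is
the corresponding module's public API, so a pipeline run is exactly the
sum of its testable parts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import abundance as ab
from . import cleavage as cl
from . import decapping as dc
from . import report as rp
from . import simulate as sim
from . import stability as st
from .preprocess import PreprocessContext, PreprocessResult, run_preprocess


@dataclass
class PipelineResult:
    config: sim.SimConfig
    simulation: sim.SimOutput
    pare: list[PreprocessResult]
    cpare: list[PreprocessResult]
    abundance: pd.DataFrame
    stability: pd.DataFrame
    stability_summary: st.StabilitySummary
    cleavage_calls: pd.DataFrame
    cleavage_cascade: dict
    percentile_hist: pd.Series
    cap_calls: pd.DataFrame
    cap_cascade: dict
    decap_calls: pd.DataFrame
    decap_cascade: dict
    offset_hist: pd.Series
    offset_summary: dict
    summary: dict = field(default_factory=dict)


def run_pipeline(
    config: sim.SimConfig,
    outdir: str | Path | None = None,
    fdr_max: float = st.DEFAULT_FDR,
    lfc_min: float = st.DEFAULT_LFC,
    min_abundance: float = st.DEFAULT_MIN_ABUNDANCE,
) -> PipelineResult:
    """Full synthetic run with the study's thresholds; optionally writes TSVs."""
    simulation = sim.simulate_all(config)
    tr = simulation.transcriptome
    ctx = PreprocessContext(
        genome=tr.genome,
        mito={"chrM": tr.genome["chrM"]},
        annotations=tr.annotations,
    )

    pare = [
        run_preprocess(lib, ctx, f"PARE_r{r}", "PARE", r)
        for r, lib in zip((1, 2), simulation.pare)
    ]
    cpare = [
        run_preprocess(lib, ctx, f"CPARE_r{r}", "CPARE", r)
        for r, lib in zip((1, 2), simulation.cpare)
    ]

    abund = ab.abundance_table(
        [p.table for p in pare], simulation.rnaseq, tr.annotations
    )
    stability, stab_summary = st.classify_stability(
        abund, fdr_max=fdr_max, lfc_min=lfc_min, min_abundance=min_abundance
    )

    profiles = [ab.profiles_from_table(p.table, tr.annotations) for p in pare]
    cleavage_calls, cleavage_cascade = cl.call_endonucleolytic(
        profiles[0], profiles[1]
    )
    percentile_hist = cl.percentile_distribution(cleavage_calls)

    windows = dc.build_windows(tr.annotations, tr.genome)
    cpare_win = [
        dc.project_tags_to_window(
            p.filtered_tags, windows, p.table.total_mapped_reads
        )
        for p in cpare
    ]
    pare_win = [
        dc.project_tags_to_window(
            p.filtered_tags, windows, p.table.total_mapped_reads
        )
        for p in pare
    ]
    cap_calls, cap_cascade = dc.infer_cap_position(cpare_win[0], cpare_win[1])
    decap_calls, decap_cascade = dc.call_decapped(
        cap_calls, pare_win[0], pare_win[1]
    )
    offset_hist, offset_summary = dc.offset_distribution(cap_calls)

    summary = rp.summary_tables(
        stability=stability,
        cleavage_calls=cleavage_calls,
        cap_calls=cap_calls,
        decap_calls=decap_calls,
    )

    result = PipelineResult(
        config=config,
        simulation=simulation,
        pare=pare,
        cpare=cpare,
        abundance=abund,
        stability=stability,
        stability_summary=stab_summary,
        cleavage_calls=cleavage_calls,
        cleavage_cascade=cleavage_cascade,
        percentile_hist=percentile_hist,
        cap_calls=cap_calls,
        cap_cascade=cap_cascade,
        decap_calls=decap_calls,
        decap_cascade=decap_cascade,
        offset_hist=offset_hist,
        offset_summary=offset_summary,
        summary=summary,
    )
    if outdir is not None:
        write_pipeline_outputs(result, outdir)
    return result


def write_pipeline_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim.write_outputs(result.simulation, outdir / "simulated")
    for p in result.pare + result.cpare:
        p.table.to_tsv(outdir / f"tags_{p.table.library_id}.tsv")
    result.abundance.to_csv(
        outdir / "abundance.tsv", sep="\t", index=False, float_format="%.10g"
    )
    result.stability.to_csv(
        outdir / "stability.tsv", sep="\t", index=False, float_format="%.10g"
    )
    result.cleavage_calls.to_csv(
        outdir / "cleavage_calls.tsv", sep="\t", index=False, float_format="%.10g"
    )
    result.percentile_hist.rename("count").to_csv(outdir / "cleavage_percentiles.tsv", sep="\t")
    result.cap_calls.to_csv(
        outdir / "cap_calls.tsv", sep="\t", index=False, float_format="%.10g"
    )
    result.decap_calls.to_csv(
        outdir / "decap_calls.tsv", sep="\t", index=False, float_format="%.10g"
    )
    result.offset_hist.rename("count").to_csv(outdir / "cap_offsets.tsv", sep="\t")
    cascade = {
        "cleavage": result.cleavage_cascade,
        "cap": result.cap_cascade,
        "decap": result.decap_cascade,
        "stability": result.stability_summary.as_dict(),
        "offset_summary": result.offset_summary,
    }
    (outdir / "cascades.json").write_text(
        json.dumps(cascade, indent=2, sort_keys=True) + "\n"
    )
    rp.write_summary(result.summary, outdir / "summary.json")
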