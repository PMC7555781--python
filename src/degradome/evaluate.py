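"""Recovery and specificity metrics of a synthetic run against its truth.

Used to benchmark the calling pipeline on generated data where the
planted signals are known exactly.
"""

from __future__ import annotations

import numpy as np

from .pipeline import PipelineResult
from .report import replicate_correlation


def stability_metrics(result: PipelineResult) -> dict:
    truth = result.simulation.truth.table
    merged = result.stability.merge(truth, on="transcript_id")
    out: dict = {"n": len(merged)}
    for cls in ("stable", "unstable"):
        planted = merged[merged["stability_class"] == cls]
        out[f"n_planted_{cls}"] = len(planted)
        out[f"sensitivity_{cls}"] = (
            float((planted["class"] == cls).mean()) if len(planted) else float("nan")
        )
    swaps = (
        ((merged["stability_class"] == "stable") & (merged["class"] == "unstable"))
        | ((merged["stability_class"] == "unstable") & (merged["class"] == "stable"))
    ).sum()
    out["class_swaps"] = int(swaps)
    null_like = merged[merged["stability_class"] == "neither"]
    out["neither_misclass_rate"] = (
        float((null_like["class"] != "neither").mean())
        if len(null_like)
        else float("nan")
    )
    return out


def cleavage_metrics(result: PipelineResult) -> dict:
    truth = result.simulation.truth.table
    planted = truth[truth["planted_cleavage_position"] >= 0]
    calls = result.cleavage_calls
    hit = planted.merge(calls, on="transcript_id")
    unplanted_tids = set(truth.loc[truth["planted_cleavage_position"] < 0,
                                   "transcript_id"])
    # decap-planted transcripts carry a genuine 5'-end peak; exclude them
    # from the cleavage false-positive denominator
    decapped = set(truth.loc[truth["is_decapped"], "transcript_id"])
    fp_pool = unplanted_tids - decapped
    fp = sum(t in fp_pool for t in calls["transcript_id"])
    return {
        "n_planted": len(planted),
        "recall": float(len(hit) / len(planted)) if len(planted) else float("nan"),
        "exact_position_rate": (
            float((hit["position"] == hit["planted_cleavage_position"]).mean())
            if len(hit)
            else float("nan")
        ),
        "false_positive_rate": float(fp / len(fp_pool)) if fp_pool else float("nan"),
        "n_calls": len(calls),
    }


def decap_metrics(result: PipelineResult) -> dict:
    truth = result.simulation.truth.table
    planted = truth[truth["is_decapped"]]
    calls = result.decap_calls
    hit = planted.merge(calls, on="transcript_id")
    cleaved_only = set(truth.loc[truth["planted_cleavage_position"] >= 0,
                                 "transcript_id"])
    false_on_cleaved = sum(t in cleaved_only for t in calls["transcript_id"])
    offset_ok = True
    if len(hit):
        offset_ok = bool((hit["cap_offset"] == hit["planted_cap_position"]).all())
    return {
        "n_planted": len(planted),
        "recall": float(len(hit) / len(planted)) if len(planted) else float("nan"),
        "offsets_match_planted": offset_ok,
        "calls_on_cleavage_only_transcripts": int(false_on_cleaved),
        "n_calls": len(calls),
    }


def correlation_metrics(result: PipelineResult) -> dict:
    ab = result.abundance
    out = {}
    out["rnaseq_r2"] = replicate_correlation(
        ab["fpkm_r1"], ab["fpkm_r2"], log_transform=True
    )
    out["pare_r2"] = replicate_correlation(
        ab["dpkm_r1"], ab["dpkm_r2"], log_transform=True
    )
    return out


def null_metrics(result: PipelineResult) -> dict:
    """Specificity on a run with nothing planted."""
    n = len(result.stability)
    non_neither = int((result.stability["class"] != "neither").sum())
    return {
        "n": n,
        "non_neither_rate": float(non_neither / n) if n else float("nan"),
        "cleavage_call_rate": float(len(result.cleavage_calls) / n) if n else float("nan"),
        "decap_call_rate": float(len(result.decap_calls) / n) if n else float("nan"),
    }


def evaluate_run(result: PipelineResult) -> dict:
    return {
        "stability": stability_metrics(result),
        "cleavage": cleavage_metrics(result),
        "decap": decap_metrics(result),
        "correlation": correlation_metrics(result),
        "offset_summary": result.offset_summary,
        "cascades": {
            "cleavage": result.cleavage_cascade,
            "cap": result.cap_cascade,
            "decap": result.decap_cascade,
        },
    }
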