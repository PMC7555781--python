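#!/usr/bin/env python
"""Descriptive outputs of the run: D-plots for representative transcripts
(one planted cleaved, one decapped, one neither), the run summary with
class/call cross-tabulations, and the replicate-correlation numbers.

Writes D-plot PNG+TSV pairs under results/run/dplots/ and summary.json.
"""

from pathlib import Path

import pandas as pd

from degradome.abundance import profiles_from_table
from degradome.io import read_fasta, read_gtf
from degradome.preprocess import TagTable
from degradome.report import make_dplot, summary_tables, write_summary

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    sim = RUN / "simulated"
    annots = read_gtf(sim / "annotation.gtf", read_fasta(sim / "cdna.fa"))
    tables = [TagTable.from_tsv(RUN / f"tags_PARE_r{r}.tsv") for r in (1, 2)]
    profiles = [profiles_from_table(t, annots) for t in tables]
    truth = pd.read_csv(sim / "truth.tsv", sep="\t").set_index("transcript_id")

    picks = {}
    for tid in truth.index:
        row = truth.loc[tid]
        if row["planted_cleavage_position"] >= 0 and "cleaved" not in picks:
            picks["cleaved"] = tid
        elif row["is_decapped"] and "decapped" not in picks:
            picks["decapped"] = tid
        elif (row["stability_class"] == "neither"
              and row["planted_cleavage_position"] < 0
              and not row["is_decapped"] and "background" not in picks):
            picks["background"] = tid
    for label, tid in picks.items():
        data = make_dplot(
            {r: profiles[r - 1][tid] for r in (1, 2)},
            annots[tid],
            out_prefix=RUN / "dplots" / f"{label}_{tid}",
        )
        print(f"{label} {tid}: Max-seq positions {data.max_positions} "
              f"(planted cleavage at "
              f"{int(truth.loc[tid, 'planted_cleavage_position'])})")

    def _maybe(name):
        p = RUN / name
        return pd.read_csv(p, sep="\t") if p.exists() else None

    summary = summary_tables(
        stability=_maybe("stability.tsv"),
        cleavage_calls=_maybe("cleavage_calls.tsv"),
        cap_calls=_maybe("cap_calls.tsv"),
        decap_calls=_maybe("decap_calls.tsv"),
    )
    write_summary(summary, RUN / "summary.json")
    print("summary:", summary)


if __name__ == "__main__":
    main()
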