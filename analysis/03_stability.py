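#!/usr/bin/env python
"""Compare steady-state (FPKM) and decay (DPKM) abundance per transcript and
classify stability with the exact count test, BH FDR < 0.01 and
|log2(FPKM/DPKM)| > 2.5.

Writes abundance.tsv and stability.tsv; prints class counts, replicate R^2
and the recovery against the planted truth.
"""

import json
from pathlib import Path

import pandas as pd

from degradome.abundance import abundance_table
from degradome.io import read_fasta, read_gtf
from degradome.preprocess import TagTable
from degradome.report import replicate_correlation
from degradome.stability import classify_stability

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    sim = RUN / "simulated"
    annots = read_gtf(sim / "annotation.gtf", read_fasta(sim / "cdna.fa"))
    pare = [TagTable.from_tsv(RUN / f"tags_PARE_r{r}.tsv") for r in (1, 2)]
    rnaseq = pd.read_csv(sim / "rnaseq_counts.tsv", sep="\t")

    abund = abundance_table(pare, rnaseq, annots)
    abund.to_csv(RUN / "abundance.tsv", sep="\t", index=False, float_format="%.10g")
    (RUN / "abundance_totals.json").write_text(json.dumps({
        "rna_totals": abund.attrs["rna_totals"],
        "pare_totals": abund.attrs["pare_totals"],
    }) + "\n")

    result, summary = classify_stability(abund)
    result.to_csv(RUN / "stability.tsv", sep="\t", index=False, float_format="%.10g")
    print("class counts:", summary.as_dict())
    print("RNA-seq replicate R^2: %.3f" % replicate_correlation(
        abund["fpkm_r1"], abund["fpkm_r2"], log_transform=True))
    print("PARE replicate R^2: %.3f" % replicate_correlation(
        abund["dpkm_r1"], abund["dpkm_r2"], log_transform=True))

    truth = pd.read_csv(sim / "truth.tsv", sep="\t")
    merged = result.merge(truth, on="transcript_id")
    xtab = pd.crosstab(merged["stability_class"], merged["class"])
    print("planted class (rows) vs called class (columns):")
    print(xtab)


if __name__ == "__main__":
    main()
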