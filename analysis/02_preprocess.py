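#!/usr/bin/env python
"""Standardize and map the four tag libraries from the simulated study.

Applies the SSR / genomic multi-hit / mitochondrial filter cascade, maps
surviving tags to cDNAs at one mismatch and normalizes to RPM. Writes
per-library TagTable TSVs, the filtered tag lists (inputs to the TSS-window
projection of step 05) and the filter statistics.
"""

import json
from pathlib import Path

from degradome.io import read_fasta, read_gtf, read_tags_tsv, write_tags_tsv
from degradome.preprocess import PreprocessContext, run_preprocess

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    sim = RUN / "simulated"
    genome = read_fasta(sim / "genome.fa")
    annots = read_gtf(sim / "annotation.gtf", read_fasta(sim / "cdna.fa"))
    ctx = PreprocessContext(
        genome=genome, mito={"chrM": genome["chrM"]}, annotations=annots
    )
    all_stats = {}
    for lib_type, stem in (("PARE", "pare"), ("CPARE", "cpare")):
        for rep in (1, 2):
            lib_id = f"{lib_type}_r{rep}"
            raw = read_tags_tsv(sim / f"{stem}_rep{rep}.tsv")
            res = run_preprocess(raw, ctx, lib_id, lib_type, rep)
            res.table.to_tsv(RUN / f"tags_{lib_id}.tsv")
            write_tags_tsv(res.filtered_tags, RUN / f"filtered_{lib_id}.tsv")
            all_stats[lib_id] = res.stats
            print(f"{lib_id}: {res.stats}")
    (RUN / "preprocess_stats.json").write_text(
        json.dumps(all_stats, indent=2) + "\n"
    )


if __name__ == "__main__":
    main()
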