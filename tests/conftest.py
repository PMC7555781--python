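import numpy as np
import pandas as pd
import pytest

from degradome.io import TranscriptAnnotation
from degradome.preprocess import PreprocessContext
from degradome.simulate import SimConfig, simulate_all

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def make_annotation(seq: str, transcript_id: str = "T0", strand: str = "+",
                    chromosome: str = "chr1", start: int = 0) -> TranscriptAnnotation:
    L = len(seq)
    return TranscriptAnnotation(
        transcript_id=transcript_id,
        gene_id=f"G_{transcript_id}",
        chromosome=chromosome,
        strand=strand,
        start=start,
        end=start + L,
        cdna_sequence=seq,
        utr5_end=min(30, L // 4),
        cds_end=max(min(30, L // 4), L - L // 4),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic run shared across tests."""
    return simulate_all(SimConfig(n_transcripts=30, library_size=20000, seed=7))


@pytest.fixture(scope="session")
def small_ctx(small_sim):
    tr = small_sim.transcriptome
    return PreprocessContext(
        genome=tr.genome,
        mito={"chrM": tr.genome["chrM"]},
        annotations=tr.annotations,
    )


def tags_df(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        {"sequence": [s for s, _ in pairs], "count": [c for _, c in pairs]}
    )
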