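"""Transcript stability classification.

Steady-state abundance (RNA-seq) and decay abundance (5'-end tags) are
compared per transcript with an exact conditional count test under a
negative-binomial model, followed by Benjamini-Hochberg FDR control and
three filters (abundance, significance, fold change). A transcript with
significantly higher decay output than steady-state level is called
unstable; the converse, stable.

The fold change log2(FPKM/DPKM) equals the library-normalized count
ratio because cDNA length cancels, so the test operates directly on
counts: replicate counts are equalized to the geometric-mean library
size, pooled within condition, and the distribution of the RNA share of
the pooled total is enumerated conditionally. With a common dispersion
phi, the sum of the two replicate counts per condition is negative
binomial with shape r = 2/phi, and the conditional law of A given
A + B = n is proportional to C(a+r-1, a) * C(n-a+r-1, n-a) -- the mean
cancels. With phi = 0 this degenerates to Binomial(n, 1/2): the exact
conditional binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

DEFAULT_FDR = 0.01
DEFAULT_LFC = 2.5
DEFAULT_MIN_ABUNDANCE = 1.0


def _equalized_pooled(
    counts: Sequence[float], lib_sizes: Sequence[float], common: float
) -> int:
    scaled = [c * common / s for c, s in zip(counts, lib_sizes)]
    return int(round(sum(scaled)))


def exact_count_test(
    rna_counts: Sequence[float],
    pare_counts: Sequence[float],
    rna_lib_sizes: Sequence[float],
    pare_lib_sizes: Sequence[float],
    dispersion: float = 0.0,
) -> float:
    """Two-sided exact test for unequal relative abundance.

    Counts are equalized to the geometric-mean library size and pooled
    per condition; the p-value sums all conditional outcomes at most as
    probable as the observed one. Returns p in (0, 1]; all-zero counts
    give p = 1 by convention.
    """
    sizes = np.asarray(list(rna_lib_sizes) + list(pare_lib_sizes), dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("library sizes must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    common = float(np.exp(np.mean(np.log(sizes))))
    a = _equalized_pooled(rna_counts, rna_lib_sizes, common)
    b = _equalized_pooled(pare_counts, pare_lib_sizes, common)
    n = a + b
    if n == 0:
        return 1.0

    k = np.arange(n + 1)
    if dispersion == 0.0:
        logp = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1) + n * np.log(0.5)
    else:
        r = 2.0 / dispersion  # pooled shape over two replicates
        logp = (
            gammaln(k + r)
            - gammaln(k + 1)
            + gammaln(n - k + r)
            - gammaln(n - k + 1)
        )
    logp = logp - logsumexp(logp)
    p = float(np.exp(logsumexp(logp[logp <= logp[a] + 1e-10])))
    return min(p, 1.0)


def estimate_dispersion(
    counts: np.ndarray, lib_sizes: Sequence[float], min_mean: float = 50.0
) -> float:
    """Method-of-moments common dispersion from replicated counts.

    ``counts`` is (n_transcripts, n_replicates) for one condition.
    Per-transcript phi = (s^2 - m) / m^2 on library-size-equalized
    counts, which is unbiased per transcript; the mean over sufficiently
    expressed transcripts is returned, floored at 0. (The median would
    be badly biased low with two replicates: s^2 has one degree of
    freedom and a strongly right-skewed law.)
    """
    counts = np.asarray(counts, dtype=float)
    sizes = np.asarray(lib_sizes, dtype=float)
    common = np.exp(np.mean(np.log(sizes)))
    eq = counts * (common / sizes)
    m = eq.mean(axis=1)
    s2 = eq.var(axis=1, ddof=1)
    use = m >= min_mean
    if not use.any():
        return 0.0
    phi = (s2[use] - m[use]) / m[use] ** 2
    return float(max(np.mean(phi), 0.0))


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class StabilitySummary:
    n_stable: int
    n_unstable: int
    n_neither: int
    dispersion: float

    def as_dict(self) -> dict:
        return {
            "stable": self.n_stable,
            "unstable": self.n_unstable,
            "neither": self.n_neither,
            "dispersion": self.dispersion,
        }


def classify_stability(
    abundance: pd.DataFrame,
    fdr_max: float = DEFAULT_FDR,
    lfc_min: float = DEFAULT_LFC,
    min_abundance: float = DEFAULT_MIN_ABUNDANCE,
    dispersion: float | None = None,
) -> tuple[pd.DataFrame, StabilitySummary]:
    """Apply the abundance / significance / fold-change filter triplet.

    ``abundance`` is the table from :func:`degradome.abundance.abundance_table`
    (carrying library totals in attrs). When ``dispersion`` is None a
    common dispersion is estimated across both assays by method of
    moments. Returns the per-transcript result table (order follows the
    input) and per-class counts.

    Classes: stable requires log2(FPKM/DPKM) > +lfc_min, unstable
    < -lfc_min, both with FDR < fdr_max and mean FPKM or mean DPKM >=
    min_abundance; everything else is neither.
    """
    df = abundance.sort_values("transcript_id", ignore_index=True)
    rna_totals = df.attrs.get("rna_totals") or abundance.attrs["rna_totals"]
    pare_totals = df.attrs.get("pare_totals") or abundance.attrs["pare_totals"]

    rna = df[["rna_count_r1", "rna_count_r2"]].to_numpy(dtype=float)
    pare = df[["pare_count_r1", "pare_count_r2"]].to_numpy(dtype=float)

    if dispersion is None:
        dispersion = max(
            estimate_dispersion(rna, rna_totals),
            estimate_dispersion(pare, pare_totals),
        )

    pvals = np.array(
        [
            exact_count_test(rna[i], pare[i], rna_totals, pare_totals, dispersion)
            for i in range(len(df))
        ]
    )
    fdr = adjust_fdr(pvals)

    # pooled fold change; 0.5 pseudo-count only when one side is zero
    rna_pool = rna.sum(axis=1)
    pare_pool = pare.sum(axis=1)
    rna_rate = rna_pool / sum(rna_totals)
    pare_rate = pare_pool / sum(pare_totals)
    zero_sided = (rna_pool == 0) ^ (pare_pool == 0)
    rna_adj = np.where(zero_sided & (rna_pool == 0), 0.5 / sum(rna_totals), rna_rate)
    pare_adj = np.where(
        zero_sided & (pare_pool == 0), 0.5 / sum(pare_totals), pare_rate
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(rna_adj / pare_adj)
    log2fc = np.where((rna_pool == 0) & (pare_pool == 0), 0.0, log2fc)

    mean_fpkm = df[["fpkm_r1", "fpkm_r2"]].mean(axis=1).to_numpy()
    mean_dpkm = df[["dpkm_r1", "dpkm_r2"]].mean(axis=1).to_numpy()
    passes_abundance = (mean_fpkm >= min_abundance) | (mean_dpkm >= min_abundance)

    significant = (fdr < fdr_max) & passes_abundance
    cls = np.where(
        significant & (log2fc > lfc_min),
        "stable",
        np.where(significant & (log2fc < -lfc_min), "unstable", "neither"),
    )
    result = pd.DataFrame(
        {
            "transcript_id": df["transcript_id"],
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "passes_abundance": passes_abundance,
            "class": cls,
        }
    )
    # restore caller's row order
    result = (
        result.set_index("transcript_id")
        .loc[abundance["transcript_id"]]
        .reset_index()
    )
    summary = StabilitySummary(
        n_stable=int((cls == "stable").sum()),
        n_unstable=int((cls == "unstable").sum()),
        n_neither=int((cls == "neither").sum()),
        dispersion=float(dispersion),
    )
    return result, summary
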