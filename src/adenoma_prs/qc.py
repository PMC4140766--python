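"""Sample- and marker-level genotype quality control.

Two filters, matching standard panel-genotyping practice:

* samples whose per-individual call rate is below a threshold (default
  94%) are excluded — a call rate exactly at the threshold is retained;
* each marker is tested for deviation from Hardy–Weinberg equilibrium
  in controls with the exact conditional test; markers with P at or
  below the significance level are *flagged* in the report, not dropped.

The HWE test is exact: conditional on the observed allele counts, the
probability of every possible heterozygote count is computed with exact
integer combinatorics, and the P-value sums the probabilities of all
tables no more probable than the observed one (ties included, so P = 1
is attainable).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import CohortTable, GenotypeMatrix

__all__ = [
    "QcReport",
    "hwe_exact_test",
    "hwe_het_probabilities",
    "filter_samples_by_call_rate",
    "qc_pipeline",
    "write_qc_report",
]

DEFAULT_CALL_RATE_THRESHOLD = 0.94
DEFAULT_HWE_ALPHA = 0.05


@dataclass
class QcReport:
    """Outcome of the QC pipeline."""

    excluded_samples: list[str]
    per_sample_call_rate: dict[str, float]
    per_marker_hwe_p: dict[str, float]
    flagged_markers: list[str]
    overall_call_rate: float


@lru_cache(maxsize=4096)
def _het_weights(n_a: int, n_total: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Exact integer weights of each heterozygote count given ``n_a``
    copies of the rarer-or-either allele among ``2*n_total`` alleles.

    The weight of ``n_het`` is the number of genotype configurations:
    C(N, n_AA) * C(N - n_AA, n_Aa) * 2**n_Aa.  Conditional probabilities
    are weights over their sum.
    """
    n_b = 2 * n_total - n_a
    hets = []
    weights = []
    # n_het has the parity of n_a and satisfies the homozygote constraints
    for n_het in range(n_a % 2, min(n_a, n_b) + 1, 2):
        n_aa = (n_a - n_het) // 2
        n_bb = (n_b - n_het) // 2
        w = comb(n_total, n_aa) * comb(n_total - n_aa, n_het) * (1 << n_het)
        hets.append(n_het)
        weights.append(w)
    return tuple(hets), tuple(weights)


def hwe_het_probabilities(n_a: int, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given allele
    count ``n_a`` out of ``2*n_total``: (het counts, probabilities)."""
    hets, weights = _het_weights(n_a, n_total)
    total = sum(weights)
    probs = np.array([float(Fraction(w, total)) for w in weights])
    return np.array(hets), probs


def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact conditional Hardy–Weinberg test.

    Given genotype counts (AA, Aa, aa), returns the probability — under
    random union of the observed alleles — of a heterozygote count whose
    conditional probability does not exceed that of the observed one.
    A monomorphic marker has a single possible table, so P = 1.
    """
    for name, v in (("n_AA", n_aa_hom), ("n_Aa", n_het), ("n_aa", n_bb_hom)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    n_total = n_aa_hom + n_het + n_bb_hom
    if n_total == 0:
        raise ValueError("all genotype counts are zero")
    n_a = 2 * n_aa_hom + n_het
    hets, weights = _het_weights(n_a, n_total)
    w_obs = weights[hets.index(n_het)]
    # exact integer comparison: no floating-point tie ambiguity
    num = sum(w for w in weights if w <= w_obs)
    return float(Fraction(num, sum(weights)))


def filter_samples_by_call_rate(
    g: GenotypeMatrix, threshold: float = DEFAULT_CALL_RATE_THRESHOLD
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples with call rate strictly below ``threshold``.

    Surviving genotypes are unchanged; the report records every sample's
    call rate, the excluded ids, and the overall post-exclusion call
    rate. An empty matrix passes through untouched.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    rates = g.call_rates()
    keep = rates >= threshold
    excluded = [s for s, k in zip(g.sample_ids, keep) if not k]
    kept = g.subset_samples([s for s, k in zip(g.sample_ids, keep) if k])
    n_cells = kept.dosage.size
    overall = 1.0 - (kept.missing_mask.sum() / n_cells) if n_cells else 1.0
    report = QcReport(
        excluded_samples=excluded,
        per_sample_call_rate=dict(zip(g.sample_ids, rates.tolist())),
        per_marker_hwe_p={},
        flagged_markers=[],
        overall_call_rate=float(overall),
    )
    return kept, report


def _genotype_counts(dosage_col: np.ndarray) -> tuple[int, int, int]:
    called = dosage_col[dosage_col >= 0]
    return (
        int((called == 2).sum()),  # homozygous risk
        int((called == 1).sum()),
        int((called == 0).sum()),
    )


def qc_pipeline(
    g: GenotypeMatrix,
    labels: CohortTable,
    call_threshold: float = DEFAULT_CALL_RATE_THRESHOLD,
    hwe_alpha: float = DEFAULT_HWE_ALPHA,
) -> tuple[GenotypeMatrix, QcReport]:
    """Sample call-rate filter followed by per-marker HWE tests.

    HWE is assessed in control samples only (case genotype frequencies
    deviate from HWE in the presence of true association); markers with
    exact P <= ``hwe_alpha`` are flagged in the report but kept in the
    matrix.
    """
    controls = set(labels.samples_in_group("CONTROL"))
    if not controls:
        raise ValueError("qc_pipeline requires control samples in the cohort table")
    kept, report = filter_samples_by_call_rate(g, call_threshold)
    ctrl_rows = [i for i, s in enumerate(kept.sample_ids) if s in controls]
    ctrl_dosage = kept.dosage[ctrl_rows]
    for j, rsid in enumerate(kept.snp_ids):
        n2, n1, n0 = _genotype_counts(ctrl_dosage[:, j])
        if n2 + n1 + n0 == 0:
            continue
        p = hwe_exact_test(n2, n1, n0)
        report.per_marker_hwe_p[rsid] = p
        if p <= hwe_alpha:
            report.flagged_markers.append(rsid)
    return kept, report


def write_qc_report(report: QcReport, path: str | Path) -> None:
    """Serialise the report as a two-section TSV (samples, then markers)."""
    with open(path, "w") as fh:
        fh.write(f"# overall_call_rate\t{report.overall_call_rate!r}\n")
        fh.write("## samples\nsample_id\tcall_rate\texcluded\n")
        for s, r in report.per_sample_call_rate.items():
            fh.write(f"{s}\t{r!r}\t{int(s in set(report.excluded_samples))}\n")
        fh.write("## markers\nrsid\thwe_p\tflagged\n")
        for rsid, p in report.per_marker_hwe_p.items():
            fh.write(f"{rsid}\t{p!r}\t{int(rsid in set(report.flagged_markers))}\n")
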