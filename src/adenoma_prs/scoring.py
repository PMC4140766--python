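"""Weight derivation and polygenic risk-score computation.

The score for an individual is Σ_j β_j·n_j, where β_j is the per-allele
ln(OR) of SNP j from an unconditional (single-SNP) logistic regression
in a reference case–control panel, oriented so that β_j ≥ 0, and n_j is
the individual's risk-allele dosage (0–2).  The theoretical score range
is [0, 2·Σβ].  An unweighted variant — the plain count of risk alleles —
is computed alongside.

Missing dosages are handled by policy: ``impute`` (default) replaces a
missing n_j by its control-population expectation 2·p̂_j; ``rescale``
multiplies the observed-SNP score by Σβ_all / Σβ_observed; ``omit``
simply drops the SNP from the sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import GenotypeMatrix, GroupSummary, CohortTable, SnpPanel

__all__ = [
    "WeightEstimate",
    "ScoreResult",
    "EstimationError",
    "estimate_weights",
    "orient_to_weights",
    "compute_scores",
    "score_distribution_stats",
    "scores_as_mapping",
    "write_weights",
    "read_weights",
    "write_scores",
]

MissingPolicy = Literal["impute", "rescale", "omit"]


class EstimationError(RuntimeError):
    """A per-SNP logistic fit failed (separation, monomorphism, no convergence)."""


@dataclass(frozen=True)
class WeightEstimate:
    """Oriented per-SNP weight: β = ln(OR) ≥ 0 with its Wald SE.

    ``oriented_flip`` records that the fitted coefficient was negative
    for the panel's stated risk allele, so the orientation (and the
    effective risk allele) was swapped to make β positive.
    """

    rsid: str
    beta: float
    se_beta: float
    oriented_flip: bool

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"{self.rsid}: oriented beta must be >= 0")
        if not self.se_beta > 0:
            raise ValueError(f"{self.rsid}: se_beta must be > 0")


@dataclass(frozen=True)
class ScoreResult:
    """Per-individual weighted score, unweighted risk-allele count and
    the number of SNPs that were missing for this individual."""

    sample_id: str
    score: float
    risk_allele_count: float
    n_missing: int


def _fit_single_snp(dosage: np.ndarray, y: np.ndarray, rsid: str) -> tuple[float, float]:
    """MLE of the log-odds per dosage unit, with Wald SE from the
    observed information at the optimum."""
    uniq = np.unique(dosage)
    if uniq.size < 2:
        raise EstimationError(f"{rsid}: monomorphic in the reference panel")
    X = sm.add_constant(dosage.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparationError and friends
            raise EstimationError(f"{rsid}: logistic fit failed ({exc})") from exc
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15:
        raise EstimationError(f"{rsid}: quasi-separation (|beta| diverges)")
    return beta, se


def estimate_weights(
    g: GenotypeMatrix, labels: Sequence[int] | np.ndarray
) -> list[WeightEstimate]:
    """Per-SNP unconditional logistic regression of case status on
    risk-allele dosage (additive coding), one SNP at a time.

    A SNP whose fitted coefficient is negative has its orientation
    flipped (dosage recoded 2−n, equivalently the coefficient negated)
    so every reported β is ≥ 0. Missing dosages are dropped per SNP.
    """
    y = np.asarray(labels, dtype=float)
    if y.shape[0] != g.n_samples:
        raise ValueError("labels length does not match genotype matrix")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    out = []
    for j, rsid in enumerate(g.snp_ids):
        col = g.dosage[:, j]
        ok = col >= 0
        beta, se = _fit_single_snp(col[ok].astype(float), y[ok], rsid)
        flip = beta < 0
        out.append(WeightEstimate(rsid, abs(beta), se, flip))
    return out


def orient_to_weights(
    g: GenotypeMatrix, panel: SnpPanel, weights: Sequence[WeightEstimate]
) -> tuple[GenotypeMatrix, SnpPanel]:
    """Apply estimated weights to a panel and re-orient flipped SNPs.

    For a SNP whose estimate was flipped, the effective risk allele is
    the panel's other allele: its dosage column is recoded 2−n (missing
    preserved), the panel entry swaps its risk allele and complements
    its control frequency. The returned matrix/panel pair is consistent
    for :func:`compute_scores`.
    """
    from dataclasses import replace

    if [w.rsid for w in weights] != panel.rsids or list(g.snp_ids) != panel.rsids:
        raise ValueError("weights, panel and matrix must share order and rsids")
    dosage = g.dosage.copy()
    snps = []
    for j, (snp, w) in enumerate(zip(panel, weights)):
        if w.oriented_flip:
            col = dosage[:, j]
            called = col >= 0
            dosage[called, j] = 2 - col[called]
            snps.append(
                replace(
                    snp,
                    risk_allele=snp.other_allele,
                    beta=w.beta,
                    freq=None if snp.freq is None else 1.0 - snp.freq,
                )
            )
        else:
            snps.append(replace(snp, beta=w.beta))
    return GenotypeMatrix(list(g.sample_ids), panel.rsids, dosage), SnpPanel(tuple(snps))


def _control_freq_estimate(g: GenotypeMatrix, panel: SnpPanel) -> np.ndarray:
    """Risk-allele frequency per SNP: panel-provided control frequency
    where available, otherwise estimated from the matrix itself."""
    freqs = np.empty(len(panel))
    for j, s in enumerate(panel):
        if s.freq is not None:
            freqs[j] = s.freq
        else:
            col = g.dosage[:, j]
            called = col[col >= 0]
            freqs[j] = called.mean() / 2.0 if called.size else 0.5
    return freqs


def compute_scores(
    g: GenotypeMatrix,
    panel: SnpPanel,
    missing_policy: MissingPolicy = "impute",
    control_freqs: np.ndarray | None = None,
) -> list[ScoreResult]:
    """Weighted risk score Σβ·n and unweighted risk-allele count Σn.

    Requires the matrix columns to be aligned to the panel and the panel
    betas to be oriented (≥ 0, enforced by :class:`SnpDef`). Missing
    dosages follow ``missing_policy``; under ``impute`` both score and
    count use the expectation 2·p̂ (the count is then non-integer for
    samples with failed calls).
    """
    if list(g.snp_ids) != panel.rsids:
        raise ValueError("genotype matrix is not aligned to the panel")
    if missing_policy not in ("impute", "rescale", "omit"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    betas = panel.betas
    dosage = g.dosage.astype(float)
    miss = g.missing_mask
    n_missing = miss.sum(axis=1)

    if missing_policy == "impute":
        freqs = _control_freq_estimate(g, panel) if control_freqs is None else np.asarray(control_freqs)
        filled = np.where(miss, 2.0 * freqs[None, :], dosage)
        scores = filled @ betas
        counts = filled.sum(axis=1)
    else:
        observed = np.where(miss, 0.0, dosage)
        scores = observed @ betas
        counts = observed.sum(axis=1)
        if missing_policy == "rescale":
            sum_obs = np.where(miss, 0.0, betas[None, :]).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(sum_obs > 0, panel.sum_beta / sum_obs, 1.0)
                count_scale = np.where(
                    (len(panel) - n_missing) > 0, len(panel) / (len(panel) - n_missing), 1.0
                )
            scores = scores * scale
            counts = counts * count_scale
    return [
        ScoreResult(s, float(scores[i]), float(counts[i]), int(n_missing[i]))
        for i, s in enumerate(g.sample_ids)
    ]


def scores_as_mapping(scores: Sequence[ScoreResult]) -> dict[str, float]:
    return {r.sample_id: r.score for r in scores}


def score_distribution_stats(
    scores: Sequence[ScoreResult], labels: CohortTable, by_ma_subgroup: bool = False
) -> list[GroupSummary]:
    """Per-group n, mean and sample SD (n−1 denominator) of the score.

    With ``by_ma_subgroup`` the MA group is additionally split into
    MA (≥10) and MA (5–9) by adenoma count. Groups of size < 2 raise;
    a zero SD violates the summary-row invariant and raises too.
    """
    smap = scores_as_mapping(scores)
    unlabelled = [r.sample_id for r in scores if r.sample_id not in set(labels.sample_ids)]
    if unlabelled:
        raise KeyError(f"samples without a phenotype label: {unlabelled[:5]}")
    frame = labels.table[labels.table["sample_id"].isin(smap)].copy()
    frame["score"] = frame["sample_id"].map(smap)

    def summarise(label: str, vals: pd.Series) -> GroupSummary:
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 scored samples")
        return GroupSummary(label, int(len(vals)), float(vals.mean()), float(vals.std(ddof=1)))

    out = []
    for grp, sub in frame.groupby("group", sort=False):
        out.append(summarise(str(grp), sub["score"]))
        if by_ma_subgroup and grp == "MA":
            hi = sub[sub["adenoma_count"] >= 10]
            lo = sub[sub["adenoma_count"] < 10]
            if len(hi) >= 2:
                out.append(summarise("MA_10plus", hi["score"]))
            if len(lo) >= 2:
                out.append(summarise("MA_5_9", lo["score"]))
    return out


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def write_weights(weights: Sequence[WeightEstimate], panel: SnpPanel, path: str | Path) -> None:
    rows = []
    for w in weights:
        snp = panel[w.rsid]
        risk = snp.other_allele if w.oriented_flip else snp.risk_allele
        rows.append(
            {
                "rsid": w.rsid,
                "risk_allele": risk,
                "beta": repr(w.beta),
                "se": repr(w.se_beta),
                "flipped": int(w.oriented_flip),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_weights(path: str | Path) -> list[WeightEstimate]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        WeightEstimate(str(r.rsid), float(r.beta), float(r.se), bool(r.flipped))
        for r in df.itertuples(index=False)
    ]


def write_scores(scores: Sequence[ScoreResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in scores],
            "score": [repr(r.score) for r in scores],
            "count": [repr(r.risk_allele_count) for r in scores],
            "n_missing": [r.n_missing for r in scores],
        }
    ).to_csv(path, sep="\t", index=False)
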