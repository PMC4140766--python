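"""Modifier-gene analysis of polyposis severity in FAP.

Tests whether the SNP risk score (or any single SNP) modifies the number
of colorectal adenomas at prophylactic colectomy in FAP patients, over
and above the dominant determinant — the position class of the germline
APC variant — with age and sex as covariates.

The outcome is modelled as ln(polyp count) in an ordinary linear
regression, so the exponentiated score coefficient reads as a
multiplicative effect on polyp number per unit of score (a raw-count
linear model is available behind ``log_outcome=False``). Because
patients cluster in families, cluster-robust (sandwich) standard errors
by family are available alongside the naive ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_io import GenotypeMatrix

__all__ = [
    "APC_CLASSES",
    "FapRecord",
    "ModifierResult",
    "fap_severity_regression",
    "per_snp_modifier_scan",
    "read_fap_records",
    "write_fap_records",
]

#: APC variant-position classes: the severe-polyposis region around
#: codons 1265–1389, the regions associated with attenuated FAP
#: (proximal, distal, alternatively spliced), and everything else.
#: "other" is the reference level in regressions.
APC_CLASSES = ("codon_1265_1389", "attenuated_region", "other")


@dataclass(frozen=True)
class FapRecord:
    """One FAP patient: polyp count at colectomy, APC class, covariates."""

    sample_id: str
    family_id: str
    polyp_count: int
    apc_class: str
    age: float
    sex: str

    def __post_init__(self) -> None:
        if self.polyp_count < 1:
            raise ValueError(f"{self.sample_id}: polyp_count must be >= 1")
        if self.apc_class not in APC_CLASSES:
            raise ValueError(
                f"{self.sample_id}: apc_class {self.apc_class!r} not in {APC_CLASSES}"
            )


@dataclass(frozen=True)
class ModifierResult:
    """Fitted modifier regression.

    ``score_effect`` is the exponentiated per-unit-score coefficient
    (multiplicative effect on polyp count under the log-outcome model);
    ``covariate_effects`` maps term name to (coef, se, p) on the model's
    own scale.
    """

    score_effect: float
    ci95: tuple[float, float]
    p: float
    covariate_effects: Mapping[str, tuple[float, float, float]]
    se_type: Literal["naive", "cluster_robust"]
    n: int

    def __post_init__(self) -> None:
        if not self.score_effect > 0:
            raise ValueError("score_effect must be > 0")
        lo, hi = self.ci95
        if not lo < self.score_effect < hi:
            raise ValueError("ci95 must bracket score_effect")


def _records_frame(records: Sequence[FapRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    df["apc_class"] = pd.Categorical(df["apc_class"], categories=list(APC_CLASSES))
    return df


def _design(df: pd.DataFrame, predictor: pd.Series) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "const": 1.0,
            "score": predictor.to_numpy(float),
            "age": df["age"].to_numpy(float),
            "sex_M": (df["sex"] == "M").to_numpy(float),
            # treatment coding, reference level "other"
            "apc_codon_1265_1389": (df["apc_class"] == "codon_1265_1389").to_numpy(float),
            "apc_attenuated_region": (df["apc_class"] == "attenuated_region").to_numpy(float),
        },
        index=df.index,
    )
    # drop indicator columns with no variation (e.g. an absent class)
    keep = [c for c in X.columns if c == "const" or X[c].nunique() > 1]
    if "score" not in keep:
        raise ValueError("predictor is constant; modifier effect is not estimable")
    return X[keep]


def _fit(
    df: pd.DataFrame,
    predictor: pd.Series,
    se_type: str,
    log_outcome: bool,
):
    y = np.log(df["polyp_count"].to_numpy(float)) if log_outcome else df["polyp_count"].to_numpy(float)
    X = _design(df, predictor)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix (collinear covariates)")
    model = sm.OLS(y, X)
    if se_type == "cluster_robust":
        return model.fit(cov_type="cluster", cov_kwds={"groups": df["family_id"]})
    if se_type != "naive":
        raise ValueError(f"unknown se_type {se_type!r}")
    return model.fit()


def fap_severity_regression(
    records: Sequence[FapRecord],
    scores: Mapping[str, float],
    se_type: Literal["naive", "cluster_robust"] = "naive",
    log_outcome: bool = True,
) -> ModifierResult:
    """Regress (log) polyp count on risk score + age + sex + APC class.

    ``scores`` maps sample_id to the weighted risk score. The APC class
    enters with treatment coding against the reference level "other";
    the score effect is reported exponentiated with a Wald 95% CI.
    Requires at least 10 records.
    """
    if len(records) < 10:
        raise ValueError(f"need >= 10 records, got {len(records)}")
    df = _records_frame(records)
    missing = [s for s in df["sample_id"] if s not in scores]
    if missing:
        raise KeyError(f"no score for samples: {missing[:5]}")
    predictor = df["sample_id"].map(scores)
    res = _fit(df, predictor, se_type, log_outcome)

    coef = float(res.params["score"])
    lo, hi = (float(v) for v in res.conf_int().loc["score"])
    cov = {
        term: (float(res.params[term]), float(res.bse[term]), float(res.pvalues[term]))
        for term in res.params.index
        if term != "score"
    }
    return ModifierResult(
        score_effect=float(np.exp(coef)),
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        p=float(res.pvalues["score"]),
        covariate_effects=cov,
        se_type=se_type,
        n=len(df),
    )


def per_snp_modifier_scan(
    records: Sequence[FapRecord],
    g: GenotypeMatrix,
    se_type: Literal["naive", "cluster_robust"] = "naive",
    log_outcome: bool = True,
) -> pd.DataFrame:
    """Repeat the severity regression with each SNP's dosage in place of
    the score; returns a frame (rsid, effect, ci95_low, ci95_high, p)
    with nominal, uncorrected P-values.

    Missing dosages are dropped per SNP (records without a call for that
    SNP do not contribute to that SNP's fit).
    """
    if len(records) < 10:
        raise ValueError(f"need >= 10 records, got {len(records)}")
    df = _records_frame(records)
    frame = g.to_frame().astype(float)
    rows = []
    for rsid in g.snp_ids:
        dose = df["sample_id"].map(frame[rsid])
        ok = dose.notna()
        res = _fit(df[ok], dose[ok], se_type, log_outcome)
        lo, hi = (float(v) for v in res.conf_int().loc["score"])
        rows.append(
            {
                "rsid": rsid,
                "effect": float(np.exp(res.params["score"])),
                "ci95_low": float(np.exp(lo)),
                "ci95_high": float(np.exp(hi)),
                "p": float(res.pvalues["score"]),
            }
        )
    return pd.DataFrame(rows)


def write_fap_records(records: Sequence[FapRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)


def read_fap_records(path) -> list[FapRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str, "sex": str})
    return [
        FapRecord(
            sample_id=r.sample_id,
            family_id=r.family_id,
            polyp_count=int(r.polyp_count),
            apc_class=str(r.apc_class),
            age=float(r.age),
            sex=str(r.sex),
        )
        for r in df.itertuples(index=False)
    ]
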