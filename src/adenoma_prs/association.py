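"""Group-level inference on the risk score and the SNP panel.

Covers the study-style battery: Shapiro–Wilk normality diagnostics of
the score, two-sample t-tests of each case group versus controls (Welch
by default, pooled available, and a summary-statistics entry point so
published tables can be checked without raw data), proportional-odds
ordered logistic regression of severity group on the score, a joint
multivariate logistic model giving per-SNP odds ratios, and the
variance in case status explained by a SNP set (Nagelkerke pseudo-R² by
default, liability-scale transform on request).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .core_io import GenotypeMatrix, SnpPanel

__all__ = [
    "TTestResult",
    "OrderedLogitResult",
    "SnpAssociation",
    "VarianceExplained",
    "shapiro_wilk",
    "two_sample_t",
    "t_from_summary",
    "ordered_logit",
    "multivariate_snp_model",
    "variance_explained",
]

SEVERITY_ORDER = ("CONTROL", "MA_5_9", "MA_10plus")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float
    variant: Literal["welch", "pooled"]

    def __post_init__(self) -> None:
        if not self.df > 0:
            raise ValueError("df must be > 0")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")


@dataclass(frozen=True)
class OrderedLogitResult:
    """Proportional-odds fit: common slope of the score on the ordered
    severity outcome plus the K−1 strictly increasing cutpoints."""

    score_coefficient: float
    se: float
    p: float
    cutpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        diffs = np.diff(self.cutpoints)
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError("cutpoints must be strictly increasing")


@dataclass(frozen=True)
class SnpAssociation:
    rsid: str
    or_joint: float
    ci95_low: float
    ci95_high: float
    p: float

    def __post_init__(self) -> None:
        if not 0 < self.ci95_low < self.or_joint < self.ci95_high:
            raise ValueError(f"{self.rsid}: CI must bracket the OR and all must be > 0")


@dataclass(frozen=True)
class VarianceExplained:
    method: Literal["nagelkerke", "liability"]
    r2_percent: float
    snp_subset: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_percent <= 100.0:
            raise ValueError("r2_percent must lie in [0, 100]")


# ---------------------------------------------------------------------------
# normality and t-tests
# ---------------------------------------------------------------------------


def shapiro_wilk(values: Sequence[float]) -> float:
    """Shapiro–Wilk normality P-value (diagnostic only)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro–Wilk requires n >= 3, got {x.size}")
    return float(st.shapiro(x).pvalue)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], variant: Literal["welch", "pooled"] = "welch"
) -> TTestResult:
    """Two-sided two-sample t-test of mean(a) − mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups have zero variance; t is degenerate")
    return t_from_summary(
        a.size, a.mean(), a.std(ddof=1), b.size, b.mean(), b.std(ddof=1), variant
    )


def t_from_summary(
    n1: int,
    m1: float,
    s1: float,
    n2: int,
    m2: float,
    s2: float,
    variant: Literal["welch", "pooled"] = "welch",
) -> TTestResult:
    """Two-sample t-test from group summaries (n, mean, SD), enabling
    checks of published summary tables without raw data."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0 or (s1 == 0 and s2 == 0):
        raise ValueError("SDs must be >= 0 and not both zero")
    if variant == "welch":
        res = st.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    elif variant == "pooled":
        res = st.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
        df = n1 + n2 - 2
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    return TTestResult(
        t=float(res.statistic), df=float(df), p=float(res.pvalue), mean_diff=float(m1 - m2),
        variant=variant,
    )


# ---------------------------------------------------------------------------
# ordered logistic regression
# ---------------------------------------------------------------------------


def ordered_logit(
    scores: Sequence[float], groups: Sequence[str], order: Sequence[str] = SEVERITY_ORDER
) -> OrderedLogitResult:
    """Proportional-odds cumulative-logit regression of the ordered
    severity group on the score.

    The categories present in ``groups`` must be a subset of ``order``
    (lowest first); at least two must be present. Returns the common
    score coefficient (log-odds of a higher category per unit score)
    with its Wald SE/P and the fitted cutpoints.
    """
    scores = np.asarray(scores, dtype=float)
    groups = pd.Series(groups)
    unknown = set(groups) - set(order)
    if unknown:
        raise ValueError(f"groups outside the stated order: {sorted(unknown)}")
    present = [c for c in order if (groups == c).any()]
    if len(present) < 2:
        raise ValueError("ordered_logit requires >= 2 categories present")
    y = pd.Series(pd.Categorical(groups, categories=present, ordered=True))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(y, scores[:, None], distr="logit")
        res = model.fit(method="bfgs", maxiter=500, disp=0, gtol=1e-8)
    grad = np.asarray(res.mle_retvals.get("gopt", [np.inf]), dtype=float)
    # BFGS can stop with warnflag 2 (precision loss) at a point whose
    # gradient is already far below tolerance; that is convergence.
    if not res.mle_retvals.get("converged", True) and np.abs(grad).max() > 1e-5:
        raise RuntimeError(f"ordered logit did not converge: {res.mle_retvals}")
    params = np.asarray(res.params, dtype=float)
    coef = float(params[0])
    se = float(np.asarray(res.bse, dtype=float)[0])
    if not np.isfinite(se):
        raise RuntimeError("ordered logit: non-finite SE (separation?)")
    cutpoints = tuple(float(v) for v in model.transform_threshold_params(params)[1:-1])
    return OrderedLogitResult(
        score_coefficient=coef,
        se=se,
        p=float(2 * st.norm.sf(abs(coef / se))),
        cutpoints=cutpoints,
    )


# ---------------------------------------------------------------------------
# joint per-SNP model and variance explained
# ---------------------------------------------------------------------------


def _design_from_matrix(g: GenotypeMatrix, impute_freqs: np.ndarray | None = None) -> pd.DataFrame:
    dosage = g.dosage.astype(float)
    if g.missing_mask.any():
        if impute_freqs is None:
            raise ValueError(
                "genotype matrix contains missing dosages; pass impute_freqs "
                "(control risk-allele frequencies) to mean-impute them"
            )
        freqs = np.asarray(impute_freqs, dtype=float)
        dosage = np.where(g.missing_mask, 2.0 * freqs[None, :], dosage)
    X = pd.DataFrame(dosage, columns=g.snp_ids, index=g.sample_ids)
    return sm.add_constant(X)


def _fit_joint_logit(g: GenotypeMatrix, y: np.ndarray, impute_freqs: np.ndarray | None = None):
    X = _design_from_matrix(g, impute_freqs)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design ({rank} < {X.shape[1]}): collinear or monomorphic SNPs"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, X).fit(disp=0, maxiter=200)


def multivariate_snp_model(
    g: GenotypeMatrix,
    labels: Sequence[int] | np.ndarray,
    impute_freqs: np.ndarray | None = None,
) -> tuple[list[SnpAssociation], "sm.discrete.discrete_model.BinaryResultsWrapper"]:
    """One joint logistic regression of case status on all panel SNPs
    (additive dosages). Returns per-SNP OR with Wald 95% CI and P, plus
    the fitted model for downstream variance-explained computations.

    Missing dosages are mean-imputed with 2·p̂ when ``impute_freqs``
    (control risk-allele frequencies, panel order) is given."""
    y = np.asarray(labels, dtype=float)
    if g.n_samples <= g.n_snps + 1:
        raise ValueError("need more samples than SNPs + 1 for the joint model")
    res = _fit_joint_logit(g, y, impute_freqs)
    ci = res.conf_int()
    out = []
    for rsid in g.snp_ids:
        out.append(
            SnpAssociation(
                rsid=rsid,
                or_joint=float(np.exp(res.params[rsid])),
                ci95_low=float(np.exp(ci.loc[rsid, 0])),
                ci95_high=float(np.exp(ci.loc[rsid, 1])),
                p=float(res.pvalues[rsid]),
            )
        )
    return out, res


def _nagelkerke_from_ll(ll_fit: float, ll_null: float, n: int) -> float:
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_fit) / n)
    max_r2 = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_r2)


def variance_explained(
    g: GenotypeMatrix,
    labels: Sequence[int] | np.ndarray,
    snp_subset: Sequence[str] | None = None,
    method: Literal["nagelkerke", "liability"] = "nagelkerke",
    prevalence: float | None = None,
    impute_freqs: np.ndarray | None = None,
) -> VarianceExplained:
    """Percent of variation in case status attributed to a SNP set.

    ``nagelkerke``: rescaled likelihood-ratio pseudo-R² of the joint
    logistic model against the intercept-only model. ``liability``:
    observed-scale (Cox–Snell-free) linear-probability R² transformed to
    the liability scale for an assumed population ``prevalence`` — the
    transform needs an explicit prevalence, it is never defaulted.
    A subset analysis refits the joint model on that subset.
    """
    y = np.asarray(labels, dtype=float)
    sub = g
    sub_freqs = impute_freqs
    if snp_subset is not None:
        cols = [g.snp_ids.index(r) for r in snp_subset]
        sub = GenotypeMatrix(list(g.sample_ids), [g.snp_ids[c] for c in cols], g.dosage[:, cols])
        if impute_freqs is not None:
            sub_freqs = np.asarray(impute_freqs, dtype=float)[cols]
    if method == "nagelkerke":
        res = _fit_joint_logit(sub, y, sub_freqs)
        # intercept-only log-likelihood in closed form (exact null MLE)
        ybar = float(y.mean())
        ll_null = len(y) * (ybar * np.log(ybar) + (1 - ybar) * np.log1p(-ybar))
        r2 = _nagelkerke_from_ll(float(res.llf), ll_null, sub.n_samples)
    elif method == "liability":
        if prevalence is None or not 0 < prevalence < 1:
            raise ValueError("liability-scale R2 requires a prevalence in (0, 1)")
        # observed-scale R2 from a linear probability model, then the
        # standard ascertainment-corrected threshold-model transform
        X = _design_from_matrix(sub, sub_freqs).to_numpy()
        fitted = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        r2_obs = float(np.var(fitted) / np.var(y))
        case_frac = float(y.mean())
        z = st.norm.pdf(st.norm.ppf(prevalence))
        k = prevalence
        c = k * (1 - k) / z**2 * k * (1 - k) / (case_frac * (1 - case_frac))
        r2 = r2_obs * c
    else:
        raise ValueError(f"unknown method {method!r}")
    return VarianceExplained(
        method=method,
        r2_percent=float(np.clip(r2 * 100.0, 0.0, 100.0)),
        snp_subset=tuple(sub.snp_ids),
    )
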