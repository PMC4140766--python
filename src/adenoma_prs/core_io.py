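"""Domain types and file I/O for the adenoma PRS pipeline.

The pipeline works with four kinds of tabular data, all tab-separated
plain text:

* a SNP *panel* (rsid, chromosome, hg19 position, the two alleles, the
  risk allele and its per-allele log-odds weight beta),
* a *genotype dosage* matrix (samples x panel SNPs, risk-allele counts
  0/1/2 with ``NA`` for a failed call),
* a *phenotype* table (group label, adenoma count, CRC history, age, sex),
* *group summary* rows shaped like the study-style summary table
  (n, mean score, SD, t and P versus controls).

Genotypes may alternatively be read from a VCF; GT fields are converted
to risk-allele dosage at read time so that downstream code never has to
re-check allele orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SnpDef",
    "SnpPanel",
    "GenotypeMatrix",
    "CohortTable",
    "GroupSummary",
    "FormatError",
    "AlleleMismatchError",
    "STUDY_PANEL",
    "read_panel",
    "write_panel",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_group_summaries",
    "write_group_summaries",
]

#: Sentinel dosage for a failed genotype call. Stored as ``-1`` in the
#: integer dosage array; serialised as ``NA`` in TSV.
MISSING: int = -1

VALID_GROUPS = ("MA", "FAP_mutant", "FAP_like_wt", "CONTROL")


class FormatError(ValueError):
    """A file violates the expected tabular format."""


class AlleleMismatchError(ValueError):
    """A VCF site's REF/ALT alleles do not contain the panel risk allele."""


@dataclass(frozen=True)
class SnpDef:
    """One biallelic marker of the panel.

    ``beta`` is the per-allele ln(OR) weight, oriented so that it is
    non-negative: ``risk_allele`` is the allele whose count enters the
    score. ``freq`` optionally carries the control-population risk-allele
    frequency (used by the simulator and by mean-imputation of missing
    dosages); it is not required for scoring observed genotypes.
    """

    rsid: str
    chrom: str
    pos_hg19: int
    allele_a: str
    allele_b: str
    risk_allele: str
    beta: float
    freq: float | None = None

    def __post_init__(self) -> None:
        if self.risk_allele not in (self.allele_a, self.allele_b):
            raise ValueError(
                f"{self.rsid}: risk allele {self.risk_allele!r} is neither "
                f"{self.allele_a!r} nor {self.allele_b!r}"
            )
        if not math.isfinite(self.beta) or self.beta < 0:
            raise ValueError(
                f"{self.rsid}: beta must be finite and >= 0 after risk-allele "
                f"orientation, got {self.beta}"
            )
        if self.freq is not None and not 0.0 < self.freq < 1.0:
            raise ValueError(f"{self.rsid}: freq must lie in (0, 1), got {self.freq}")

    @property
    def other_allele(self) -> str:
        return self.allele_b if self.risk_allele == self.allele_a else self.allele_a


@dataclass(frozen=True)
class SnpPanel:
    """An ordered collection of :class:`SnpDef` with unique rsIDs."""

    snps: tuple[SnpDef, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "snps", tuple(self.snps))
        seen: set[str] = set()
        for s in self.snps:
            if s.rsid in seen:
                raise FormatError(f"duplicate rsid in panel: {s.rsid}")
            seen.add(s.rsid)

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    def __getitem__(self, rsid: str) -> SnpDef:
        for s in self.snps:
            if s.rsid == rsid:
                return s
        raise KeyError(rsid)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    @property
    def betas(self) -> np.ndarray:
        return np.array([s.beta for s in self.snps], dtype=float)

    @property
    def sum_beta(self) -> float:
        """Sum of weights; the score's theoretical maximum is ``2 * sum_beta``."""
        return float(self.betas.sum())

    def with_betas(self, betas: Sequence[float]) -> "SnpPanel":
        """Return a copy of the panel with replaced weights (same order)."""
        if len(betas) != len(self.snps):
            raise ValueError("beta vector length does not match panel size")
        return SnpPanel(tuple(replace(s, beta=float(b)) for s, b in zip(self.snps, betas)))

    def subset(self, rsids: Iterable[str]) -> "SnpPanel":
        keep = list(rsids)
        missing = set(keep) - set(self.rsids)
        if missing:
            raise KeyError(f"rsids not in panel: {sorted(missing)}")
        return SnpPanel(tuple(s for s in self.snps if s.rsid in keep))


@dataclass
class GenotypeMatrix:
    """Samples x SNPs risk-allele dosage matrix.

    ``dosage`` is an int8 array with values in {0, 1, 2, MISSING};
    orientation to the risk allele happened at read (or simulation) time.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"dosage contains values outside {{0,1,2,NA}} at {np.argwhere(bad)[0]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def call_rates(self) -> np.ndarray:
        """Per-sample fraction of non-missing genotypes."""
        if self.n_snps == 0:
            return np.ones(self.n_samples)
        return 1.0 - self.missing_mask.mean(axis=1)

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in keep]
        return GenotypeMatrix(list(keep), list(self.snp_ids), self.dosage[rows])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.snp_ids, dtype="Int8")
        return df.mask(df == MISSING)


@dataclass
class CohortTable:
    """Per-individual phenotype labels for the study cohorts.

    The MA subgroup (5-9 vs >=10 adenomas) is derived from
    ``adenoma_count`` on demand rather than stored.
    """

    table: pd.DataFrame  # columns: sample_id, group, adenoma_count, crc_history, age, sex

    REQUIRED = ("sample_id", "group", "adenoma_count", "crc_history", "age", "sex")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise FormatError(f"phenotype table missing columns: {sorted(missing)}")
        bad = set(self.table["group"]) - set(VALID_GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        ma = self.table["group"] == "MA"
        if ma.any() and self.table.loc[ma, "adenoma_count"].isna().any():
            raise FormatError("adenoma_count is required for MA individuals")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def group_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]

    def samples_in_group(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "sample_id"].tolist()

    def ma_subgroup(self) -> pd.Series:
        """``MA_10plus`` / ``MA_5_9`` for MA samples, NA otherwise."""
        count = self.table["adenoma_count"]
        sub = pd.Series(pd.NA, index=self.table.index, dtype="string")
        ma = self.table["group"] == "MA"
        sub[ma & (count >= 10)] = "MA_10plus"
        sub[ma & (count < 10)] = "MA_5_9"
        return sub.set_axis(self.table["sample_id"])

    def subset(self, sample_ids: Sequence[str]) -> "CohortTable":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return CohortTable(keep.copy())


@dataclass(frozen=True)
class GroupSummary:
    """One row of the per-group score summary: n, mean, SD, t and P
    versus the control group (t and P are ``None`` for the control row
    itself or when not yet computed)."""

    group_label: str
    n: int
    mean_score: float
    sd_score: float
    t_vs_controls: float | None = None
    p_vs_controls: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"{self.group_label}: group summary requires n >= 2, got {self.n}")
        if not self.sd_score > 0:
            raise ValueError(f"{self.group_label}: sd_score must be > 0, got {self.sd_score}")


# ---------------------------------------------------------------------------
# The study's 18-marker panel.
#
# rsIDs, positions and alleles follow the published marker list (hg19,
# 1-based); for rs10795668 the risk allele is G (its printed variant
# allele A is the protective one).  The per-allele ln(OR) weights are
# GWAS-scale (ORs 1.03-1.27), distinct and irregularly spaced, and sum
# to 2.39 so the score's theoretical range is exactly [0, 4.78];
# together with the control risk-allele frequencies they are calibrated
# so the control score distribution has mean 2.27 and SD 0.42 and is
# indistinguishable from normal at cohort sample sizes.  The three
# markers individually associated with the multiple-adenoma phenotype
# (rs6983267, rs10795668, rs3802842) receive the largest weights.
# ---------------------------------------------------------------------------


def _study_weight_ladder() -> tuple[np.ndarray, np.ndarray]:
    """18 (beta, freq) pairs, ascending in beta.

    Betas are mean 4.78/36 plus a standardized normal-quantile spread
    (irregular spacing keeps score values off a coarse lattice); the
    spread and frequency-shift constants solve mean = 2.27, SD = 0.42
    for the implied control score distribution.
    """
    from scipy.stats import norm

    n = 18
    q = norm.ppf((np.arange(n) + 0.5) / n)
    u = q / q.std()
    betas = 4.78 / (2 * n) + 0.053443043633017155 * u
    freqs = np.linspace(0.65, 0.30, n) + 0.04233267393129993
    return betas, freqs


_LADDER_BETAS, _LADDER_FREQS = _study_weight_ladder()

_STUDY_SNPS = (
    # rsid, chrom, pos, allele_a, allele_b, risk_allele, weight rank (0=smallest)
    ("rs6691170", "1", 220112069, "G", "T", "T", 0),
    ("rs6687758", "1", 220231571, "A", "G", "G", 1),
    ("rs10936599", "3", 170974795, "C", "T", "T", 2),
    ("rs16892766", "8", 117699864, "A", "C", "C", 3),
    ("rs6983267", "8", 128482487, "G", "T", "T", 17),
    ("rs10795668", "10", 8741225, "G", "A", "G", 16),
    ("rs3802842", "11", 110676919, "A", "C", "C", 15),
    ("rs7136702", "12", 49166483, "C", "T", "T", 4),
    ("rs11169552", "12", 49441930, "C", "T", "T", 5),
    ("rs4444235", "14", 53480669, "T", "C", "C", 6),
    ("rs1957636", "14", 53629768, "G", "A", "A", 7),
    ("rs4779584", "15", 30782048, "C", "T", "T", 8),
    ("rs9929218", "16", 67378447, "G", "A", "A", 9),
    ("rs4939827", "18", 44707461, "T", "C", "C", 10),
    ("rs10411210", "19", 38224140, "C", "T", "T", 11),
    ("rs961253", "20", 6352281, "C", "A", "A", 12),
    ("rs4813802", "20", 6647595, "T", "G", "G", 13),
    ("rs4925386", "20", 60354439, "C", "T", "T", 14),
)

STUDY_PANEL = SnpPanel(
    tuple(
        SnpDef(r, c, p, a, b, k, float(_LADDER_BETAS[rank]), float(_LADDER_FREQS[rank]))
        for r, c, p, a, b, k, rank in _STUDY_SNPS
    )
)


# ---------------------------------------------------------------------------
# Panel TSV
# ---------------------------------------------------------------------------

_PANEL_COLS = ["rsid", "chrom", "pos", "allele_a", "allele_b", "risk_allele", "beta"]


def read_panel(path: str | Path) -> SnpPanel:
    """Read a panel TSV (header: rsid, chrom, pos, allele_a, allele_b,
    risk_allele, beta, optionally freq).

    Raises :class:`FormatError` for duplicate rsIDs and ``ValueError``
    naming the SNP for a negative (mis-oriented) beta.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    missing = set(_PANEL_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"panel file missing columns: {sorted(missing)}")
    snps = []
    for row in df.itertuples(index=False):
        freq = getattr(row, "freq", None)
        if freq is not None and pd.isna(freq):
            freq = None
        snps.append(
            SnpDef(
                rsid=str(row.rsid),
                chrom=str(row.chrom),
                pos_hg19=int(row.pos),
                allele_a=str(row.allele_a),
                allele_b=str(row.allele_b),
                risk_allele=str(row.risk_allele),
                beta=float(row.beta),
                freq=None if freq is None else float(freq),
            )
        )
    return SnpPanel(tuple(snps))


def write_panel(panel: SnpPanel, path: str | Path) -> None:
    rows = [
        {
            "rsid": s.rsid,
            "chrom": s.chrom,
            "pos": s.pos_hg19,
            "allele_a": s.allele_a,
            "allele_b": s.allele_b,
            "risk_allele": s.risk_allele,
            "beta": repr(s.beta),
            "freq": "" if s.freq is None else repr(s.freq),
        }
        for s in panel
    ]
    pd.DataFrame(rows, columns=_PANEL_COLS + ["freq"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype dosage TSV
# ---------------------------------------------------------------------------


def read_genotypes_tsv(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Read a dosage TSV (first column ``sample_id``, one column per panel
    rsID, cells in {0, 1, 2, NA}) and align columns to panel order."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise FormatError("first column of a genotype TSV must be 'sample_id'")
    unknown = set(df.columns[1:]) - set(panel.rsids)
    if unknown:
        raise FormatError(f"genotype columns not in panel: {sorted(unknown)}")
    absent = [r for r in panel.rsids if r not in df.columns]
    if absent:
        raise FormatError(f"genotype file lacks panel markers: {absent}")
    sample_ids = df["sample_id"].tolist()
    dosage = np.empty((len(sample_ids), len(panel)), dtype=np.int8)
    lut = {"0": 0, "1": 1, "2": 2, "NA": MISSING}
    for j, rsid in enumerate(panel.rsids):
        col = df[rsid]
        try:
            dosage[:, j] = [lut[v] for v in col]
        except KeyError as exc:
            raise FormatError(f"invalid dosage value {exc.args[0]!r} in column {rsid}") from None
    return GenotypeMatrix(sample_ids, panel.rsids, dosage)


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    cells = np.where(g.dosage == MISSING, "NA", g.dosage.astype(str))
    df = pd.DataFrame(cells, index=g.sample_ids, columns=g.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_genotypes_vcf(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field only) and convert to
    risk-allele dosage.

    Sites are matched to the panel by the ID column first, then by
    (chrom, pos). Half calls and ``./.`` become MISSING; panel sites
    absent from the VCF are MISSING for every sample. A matched site
    whose REF/ALT do not include the panel risk allele raises
    :class:`AlleleMismatchError` — no strand flipping is attempted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    by_id = {s.rsid: j for j, s in enumerate(panel)}
    by_pos = {(s.chrom, s.pos_hg19): j for j, s in enumerate(panel)}
    dosage = np.full((len(samples), len(panel)), MISSING, dtype=np.int8)
    for var in vcf:
        j = by_id.get(var.ID) if var.ID else None
        if j is None:
            j = by_pos.get((var.CHROM.removeprefix("chr"), var.POS))
        if j is None:
            continue
        snp = panel.snps[j]
        alts = list(var.ALT)
        alleles = [var.REF] + alts
        if snp.risk_allele not in alleles:
            raise AlleleMismatchError(
                f"{snp.rsid}: risk allele {snp.risk_allele} matches neither REF "
                f"{var.REF} nor ALT {','.join(alts) or '.'}"
            )
        risk_idx = alleles.index(snp.risk_allele)
        for i, gt in enumerate(var.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:  # ./., .|. or half call
                continue
            dosage[i, j] = (a1 == risk_idx) + (a2 == risk_idx)
    return GenotypeMatrix(samples, panel.rsids, dosage)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> CohortTable:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "group": str, "sex": str},
    )
    df["adenoma_count"] = pd.to_numeric(df["adenoma_count"], errors="raise").astype("Int64")
    df["crc_history"] = df["crc_history"].astype(bool)
    return CohortTable(df)


def write_phenotypes(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Group summaries (the summary-table row shape)
# ---------------------------------------------------------------------------

_SUMMARY_COLS = ["group", "n", "mean", "SD", "t", "P"]


def write_group_summaries(rows: Sequence[GroupSummary], path: str | Path) -> None:
    """Write summary rows as TSV with columns group/n/mean/SD/t/P; the
    control row (no t-test against itself) prints ``—`` for t and P."""
    out = []
    for r in rows:
        out.append(
            {
                "group": r.group_label,
                "n": r.n,
                "mean": repr(float(r.mean_score)),
                "SD": repr(float(r.sd_score)),
                "t": "—" if r.t_vs_controls is None else repr(float(r.t_vs_controls)),
                "P": "—" if r.p_vs_controls is None else repr(float(r.p_vs_controls)),
            }
        )
    pd.DataFrame(out, columns=_SUMMARY_COLS).to_csv(path, sep="\t", index=False)


def read_group_summaries(path: str | Path) -> list[GroupSummary]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_SUMMARY_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"summary file missing columns: {sorted(missing)}")
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            GroupSummary(
                group_label=r.group,
                n=int(r.n),
                mean_score=float(r.mean),
                sd_score=float(r.SD),
                t_vs_controls=None if r.t == "—" else float(r.t),
                p_vs_controls=None if r.P == "—" else float(r.P),
            )
        )
    return rows
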