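"""File formats: VCF genotypes, FAM pedigrees, phenotype TSVs, summary stats.

Readers assemble father-mother-offspring trios from a PLINK-style FAM table
and a VCF dosage matrix; writers exist for every format so that simulated
cohorts round-trip losslessly through the on-disk representation.  Summary
statistics use a tab-separated schema with the columns

    snp  chr  pos  ea  oa  eaf  effect_type  beta  se  p  n  method

where ``ea`` is the counted (dosage) allele.  Extra columns in foreign
files are preserved on read and ignored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import TrioDataset
from .gwas import SummaryStatRecord, inverse_normal_transform

logger = logging.getLogger(__name__)

SUMSTAT_COLUMNS = ("snp", "chr", "pos", "ea", "oa", "eaf", "effect_type",
                   "beta", "se", "p", "n", "method")
FAM_COLUMNS = ("fid", "iid", "pat", "mat", "sex", "phe")


# -- genotypes --------------------------------------------------------------

def read_genotype_matrix(vcf_path) -> tuple[pd.DataFrame, np.ndarray,
                                            list[str]]:
    """Read a VCF into (SNP metadata, sample x SNP dosage matrix, samples).

    Dosage is the ALT-allele count in {0, 1, 2}; missing genotypes become
    NaN.  Multiallelic sites are skipped with a warning.  Positions are
    1-based as in the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{vcf_path}: VCF contains no samples")
    meta_rows, columns = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning("skipping multiallelic site %s:%s",
                           variant.CHROM, variant.POS)
            continue
        dosage = variant.gt_types.astype(float)  # 0/1/2, 3 = missing
        dosage[dosage == 3] = np.nan
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        meta_rows.append({"snp": snp_id, "chr": variant.CHROM,
                          "pos": int(variant.POS), "ea": variant.ALT[0],
                          "oa": variant.REF})
        columns.append(dosage)
    meta = pd.DataFrame(meta_rows,
                        columns=["snp", "chr", "pos", "ea", "oa"])
    matrix = (np.column_stack(columns) if columns
              else np.empty((len(samples), 0)))
    return meta, matrix, samples


def write_vcf(path, meta: pd.DataFrame, dosages: np.ndarray,
              samples: list[str]) -> None:
    """Write a dosage matrix as a minimal GT-only VCF (text, uncompressed)."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for chrom in pd.unique(meta["chr"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, row in meta.reset_index(drop=True).iterrows():
            calls = [gt_of.get(None if np.isnan(d) else int(d), "./.")
                     for d in dosages[:, j]]
            fh.write(f"{row['chr']}\t{row['pos']}\t{row['snp']}\t"
                     f"{row['oa']}\t{row['ea']}\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


# -- pedigree ---------------------------------------------------------------

@dataclass
class PedigreeIndex:
    """Resolved analysis trios: (family, father, mother, offspring) ids."""

    trios: list[tuple[str, str, str, str]]
    dropped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trios)


def read_fam(path) -> pd.DataFrame:
    fam = pd.read_csv(path, sep=r"\s+", header=None,
                      names=FAM_COLUMNS, dtype=str)
    if fam.isna().any().any():
        raise ValueError(f"{path}: truncated or malformed FAM file")
    return fam


def build_pedigree_index(fam: pd.DataFrame,
                         genotyped: set[str] | None = None) -> PedigreeIndex:
    """Select one father-mother-offspring trio per family.

    Offspring are rows with both parent ids non-zero; a family with several
    eligible offspring contributes its first by id order.  Each individual
    may appear in at most one analysis trio; duplicate individual rows are
    an error.
    """
    if fam["iid"].duplicated().any():
        dup = fam.loc[fam["iid"].duplicated(), "iid"].iloc[0]
        raise ValueError(f"duplicate individual id in FAM: {dup}")
    present = set(fam["iid"])
    if genotyped is not None:
        present &= genotyped
    used: set[str] = set()
    trios, dropped = [], {}

    def drop(reason):
        dropped[reason] = dropped.get(reason, 0) + 1

    for fid, group in fam.sort_values("iid").groupby("fid", sort=True):
        offspring = group[(group["pat"] != "0") & (group["mat"] != "0")]
        chosen = None
        for _, row in offspring.iterrows():
            members = (row["pat"], row["mat"], row["iid"])
            if any(m not in present for m in members):
                drop("member_not_genotyped")
                continue
            if any(m in used for m in members):
                drop("member_already_used")
                continue
            chosen = (fid, *members)
            break
        if chosen is None:
            if len(offspring) == 0:
                drop("no_offspring_with_parents")
            continue
        used.update(chosen[1:])
        trios.append(chosen)
    trios.sort(key=lambda t: t[0])
    return PedigreeIndex(trios=trios, dropped=dropped)


# -- phenotypes -------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    """TSV with an ``iid`` column plus named phenotype/covariate columns."""
    table = pd.read_csv(path, sep="\t", dtype={0: str})
    if "iid" not in table.columns:
        raise ValueError(f"{path}: phenotype table must have an iid column")
    return table.set_index("iid")


def write_phenotypes(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index_label="iid", float_format="%.10g")


def write_fam(path, trios: list[tuple[str, str, str, str]]) -> None:
    """Write one FAM row per trio member (parents as founders)."""
    with open(path, "w") as fh:
        for fid, father, mother, child in trios:
            fh.write(f"{fid}\t{father}\t0\t0\t1\t-9\n")
            fh.write(f"{fid}\t{mother}\t0\t0\t2\t-9\n")
            fh.write(f"{fid}\t{child}\t{father}\t{mother}\t0\t-9\n")


# -- assembled panel --------------------------------------------------------

@dataclass
class TrioPanel:
    """Per-SNP trio dosages plus one phenotype per role, over many SNPs."""

    snps: pd.DataFrame            # snp, chr, pos, ea, oa
    F: np.ndarray                 # (n_trios, n_snps) dosages, NaN missing
    M: np.ndarray
    O: np.ndarray
    ZF: np.ndarray                # (n_trios,)
    ZM: np.ndarray
    ZO: np.ndarray
    covariates: object | None = None
    family_ids: np.ndarray | None = None
    report: dict = field(default_factory=dict)

    @property
    def n_trios(self) -> int:
        return len(self.ZO)

    def dataset(self, j: int) -> TrioDataset:
        """Complete-case trio dataset for SNP column ``j``."""
        data = TrioDataset(self.F[:, j], self.M[:, j], self.O[:, j],
                           self.ZF, self.ZM, self.ZO,
                           covariates=self.covariates,
                           family_ids=self.family_ids)
        return data.complete_cases()

    def eaf(self, j: int) -> float:
        """Effect-allele frequency from the parental (founder) dosages."""
        parents = np.concatenate([self.F[:, j], self.M[:, j]])
        parents = parents[np.isfinite(parents)]
        return float(parents.mean() / 2.0) if len(parents) else np.nan

    def int_transformed(self) -> "TrioPanel":
        """Panel with each role's phenotype inverse-normal transformed."""
        return TrioPanel(self.snps, self.F, self.M, self.O,
                         inverse_normal_transform(self.ZF),
                         inverse_normal_transform(self.ZM),
                         inverse_normal_transform(self.ZO),
                         covariates=self.covariates,
                         family_ids=self.family_ids, report=self.report)


def assemble_trios(pedigree: PedigreeIndex, meta: pd.DataFrame,
                   dosages: np.ndarray, samples: list[str],
                   phenotypes: pd.DataFrame, phenotype: str,
                   covariate_cols: list[str] | None = None) -> TrioPanel:
    """Join pedigree, genotype matrix and phenotype table into a panel.

    Trios with a missing phenotype for any member are dropped here
    (complete-case analysis); per-SNP genotype missingness is handled when
    a SNP's dataset is extracted.  Ordering is deterministic by family id.
    """
    sample_idx = {s: i for i, s in enumerate(samples)}
    rows_f, rows_m, rows_o, fids = [], [], [], []
    zf, zm, zo = [], [], []
    covs = {"F": [], "M": [], "O": []}
    dropped = dict(pedigree.dropped)

    def drop(reason):
        dropped[reason] = dropped.get(reason, 0) + 1

    for fid, father, mother, child in pedigree.trios:
        if any(m not in sample_idx for m in (father, mother, child)):
            drop("member_not_genotyped")
            continue
        if any(m not in phenotypes.index for m in (father, mother, child)):
            drop("member_missing_phenotype")
            continue
        values = [phenotypes.loc[m, phenotype]
                  for m in (father, mother, child)]
        if any(pd.isna(v) for v in values):
            drop("member_missing_phenotype")
            continue
        rows_f.append(sample_idx[father])
        rows_m.append(sample_idx[mother])
        rows_o.append(sample_idx[child])
        fids.append(fid)
        zf.append(float(values[0]))
        zm.append(float(values[1]))
        zo.append(float(values[2]))
        if covariate_cols:
            for role, member in zip("FMO", (father, mother, child)):
                covs[role].append(
                    phenotypes.loc[member, covariate_cols].astype(float))
    if not fids:
        raise ValueError("no assemblable trios")
    covariates = None
    if covariate_cols:
        covariates = {role: pd.DataFrame(covs[role]).reset_index(drop=True)
                      for role in "FMO"}
    panel = TrioPanel(
        snps=meta.reset_index(drop=True),
        F=dosages[rows_f, :], M=dosages[rows_m, :], O=dosages[rows_o, :],
        ZF=np.array(zf), ZM=np.array(zm), ZO=np.array(zo),
        covariates=covariates, family_ids=np.array(fids),
        report={"n_trios": len(fids), "dropped": dropped})
    logger.info("assembled %d trios (dropped: %s)", len(fids), dropped)
    return panel


# -- variant / sample QC ----------------------------------------------------

def hwe_pvalue(dosages: np.ndarray) -> float:
    """Chi-square (1 df) Hardy-Weinberg test from founder dosages."""
    d = dosages[np.isfinite(dosages)]
    n = len(d)
    if n == 0:
        return np.nan
    counts = np.array([(d == 0).sum(), (d == 1).sum(), (d == 2).sum()],
                      dtype=float)
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    if np.any(expected < 1e-12):
        return 1.0
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def variant_qc_mask(dosages: np.ndarray, maf_min: float = 0.01,
                    call_rate_min: float = 0.99,
                    hwe_p_min: float = 1e-7) -> np.ndarray:
    """Boolean keep-mask per SNP column using conventional GWAS thresholds."""
    n, p = dosages.shape
    keep = np.ones(p, dtype=bool)
    for j in range(p):
        col = dosages[:, j]
        finite = np.isfinite(col)
        call_rate = finite.mean()
        if call_rate < call_rate_min:
            keep[j] = False
            continue
        freq = col[finite].mean() / 2.0 if finite.any() else np.nan
        maf = min(freq, 1 - freq) if np.isfinite(freq) else 0.0
        if maf <= maf_min or hwe_pvalue(col) <= hwe_p_min:
            keep[j] = False
    return keep


# -- summary statistics -----------------------------------------------------

def records_to_frame(records: list[SummaryStatRecord]) -> pd.DataFrame:
    rows = [{"snp": r.snp_id, "chr": r.chromosome, "pos": r.position,
             "ea": r.effect_allele, "oa": r.other_allele, "eaf": r.eaf,
             "effect_type": r.effect_type, "beta": r.beta, "se": r.se,
             "p": r.p, "n": r.n, "method": r.method_tag, "note": r.note}
            for r in records]
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[SummaryStatRecord]:
    return [SummaryStatRecord(
        snp_id=row["snp"], chromosome=str(row["chr"]),
        position=int(row["pos"]), effect_allele=row["ea"],
        other_allele=row["oa"], eaf=float(row["eaf"]),
        effect_type=row["effect_type"], beta=float(row["beta"]),
        se=float(row["se"]), p=float(row["p"]), n=int(row["n"]),
        method_tag=row["method"], note=str(row.get("note", "") or ""))
        for _, row in frame.iterrows()]


def write_summary_stats(records, path) -> None:
    """Serialize summary records (or a frame) as TSV, 10 significant digits.

    Exact zeros in the p column are replaced by the smallest positive
    double with a warning, so that downstream -log10 handling never sees
    p = 0.
    """
    frame = (records.copy() if isinstance(records, pd.DataFrame)
             else records_to_frame(records))
    if (frame["p"] == 0).any():
        warnings.warn("p-values of exactly 0 replaced by the smallest "
                      "positive double", stacklevel=2)
        frame.loc[frame["p"] == 0, "p"] = np.nextafter(0, 1)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g",
                 na_rep="NA")


def read_summary_stats(path) -> pd.DataFrame:
    """Read a summary-stat TSV, validating the required schema columns."""
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in SUMSTAT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing summary-stat columns {missing}")
    return frame
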