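"""Genotype/phenotype containers, file readers and writers, and QC filters.

The universal in-memory object is :class:`GenotypeMatrix`: an
``n_samples x n_markers`` array of additive genotype codes {0, 1, 2}
(count of the coded allele, with ``-1`` as the missing sentinel) plus a
binary phenotype vector (1 = case, 0 = control).  Supported on-disk
formats are delimited CSV, VCF (GT field, biallelic sites only) and the
PLINK additive-coded text export (``.raw``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "MISSING", "read_genotypes", "write_csv", "write_vcf", "qc_filter"]


@dataclass
class GenotypeMatrix:
    genotypes: np.ndarray  # (n_samples, n_markers), int8 codes {0,1,2,MISSING}
    phenotype: np.ndarray  # (n_samples,), {0,1}
    marker_ids: list[str]
    sample_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, m = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length does not match sample count")
        if len(self.marker_ids) != m or len(self.sample_ids) != n:
            raise ValueError("id lists do not match matrix dimensions")
        valid = np.isin(self.genotypes, [0, 1, 2, MISSING])
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"genotype code outside {{0,1,2}} at sample {self.sample_ids[bad[0]]}, "
                f"marker {self.marker_ids[bad[1]]}"
            )
        if not np.isin(self.phenotype, [0, 1]).all():
            raise ValueError("phenotype must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.genotypes[:, j]

    def permute_markers(self, order) -> "GenotypeMatrix":
        """Reorder the marker columns; useful for order-robustness studies."""
        order = np.asarray(order)
        return GenotypeMatrix(
            genotypes=self.genotypes[:, order],
            phenotype=self.phenotype.copy(),
            marker_ids=[self.marker_ids[j] for j in order],
            sample_ids=list(self.sample_ids),
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# readers

def _read_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    if "phenotype" not in df.columns:
        raise ValueError(f"{path}: CSV must contain a 'phenotype' column")
    pheno = df.pop("phenotype").to_numpy()
    geno = df.to_numpy(dtype=float)
    geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    return GenotypeMatrix(
        genotypes=geno,
        phenotype=pheno,
        marker_ids=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
    )


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    ids: list[str] = []
    n_multiallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if any(a < 0 for a in alleles):
                continue
            codes[i] = sum(1 for a in alleles if a == 1)
        columns.append(codes)
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    if n_multiallelic:
        logger.info("skipped %d multiallelic record(s) in %s", n_multiallelic, path)
    if not columns:
        raise ValueError(f"{path}: no biallelic variants found")
    geno = np.column_stack(columns)
    # a VCF carries no phenotype; caller must attach one
    return GenotypeMatrix(
        genotypes=geno,
        phenotype=np.zeros(len(samples), dtype=np.int8),
        marker_ids=ids,
        sample_ids=samples,
        metadata={"n_multiallelic_skipped": n_multiallelic, "phenotype_missing": True},
    )


def _read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+")
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    for c in meta_cols:
        if c not in df.columns:
            raise ValueError(f"{path}: missing PLINK .raw column {c}")
    pheno = df["PHENOTYPE"].to_numpy()
    # PLINK codes case/control as 2/1; tolerate an already-binary column
    if set(np.unique(pheno)) <= {1, 2}:
        pheno = (pheno == 2).astype(np.int8)
    geno_df = df.drop(columns=meta_cols)
    geno = geno_df.to_numpy(dtype=float)
    geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    return GenotypeMatrix(
        genotypes=geno,
        phenotype=pheno,
        marker_ids=[str(c) for c in geno_df.columns],
        sample_ids=[str(i) for i in df["IID"]],
    )


_READERS = {"csv": _read_csv, "vcf": _read_vcf, "plink_raw": _read_plink_raw}


def read_genotypes(path, format: str = "csv") -> GenotypeMatrix:
    """Read a genotype matrix from ``csv``, ``vcf`` or ``plink_raw`` text."""
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_READERS)}")
    return reader(path)


# ---------------------------------------------------------------------------
# writers

def write_csv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.genotypes, index=g.sample_ids, columns=g.marker_ids)
    df = df.astype(object).mask(df == MISSING, other="")
    df.insert(0, "phenotype", g.phenotype)
    df.to_csv(path, index_label="sample_id")


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write unphased GT-only VCF; markers become chr1 records at 1-based positions."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.sample_ids) + "\n")
        for j, mid in enumerate(g.marker_ids):
            gts = "\t".join(gt_map[int(c)] for c in g.genotypes[:, j])
            fh.write(f"1\t{j + 1}\t{mid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# QC

def _hwe_exact_midp(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Mid-p exact test of Hardy-Weinberg equilibrium (biallelic site).

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and returns the mid-p two-sided probability.
    """
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n == 0 or n_minor == 0 or n_minor == 2 * n:
        return 1.0
    n_minor = min(n_minor, 2 * n - n_minor)
    # log-probabilities of every feasible heterozygote count with same parity
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    from scipy.special import gammaln

    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_het][0]
    return float(np.sum(p[p < obs]) + 0.5 * np.sum(p[p == obs]))


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    hwe_p_min: float | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Drop markers failing MAF, missingness or (optional) HWE thresholds.

    A marker is removed when its minor-allele frequency is ``<= maf_min``,
    its missing-call rate is ``> miss_max``, or (when ``hwe_p_min`` is set)
    its HWE exact mid-p value in controls is below ``hwe_p_min``.
    """
    geno = g.genotypes
    obs = geno != MISSING
    miss_rate = 1.0 - obs.mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(obs, geno, 0).sum(axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1))
    maf = np.minimum(freq, 1.0 - freq)

    drop_maf = maf <= maf_min
    drop_miss = miss_rate > miss_max
    drop_hwe = np.zeros(g.n_markers, dtype=bool)
    if hwe_p_min is not None:
        controls = g.phenotype == 0
        for j in range(g.n_markers):
            col = geno[controls, j]
            col = col[col != MISSING]
            p = _hwe_exact_midp(
                int((col == 1).sum()), int((col == 2).sum()), int((col == 0).sum())
            )
            drop_hwe[j] = p < hwe_p_min

    keep = ~(drop_maf | drop_miss | drop_hwe)
    if not keep.any():
        raise ValueError("QC removed every marker")
    report = {
        "n_input": g.n_markers,
        "n_dropped_maf": int(drop_maf.sum()),
        "n_dropped_missing": int(drop_miss.sum()),
        "n_dropped_hwe": int(drop_hwe.sum()),
        "n_kept": int(keep.sum()),
    }
    kept = GenotypeMatrix(
        genotypes=geno[:, keep],
        phenotype=g.phenotype.copy(),
        marker_ids=[m for m, k in zip(g.marker_ids, keep) if k],
        sample_ids=list(g.sample_ids),
        metadata=dict(g.metadata),
    )
    return kept, report
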