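"""Case-control genotype simulator for two-locus epistasis models.

Three classic two-locus disease-odds models are supported, parameterised
by a baseline odds ``alpha`` and a genotype effect ``theta`` (``i``, ``j``
count disease-associated alleles at the two loci):

* Model 1 — independent multiplicative effects:  odds = alpha*(1+theta)^(i+j)
* Model 2 — multiplicative interaction only when both loci carry the
  allele:  odds = alpha*(1+theta)^(i*j)
* Model 3 — threshold:  odds = alpha*(1+theta) if i>=1 and j>=1 else alpha

Penetrance is odds/(1+odds).  Rather than choosing (alpha, theta)
directly, datasets are specified by interpretable population quantities —
a marginal per-allele odds-ratio parameter ``lambda`` (the odds ratio of
disease for one vs zero copies at a locus, marginalised over the other
locus under Hardy-Weinberg, equals 1 + lambda), a disease prevalence
``p``, the disease-locus minor-allele frequencies, and the LD strength
``r^2`` linking each disease locus to one tag marker.  A two-dimensional
root-find recovers (alpha, theta) from (lambda, p).

Sampling is retrospective: genotypes at the disease loci are drawn from
P(g | case) or P(g | control), each LD tag marker is generated allele-wise
from the conditional haplotype distribution, and null markers are
independent Hardy-Weinberg draws with MAFs uniform on a configurable
range.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .data import GenotypeMatrix

__all__ = [
    "DiseaseModelSpec",
    "SimParams",
    "HaplotypeDist",
    "odds_table",
    "penetrance_table",
    "solve_alpha_theta",
    "ld_haplotypes",
    "sample_dataset",
]


@dataclass(frozen=True)
class DiseaseModelSpec:
    """A two-locus odds model: id 1, 2 or 3 with baseline/effect parameters."""

    model: int
    alpha: float
    theta: float

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3):
            raise ValueError("model must be 1, 2 or 3")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")


@dataclass(frozen=True)
class SimParams:
    """Population and sampling parameters of one simulated dataset."""

    lambda_: float = 0.3
    prevalence: float = 0.1
    maf_a: float = 0.2
    maf_b: float = 0.2
    r2: float = 0.5
    n_cases: int = 1000
    n_controls: int = 1000
    n_null: int = 98
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    # MAF of each LD tag marker; None = same as its disease locus
    tag_maf: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_ <= -1:
            raise ValueError("lambda must exceed -1")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        for q in (self.maf_a, self.maf_b):
            if not (0.0 < q <= 0.5):
                raise ValueError("MAF must be in (0, 0.5]")
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must be in [0, 1]")


@dataclass(frozen=True)
class HaplotypeDist:
    """Two-locus haplotype frequencies consistent with the target r²."""

    pi_C: float
    pi_D: float
    pi_CD: float

    @property
    def pi_Cd(self) -> float:
        return self.pi_C - self.pi_CD

    @property
    def pi_cD(self) -> float:
        return self.pi_D - self.pi_CD

    @property
    def pi_cd(self) -> float:
        return 1.0 - self.pi_C - self.pi_D + self.pi_CD

    def r2(self) -> float:
        pc, pd = self.pi_C, self.pi_D
        denom = pc * (1 - pc) * pd * (1 - pd)
        return (self.pi_CD - pc * pd) ** 2 / denom


def odds_table(spec: DiseaseModelSpec) -> np.ndarray:
    """3x3 disease-odds matrix indexed by allele counts (i, j) at the loci."""
    i = np.arange(3)[:, None]
    j = np.arange(3)[None, :]
    a, t = spec.alpha, spec.theta
    if spec.model == 1:
        return a * (1.0 + t) ** (i + j)
    if spec.model == 2:
        return a * (1.0 + t) ** (i * j)
    return np.where((i >= 1) & (j >= 1), a * (1.0 + t), a) * np.ones((3, 3))


def penetrance_table(spec: DiseaseModelSpec) -> np.ndarray:
    odds = odds_table(spec)
    return odds / (1.0 + odds)


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """P(genotype = 0, 1, 2 copies of the coded allele) under Hardy-Weinberg."""
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def _lambda_prevalence(spec: DiseaseModelSpec, maf_a: float, maf_b: float) -> tuple[float, float]:
    """Marginal odds-ratio parameter and prevalence implied by a model."""
    pen = penetrance_table(spec)
    pa = hwe_genotype_probs(maf_a)
    pb = hwe_genotype_probs(maf_b)
    # P(D | g_A) marginalised over locus B under HWE
    p_d_given_ga = pen @ pb
    odds = p_d_given_ga / (1.0 - p_d_given_ga)
    lam = odds[1] / odds[0] - 1.0
    prev = float(pa @ pen @ pb)
    return float(lam), prev


def solve_alpha_theta(
    model: int,
    lambda_: float,
    prevalence: float,
    maf_a: float,
    maf_b: float,
    tol: float = 1e-10,
) -> DiseaseModelSpec:
    """Recover (alpha, theta) reproducing the target (lambda, prevalence).

    Solves the two-equation system by root-finding in
    ``(log alpha, log(1+theta))``, which keeps both parameters in range.
    Residuals are verified below 1e-8; infeasible targets raise.
    """
    if lambda_ == 0.0:
        spec = DiseaseModelSpec(model=model, alpha=prevalence / (1 - prevalence), theta=0.0)
        return spec

    def residuals(x):
        spec = DiseaseModelSpec(model=model, alpha=float(np.exp(x[0])), theta=float(np.expm1(x[1])))
        lam, prev = _lambda_prevalence(spec, maf_a, maf_b)
        return [lam - lambda_, prev - prevalence]

    x0 = np.array([np.log(prevalence / (1 - prevalence)), np.log1p(max(lambda_, 1e-3))])
    sol = optimize.root(residuals, x0, method="hybr", tol=tol)
    if not sol.success:
        raise RuntimeError(f"alpha/theta solver failed: {sol.message}")
    spec = DiseaseModelSpec(
        model=model, alpha=float(np.exp(sol.x[0])), theta=float(np.expm1(sol.x[1]))
    )
    lam, prev = _lambda_prevalence(spec, maf_a, maf_b)
    if abs(lam - lambda_) > 1e-8 or abs(prev - prevalence) > 1e-8:
        raise RuntimeError(
            f"targets not reproduced: lambda residual {lam - lambda_:.2e}, "
            f"prevalence residual {prev - prevalence:.2e}"
        )
    return spec


def ld_haplotypes(pi_C: float, pi_D: float, r2: float) -> HaplotypeDist:
    """Haplotype frequencies with the positive-coupling sign of r = +sqrt(r²)."""
    pc, pd = pi_C, pi_D
    pi_cd_prod = pc * (1 - pc) * pd * (1 - pd)
    pi_CD = pc * pd + np.sqrt(r2) * np.sqrt(pi_cd_prod)
    lo, hi = max(0.0, pc + pd - 1.0), min(pc, pd)
    if not (lo - 1e-12 <= pi_CD <= hi + 1e-12):
        raise ValueError(
            f"r2={r2} with pi_C={pc}, pi_D={pd} requires haplotype frequency "
            f"{pi_CD:.4f} outside the feasible range [{lo:.4f}, {hi:.4f}]"
        )
    return HaplotypeDist(pi_C=pc, pi_D=pd, pi_CD=float(np.clip(pi_CD, lo, hi)))


def _genotype_to_alleles(g: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Split genotype codes (0/1/2 copies) into two allele indicators."""
    n = g.shape[0]
    alleles = np.zeros((n, 2), dtype=np.int8)
    alleles[g == 2] = 1
    het = g == 1
    # a heterozygote carries one copy; which chromosome is immaterial
    which = rng.integers(0, 2, size=int(het.sum()))
    alleles[np.where(het)[0], which] = 1
    return alleles


def _sample_tag_marker(
    locus_geno: np.ndarray, hap: HaplotypeDist, rng: np.random.Generator
) -> np.ndarray:
    """Draw the tag-marker genotype allele-wise from P(C-allele | D-allele)."""
    alleles = _genotype_to_alleles(locus_geno, rng)
    p_c_given_d = hap.pi_CD / hap.pi_D
    p_c_given_not_d = hap.pi_Cd / (1.0 - hap.pi_D)
    probs = np.where(alleles == 1, p_c_given_d, p_c_given_not_d)
    marker_alleles = rng.random(alleles.shape) < probs
    return marker_alleles.sum(axis=1).astype(np.int8)


def sample_dataset(params: SimParams, model: int = 1) -> GenotypeMatrix:
    """Simulate one case-control dataset.

    The returned matrix has ``n_null + 4`` marker columns: two disease loci
    and one LD tag marker per locus, placed at random positions among the
    null markers.  ``metadata`` records the true-locus and tag indices, the
    solved (alpha, theta) and all parameters.
    """
    rng = np.random.default_rng(params.seed)
    spec = solve_alpha_theta(
        model, params.lambda_, params.prevalence, params.maf_a, params.maf_b
    )
    pen = penetrance_table(spec)
    pa = hwe_genotype_probs(params.maf_a)
    pb = hwe_genotype_probs(params.maf_b)
    joint = pa[:, None] * pb[None, :]

    p_case = pen * joint
    p_case /= p_case.sum()
    p_ctrl = (1.0 - pen) * joint
    p_ctrl /= p_ctrl.sum()

    n = params.n_cases + params.n_controls
    pheno = np.concatenate(
        [np.ones(params.n_cases, dtype=np.int8), np.zeros(params.n_controls, dtype=np.int8)]
    )

    cells_case = rng.choice(9, size=params.n_cases, p=p_case.ravel())
    cells_ctrl = rng.choice(9, size=params.n_controls, p=p_ctrl.ravel())
    cells = np.concatenate([cells_case, cells_ctrl])
    g_a = (cells // 3).astype(np.int8)
    g_b = (cells % 3).astype(np.int8)

    tag_maf_a = params.tag_maf if params.tag_maf is not None else params.maf_a
    tag_maf_b = params.tag_maf if params.tag_maf is not None else params.maf_b
    hap_a = ld_haplotypes(tag_maf_a, params.maf_a, params.r2)
    hap_b = ld_haplotypes(tag_maf_b, params.maf_b, params.r2)
    tag_a = _sample_tag_marker(g_a, hap_a, rng)
    tag_b = _sample_tag_marker(g_b, hap_b, rng)

    null_mafs = rng.uniform(*params.null_maf_range, size=params.n_null)
    nulls = rng.binomial(2, null_mafs[None, :].repeat(n, axis=0)).astype(np.int8)

    n_markers = params.n_null + 4
    order = rng.permutation(n_markers)
    special = {order[0]: g_a, order[1]: g_b, order[2]: tag_a, order[3]: tag_b}
    geno = np.empty((n, n_markers), dtype=np.int8)
    null_iter = iter(range(params.n_null))
    for j in range(n_markers):
        geno[:, j] = special.get(j, None) if j in special else nulls[:, next(null_iter)]

    names = {order[0]: "locusA", order[1]: "locusB", order[2]: "tagA", order[3]: "tagB"}
    marker_ids = [names.get(j, f"null{j}") for j in range(n_markers)]
    return GenotypeMatrix(
        genotypes=geno,
        phenotype=pheno,
        marker_ids=marker_ids,
        sample_ids=[f"s{i}" for i in range(n)],
        metadata={
            "model": model,
            "alpha": spec.alpha,
            "theta": spec.theta,
            "disease_loci": sorted((int(order[0]), int(order[1]))),
            "tag_markers": sorted((int(order[2]), int(order[3]))),
            "params": params,
        },
    )
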