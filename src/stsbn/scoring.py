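"""Decomposable local score of the disease node given a candidate parent set.

The score is a BIC-family criterion with an adjustable penalty coefficient:

    score = loglik - kappa * n_params * ln(N)

where ``loglik`` is the maximised multinomial log-likelihood of the disease
state D given the joint parent configuration,

    loglik = Σ_{j,k} N_jk ln(N_jk / N_j.)

and ``n_params = (Cat(D)-1) · Π_i Cat(parent_i)`` counts the free
conditional-probability parameters.  ``kappa = 0.5`` is the standard BIC;
the default ``kappa = 0.17`` softens the penalty for the moderate sample
sizes typical of case-control SNP panels.  Category counts use the
categories actually observed in each column, so a monomorphic marker
contributes a factor of 1.  No smoothing is applied — the plug-in ML
estimates are what BIC assumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LocalScore", "local_score", "DEFAULT_KAPPA"]

DEFAULT_KAPPA = 0.17


@dataclass(frozen=True)
class LocalScore:
    loglik: float
    penalty: float
    score: float
    n_params: int
    kappa: float


def local_score(d, parents=(), kappa: float = DEFAULT_KAPPA) -> LocalScore:
    """Score the disease vector ``d`` against a set of parent genotype vectors.

    Parameters
    ----------
    d : array-like of int
        Binary phenotype (1 = case, 0 = control).
    parents : sequence of array-like
        Genotype columns; an empty sequence scores the marginal
        distribution of ``d``.
    kappa : float
        Penalty coefficient multiplying ``n_params * ln(N)``.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    d = np.asarray(d)
    n = d.shape[0]
    if n == 0:
        raise ValueError("empty phenotype vector")
    parents = [np.asarray(p) for p in parents]
    for p in parents:
        if p.shape[0] != n:
            raise ValueError("parent length does not match phenotype length")

    d_cats, d_codes = np.unique(d, return_inverse=True)
    kd = len(d_cats)

    config = np.zeros(n, dtype=np.int64)
    n_parent_cfg = 1
    for p in parents:
        cats, codes = np.unique(p, return_inverse=True)
        config = config * len(cats) + codes
        n_parent_cfg *= len(cats)
    _, config = np.unique(config, return_inverse=True)
    ncfg = int(config.max()) + 1 if n else 0

    njk = np.bincount(config * kd + d_codes, minlength=ncfg * kd).reshape(ncfg, kd)
    nj = njk.sum(axis=1, keepdims=True)
    mask = njk > 0
    loglik = float(np.sum(njk[mask] * np.log(njk[mask] / nj.repeat(kd, axis=1)[mask])))

    n_params = (kd - 1) * n_parent_cfg
    penalty = kappa * n_params * np.log(n)
    return LocalScore(
        loglik=loglik,
        penalty=float(penalty),
        score=float(loglik - penalty),
        n_params=int(n_params),
        kappa=float(kappa),
    )
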