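"""Fixed-effects inverse-variance-weighted meta-analysis with heterogeneity.

Strata are pooled with weights w_i = 1/se_i^2:

    beta = sum(w_i b_i) / sum(w_i),   se = (sum w_i)^(-1/2),
    z = beta/se,                      p = two-sided normal tail,
    Q = sum w_i (b_i - beta)^2,       p_het ~ chi-square(k-1),
    I^2 = max(0, (Q - (k-1))/Q) * 100.

Fixed effects only: heterogeneity is reported, never acted on. Strata must
share the SNP, trait and coded allele — no silent allele flipping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

__all__ = ["MetaResult", "ivw", "ivw_meta", "meta_to_frame"]


@dataclass
class MetaResult:
    """Pooled effect for one SNP x trait x population, with heterogeneity."""

    snp: str
    trait: str
    population: str
    coded_allele: str
    beta: float
    se: float
    z: float
    p: float
    k: int
    q: float
    p_het: float
    i2: float  # percent, clipped at 0


def ivw(betas: Sequence[float], ses: Sequence[float]) -> tuple[float, float, float, float, float, float, float]:
    """Closed-form IVW pooling; returns (beta, se, z, p, Q, p_het, I2)."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise DomainError("cannot meta-analyze zero strata")
    if np.any(s <= 0) or np.any(~np.isfinite(s)):
        raise DomainError("all standard errors must be finite and > 0")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (b - beta) ** 2))
    k = b.size
    if k > 1:
        p_het = float(stats.chi2.sf(q, k - 1))
        i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    else:
        p_het = float("nan")
        i2 = 0.0
    return beta, se, z, p, q, p_het, i2


def ivw_meta(results: Sequence) -> MetaResult:
    """Pool per-stratum association results for one SNP/trait/coded allele.

    ``results`` are AssocResult-like objects (attributes snp, trait, beta,
    se, plus optional coded_allele / population). Strata flagged inestimable
    (``estimable=False``) must be removed by the caller beforehand.
    """
    results = list(results)
    if not results:
        raise DomainError("cannot meta-analyze zero strata")
    snps = {r.snp for r in results}
    traits = {r.trait for r in results}
    alleles = {getattr(r, "coded_allele", "coded") for r in results}
    if len(snps) > 1 or len(traits) > 1:
        raise DomainError(f"strata mix SNPs/traits: {snps} x {traits}")
    if len(alleles) > 1:
        raise DomainError(
            f"strata code different alleles {alleles}; flip explicitly before pooling"
        )
    beta, se, z, p, q, p_het, i2 = ivw([r.beta for r in results], [r.se for r in results])
    populations = {getattr(r, "population", "") for r in results}
    return MetaResult(
        snp=snps.pop(),
        trait=traits.pop(),
        population=populations.pop() if len(populations) == 1 else "pooled",
        coded_allele=alleles.pop(),
        beta=beta,
        se=se,
        z=z,
        p=p,
        k=len(results),
        q=q,
        p_het=p_het,
        i2=i2,
    )


def meta_to_frame(results: Sequence[MetaResult]) -> pd.DataFrame:
    """Tabular view of pooled results (one row per SNP x trait x population)."""
    return pd.DataFrame(
        {
            "snp": [r.snp for r in results],
            "coded_allele": [r.coded_allele for r in results],
            "trait": [r.trait for r in results],
            "population": [r.population for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "z": [r.z for r in results],
            "p": [r.p for r in results],
            "k": [r.k for r in results],
            "Q": [r.q for r in results],
            "p_het": [r.p_het for r in results],
            "I2": [round(r.i2, 2) for r in results],
        }
    )
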