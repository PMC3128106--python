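"""Population-structure descriptives: allele-frequency concordance,
Weir-Cockerham F_ST, and two-locus linkage disequilibrium.

Only coded-allele frequencies (not genotype counts) are available from
summary tables, so F_ST uses Hardy-Weinberg-implied heterozygosity
h_i = 2 p_i (1 - p_i). The two-population Weir-Cockerham variance-components
estimator is used, either with sample-size weighting (the default) or with
equal weights; the estimate theta = a / (a + b + c) is not truncated and may
be slightly negative for undifferentiated pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "FstComponents",
    "LDStats",
    "build_caf_table",
    "caf_correlation",
    "weir_cockerham_fst",
    "fst_panel_summary",
    "ld_r2",
    "ld_r2_from_genotypes",
]


@dataclass
class FstComponents:
    """Weir-Cockerham variance components and intermediates for two samples."""

    a: float
    b: float
    c: float
    n_bar: float
    n_c: float
    p_bar: float
    h_bar: float
    s2: float
    theta: float
    defined: bool = True


@dataclass
class LDStats:
    d: float
    r2: float
    d_prime: float
    p_a: float
    p_b: float
    defined: bool = True


def build_caf_table(
    tables: Mapping[str, pd.DataFrame],
    populations: Sequence[str] = ("EA", "AA", "AI", "MAH"),
    max_discrepancy: float = 0.01,
) -> pd.DataFrame:
    """Deduplicated SNP x population coded-allele-frequency panel.

    ``tables`` maps trait label to a long-format summary frame with columns
    snp, population, caf. A SNP appearing in several trait tables gets the
    mean of its per-table frequencies after asserting that they disagree by
    at most ``max_discrepancy`` in every population.
    """
    per_snp: dict[str, dict[str, list[float]]] = {}
    for df in tables.values():
        for _, row in df.iterrows():
            if pd.isna(row["caf"]):
                continue
            per_snp.setdefault(row["snp"], {}).setdefault(row["population"], []).append(
                float(row["caf"])
            )
    records = {}
    for snp, by_pop in per_snp.items():
        rec = {}
        for pop, vals in by_pop.items():
            if max(vals) - min(vals) > max_discrepancy + 1e-12:
                raise DomainError(
                    f"CAF for {snp} in {pop} differs across trait tables by more than "
                    f"{max_discrepancy}: {vals}"
                )
            rec[pop] = float(np.mean(vals))
        records[snp] = rec
    table = pd.DataFrame.from_dict(records, orient="index")
    return table.reindex(columns=[p for p in populations if p in table.columns])


def caf_correlation(table: pd.DataFrame, pop_a: str, pop_b: str) -> tuple[float, int]:
    """Pearson r between two populations' CAF columns over pairwise-complete SNPs.

    Returns (r, number of SNPs used); fewer than 3 complete pairs is an error.
    """
    sub = table[[pop_a, pop_b]].dropna()
    if len(sub) < 3:
        raise DomainError(f"need >= 3 SNPs with data in both {pop_a} and {pop_b}")
    r = float(np.corrcoef(sub[pop_a], sub[pop_b])[0, 1])
    return r, len(sub)


def weir_cockerham_fst(
    p1: float, n1: float, p2: float, n2: float, weighted: bool = True
) -> FstComponents:
    """Two-population Weir-Cockerham theta from allele frequencies and sample sizes.

    ``n1``/``n2`` are diploid sample sizes (individuals). ``weighted=False``
    replaces both by their mean, giving the equal-weight variant of the
    estimator. Monomorphic-in-both input (same allele fixed) has no defined
    differentiation and is flagged.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 <= p <= 1.0:
            raise DomainError(f"{name} must be in [0, 1], got {p}")
    if n1 < 2 or n2 < 2:
        raise DomainError("sample sizes must be >= 2 individuals")
    if (p1 == p2 == 0.0) or (p1 == p2 == 1.0):
        return FstComponents(0, 0, 0, (n1 + n2) / 2, np.nan, p1, 0.0, 0.0, np.nan, defined=False)
    if not weighted:
        n1 = n2 = (n1 + n2) / 2.0
    r = 2
    n_bar = (n1 + n2) / 2.0
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h1, h2 = 2 * p1 * (1 - p1), 2 * p2 * (1 - p2)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    denom = a + b + c
    theta = a / denom if denom != 0 else np.nan
    return FstComponents(a, b, c, n_bar, n_c, p_bar, h_bar, s2, float(theta), defined=np.isfinite(theta))


def fst_panel_summary(
    table: pd.DataFrame,
    ref_pop: str,
    n_by_pop: Mapping[str, float],
    threshold: float = 0.15,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-population count of SNPs with theta strictly above ``threshold``.

    Applies ``weir_cockerham_fst`` between each population column and the
    reference for every SNP with data in both; undefined thetas are dropped
    from numerator and denominator.
    """
    if ref_pop not in table.columns:
        raise DomainError(f"reference population {ref_pop!r} not in table")
    rows = []
    for pop in table.columns:
        if pop == ref_pop:
            continue
        sub = table[[ref_pop, pop]].dropna()
        thetas = [
            weir_cockerham_fst(a, n_by_pop[ref_pop], b, n_by_pop[pop], weighted=weighted).theta
            for a, b in zip(sub[ref_pop], sub[pop])
        ]
        thetas = [t for t in thetas if np.isfinite(t)]
        rows.append(
            {
                "population": pop,
                "n_snps": len(thetas),
                "n_above": int(sum(t > threshold for t in thetas)),
                "proportion": sum(t > threshold for t in thetas) / len(thetas) if thetas else np.nan,
            }
        )
    return pd.DataFrame(rows)


def ld_r2(hap_counts: Sequence[float]) -> LDStats:
    """LD statistics from four haplotype counts in the order (AB, Ab, aB, ab).

    D = f(AB) - f(A) f(B); r2 = D^2 / (pA qA pB qB); D' = D / Dmax with the
    usual sign-dependent Dmax. A locus monomorphic in the sample has no
    defined LD and is flagged.
    """
    counts = np.asarray(hap_counts, dtype=float)
    if counts.shape != (4,) or np.any(counts < 0) or counts.sum() <= 0:
        raise DomainError("need four non-negative haplotype counts with positive total")
    f = counts / counts.sum()
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    q_a, q_b = 1 - p_a, 1 - p_b
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LDStats(np.nan, np.nan, np.nan, p_a, p_b, defined=False)
    d = f[0] - p_a * p_b
    r2 = d * d / (p_a * q_a * p_b * q_b)
    d_max = min(p_a * q_b, q_a * p_b) if d > 0 else min(p_a * p_b, q_a * q_b)
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    return LDStats(float(d), float(r2), float(d_prime), float(p_a), float(p_b))


def ld_r2_from_genotypes(g_a, g_b) -> float:
    """Squared correlation of two dosage vectors.

    Under random union of gametes this estimates the haplotype r2 without
    phasing; no EM reconstruction is attempted.
    """
    a = np.asarray(g_a, dtype=float)
    b = np.asarray(g_b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2 or np.var(a) == 0 or np.var(b) == 0:
        raise DomainError("need two polymorphic dosage vectors")
    return float(np.corrcoef(a, b)[0, 1] ** 2)
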