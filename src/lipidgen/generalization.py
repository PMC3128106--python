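"""Replication and generalization classification of SNP-trait associations.

Replication: the association is significant (p < alpha, strict, uncorrected)
in the European-American reference meta-analysis. Generalization: the
association replicated in the reference AND, in every non-European population
with genotype data, is significant at the same threshold with the same
direction of effect as the reference. Populations without data are skipped
("if genotyped"); a SNP with no non-European data at all is not generalized.

Near-misses — p in [alpha, 2*alpha) — are tracked separately and never
counted as generalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "PopulationEvidence",
    "GeneralizationCall",
    "classify_replication",
    "classify_generalization",
    "count_significant",
    "summarize_generalization",
]

EA = "EA"
DEFAULT_NONEA = ("AA", "AI", "MAH")


@dataclass
class PopulationEvidence:
    available: bool
    significant: bool = False
    direction_match: bool = False
    near_miss: bool = False

    @property
    def supports(self) -> bool:
        return self.significant and self.direction_match


@dataclass
class GeneralizationCall:
    snp: str
    trait: str
    ea_replicated: bool
    evidence: dict[str, PopulationEvidence] = field(default_factory=dict)
    generalized: bool = False


def classify_replication(meta_ea, alpha: float = 0.05) -> bool:
    """True iff the reference-population p-value is strictly below alpha."""
    if meta_ea is None:
        raise DomainError("reference (EA) result is required")
    return bool(meta_ea.p < alpha)


def _direction_match(beta_pop: float, beta_ea: float) -> bool:
    # a zero effect matches neither direction
    return bool(np.sign(beta_pop) != 0 and np.sign(beta_pop) == np.sign(beta_ea))


def classify_generalization(
    meta_by_pop: Mapping[str, object],
    alpha: float = 0.05,
    ea_pop: str = EA,
    nonea_pops: Sequence[str] = DEFAULT_NONEA,
) -> GeneralizationCall:
    """Classify one SNP-trait association across populations.

    ``meta_by_pop`` maps population label to an object with ``beta`` and
    ``p`` attributes (a MetaResult or a fixture summary row); a missing key
    or ``None`` value means the SNP was not genotyped in that population.
    """
    ea = meta_by_pop.get(ea_pop)
    if ea is None:
        raise DomainError(f"no reference entry {ea_pop!r} in meta_by_pop")
    ea_replicated = classify_replication(ea, alpha)
    evidence: dict[str, PopulationEvidence] = {}
    for pop in nonea_pops:
        res = meta_by_pop.get(pop)
        if res is None or (isinstance(getattr(res, "p", None), float) and np.isnan(res.p)):
            evidence[pop] = PopulationEvidence(available=False)
            continue
        sig = bool(res.p < alpha)
        evidence[pop] = PopulationEvidence(
            available=True,
            significant=sig,
            direction_match=_direction_match(res.beta, ea.beta),
            near_miss=bool(alpha <= res.p < 2 * alpha),
        )
    available = [e for e in evidence.values() if e.available]
    generalized = (
        ea_replicated and len(available) > 0 and all(e.supports for e in available)
    )
    return GeneralizationCall(
        snp=getattr(ea, "snp", ""),
        trait=getattr(ea, "trait", ""),
        ea_replicated=ea_replicated,
        evidence=evidence,
        generalized=generalized,
    )


def count_significant(rows: pd.DataFrame, alpha: float = 0.05) -> tuple[int, int, float]:
    """(#significant, #with data, fraction) for one trait x population slice.

    ``rows`` needs a ``p`` column; rows with missing p are counted in
    neither numerator nor denominator.
    """
    if len(rows) == 0:
        raise DomainError("no rows to count")
    p = rows["p"].astype(float)
    with_data = int(p.notna().sum())
    if with_data == 0:
        raise DomainError("no rows with data to count")
    k = int((p < alpha).sum())
    return k, with_data, k / with_data


def summarize_generalization(calls: Iterable[GeneralizationCall]) -> dict:
    """Counts per trait, union tallies, and per-population support sets.

    Returns a dict with per-trait generalized counts, the number of
    generalized SNP-trait associations, the number of unique generalized
    SNPs, and — for Venn-style reporting — the set of (snp, trait) pairs
    each population supports (significant and direction-consistent).
    """
    calls = list(calls)
    seen = set()
    for c in calls:
        key = (c.snp, c.trait)
        if key in seen:
            raise DomainError(f"duplicate call for {key}")
        seen.add(key)
    per_trait: dict[str, int] = {}
    support_sets: dict[str, set] = {}
    generalized_pairs = []
    near_misses = []
    for c in calls:
        per_trait.setdefault(c.trait, 0)
        if c.generalized:
            per_trait[c.trait] += 1
            generalized_pairs.append((c.snp, c.trait))
        for pop, ev in c.evidence.items():
            support_sets.setdefault(pop, set())
            if ev.available and ev.supports:
                support_sets[pop].add((c.snp, c.trait))
            if ev.available and ev.near_miss:
                near_misses.append((c.snp, c.trait, pop))
    return {
        "generalized_per_trait": per_trait,
        "generalized_associations": len(generalized_pairs),
        "generalized_unique_snps": len({s for s, _ in generalized_pairs}),
        "generalized_pairs": sorted(generalized_pairs),
        "population_support_sets": support_sets,
        "near_misses": sorted(near_misses),
    }
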