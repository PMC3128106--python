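"""Synthetic multi-population cohort generation.

Generates individual-level participant tables with the statistical structure
the downstream association/meta-analysis pipeline assumes: Hardy-Weinberg
genotypes at population-specific coded-allele frequencies, optional two-locus
LD between a causal and a tag SNP, additive per-allele effects on HDL-C,
LDL-C and ln(TG), independent demographic/clinical covariates (with an
optional confounding hook), lipid-lowering-medication use with a subtractive
treatment effect, and fasting-hours sampling.

Triglycerides are simulated log-normally: the scenario's ``lnTG`` mean/SD and
betas live on the natural-log scale and the stored ``tg`` column is the
exponentiated value. Total cholesterol is generated as
``TC = LDL + HDL + TG/5`` so that the Friedewald equation recovers the
intended LDL-C wherever it is valid (TG <= 400 mg/dl).

All randomness flows from the scenario's single integer seed through named
streams (one per variable class), so adding a covariate or SNP to a scenario
never changes the genotypes already being drawn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import stream_rng
from .errors import ConfigurationError, DomainError
from .phenotypes import HDL, LDL, LNTG, TRAITS

__all__ = [
    "CovariateParams",
    "LinkedPairSpec",
    "LinkedPairResult",
    "PopulationScenario",
    "haplotype_frequencies",
    "simulate_genotypes",
    "simulate_linked_pair",
    "simulate_phenotypes",
    "simulate_study",
]

#: Trait key under which a medication offset applies to the measured
#: triglyceride concentration (mg/dl), as opposed to the analysis-scale lnTG.
TG_MGDL = "TG"


@dataclass(frozen=True)
class CovariateParams:
    """Population covariate distribution: prevalences and moments.

    Ages are drawn from a truncated normal; the default range deliberately
    includes minors so that the adult-only exclusion rule has work to do.
    Menopause and hormone use are defined for females only.
    """

    female_fraction: float = 0.55
    age_mean: float = 50.0
    age_sd: float = 16.0
    age_range: tuple[float, float] = (5.0, 100.0)
    bmi_mean: float = 28.0
    bmi_sd: float = 5.0
    smoking_rate: float = 0.25
    t2d_rate: float = 0.10
    menopause_rate: float = 0.50
    hormone_rate: float = 0.20
    prior_mi_rate: float = 0.05

    def rate_fields(self) -> dict[str, float]:
        return {
            "female_fraction": self.female_fraction,
            "smoking_rate": self.smoking_rate,
            "t2d_rate": self.t2d_rate,
            "menopause_rate": self.menopause_rate,
            "hormone_rate": self.hormone_rate,
            "prior_mi_rate": self.prior_mi_rate,
        }


@dataclass(frozen=True)
class LinkedPairSpec:
    """A causal/tag SNP pair with a target haplotype LD of ``target_r2``.

    The haplotype covariance D is derived as sqrt(r2 * pA qA * pB qB) with
    positive (coupling) sign, then clipped to the feasible range
    max(-pA pB, -qA qB) <= D <= min(pA qB, qA pB). When the requested r2 is
    infeasible for the given frequencies, the realized (clipped) r2 is used
    and a warning is emitted at simulation time.
    """

    causal_snp: str
    tag_snp: str
    p_causal: float
    p_tag: float
    target_r2: float

    def __post_init__(self) -> None:
        for name, p in (("p_causal", self.p_causal), ("p_tag", self.p_tag)):
            if not 0.0 < p < 1.0:
                raise DomainError(f"{name} must be in (0, 1), got {p}")
        if not 0.0 <= self.target_r2 <= 1.0:
            raise DomainError(f"target_r2 must be in [0, 1], got {self.target_r2}")


@dataclass
class LinkedPairResult:
    """Simulated diploid genotypes for a linked pair, plus LD bookkeeping."""

    g_causal: np.ndarray
    g_tag: np.ndarray
    hap_freqs: np.ndarray  # (AB, Ab, aB, ab) generating frequencies
    hap_counts: np.ndarray  # realized counts over the 2n haplotypes
    realized_r2: float  # r2 implied by the (possibly clipped) D
    requested_r2: float
    clipped: bool


@dataclass
class PopulationScenario:
    """Generating parameters for one population x study stratum.

    ``trait_means``/``trait_sds`` are the marginal mean and SD of each trait
    on its analysis scale (mg/dl for HDL-C and LDL-C, ln mg/dl for lnTG).
    ``snp_effects`` maps (snp, trait) to the per-coded-allele beta on that
    same scale. ``medication_offset`` maps a measured channel (HDL-C, LDL-C,
    or TG in mg/dl) to the additive treatment shift applied to participants
    on lipid-lowering medication (negative = lowering).
    ``covariate_effects`` is the confounding hook: (covariate, trait) ->
    slope per unit of the (mean-centered) covariate; by default covariates
    do not enter the trait model.
    """

    population: str
    study: str
    n_participants: int
    snp_freqs: Mapping[str, float] = field(default_factory=dict)
    trait_means: Mapping[str, float] = field(
        default_factory=lambda: {HDL: 52.0, LDL: 122.0, LNTG: 4.79}
    )
    trait_sds: Mapping[str, float] = field(
        default_factory=lambda: {HDL: 15.0, LDL: 35.0, LNTG: 0.50}
    )
    snp_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    covariates: CovariateParams = field(default_factory=CovariateParams)
    covariate_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    medication_rate: float = 0.0
    medication_offset: Mapping[str, float] = field(default_factory=dict)
    fasting_nonfasting_rate: float = 0.05
    missing_genotype_rate: float = 0.0
    linked_pairs: Sequence[LinkedPairSpec] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        for snp, p in self.snp_freqs.items():
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"frequency of {snp} must be in [0, 1], got {p}")
        for name, rate in {
            "medication_rate": self.medication_rate,
            "fasting_nonfasting_rate": self.fasting_nonfasting_rate,
            "missing_genotype_rate": self.missing_genotype_rate,
            **self.covariates.rate_fields(),
        }.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {rate}")
        for trait, sd in self.trait_sds.items():
            if sd <= 0:
                raise ConfigurationError(f"trait SD for {trait} must be > 0")
        for trait in self.trait_means:
            if trait not in TRAITS:
                raise ConfigurationError(f"unknown trait {trait!r}")

    def with_seed(self, seed: int) -> "PopulationScenario":
        return replace(self, seed=seed)


def simulate_genotypes(
    freq: float, n: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw n independent Hardy-Weinberg genotypes at coded-allele frequency ``freq``.

    Genotype counts follow P(2) = p^2, P(1) = 2p(1-p), P(0) = (1-p)^2, i.e.
    Binomial(2, p). Deterministic given ``seed`` (or an explicit ``rng``).
    """
    if not 0.0 <= freq <= 1.0:
        raise DomainError(f"allele frequency must be in [0, 1], got {freq}")
    if n < 1:
        raise DomainError("n must be >= 1")
    if rng is None:
        rng = stream_rng(0 if seed is None else seed, "genotypes")
    return rng.binomial(2, freq, size=n).astype(np.int64)


def haplotype_frequencies(spec: LinkedPairSpec) -> tuple[np.ndarray, float, bool]:
    """Two-locus haplotype frequencies (AB, Ab, aB, ab) realizing the target r2.

    Returns (frequencies, realized_r2, clipped). D is clipped into the
    feasible range when the requested r2 cannot be attained at the given
    allele frequencies.
    """
    pa, pb = spec.p_causal, spec.p_tag
    qa, qb = 1.0 - pa, 1.0 - pb
    d_raw = np.sqrt(spec.target_r2 * pa * qa * pb * qb)
    d_lo, d_hi = max(-pa * pb, -qa * qb), min(pa * qb, qa * pb)
    d = float(np.clip(d_raw, d_lo, d_hi))
    clipped = not np.isclose(d, d_raw)
    realized_r2 = d * d / (pa * qa * pb * qb)
    freqs = np.array([pa * pb + d, pa * qb - d, qa * pb - d, qa * qb + d])
    freqs = np.clip(freqs, 0.0, 1.0)
    return freqs / freqs.sum(), realized_r2, clipped


def simulate_linked_pair(
    spec: LinkedPairSpec, n: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> LinkedPairResult:
    """Draw 2n haplotypes from the two-locus table and pair them into diploids."""
    if n < 1:
        raise DomainError("n must be >= 1")
    freqs, realized_r2, clipped = haplotype_frequencies(spec)
    if clipped:
        warnings.warn(
            f"target r2={spec.target_r2} infeasible for frequencies "
            f"({spec.p_causal}, {spec.p_tag}); realizing r2={realized_r2:.4f}",
            stacklevel=2,
        )
    if rng is None:
        rng = stream_rng(0 if seed is None else seed, "linked-pair", spec.causal_snp, spec.tag_snp)
    # haplotype classes: 0=AB, 1=Ab, 2=aB, 3=ab
    haps = rng.choice(4, size=(n, 2), p=freqs)
    carries_a = (haps == 0) | (haps == 1)
    carries_b = (haps == 0) | (haps == 2)
    counts = np.bincount(haps.ravel(), minlength=4)
    return LinkedPairResult(
        g_causal=carries_a.sum(axis=1).astype(np.int64),
        g_tag=carries_b.sum(axis=1).astype(np.int64),
        hap_freqs=freqs,
        hap_counts=counts,
        realized_r2=realized_r2,
        requested_r2=spec.target_r2,
        clipped=clipped,
    )


def _covariate_frame(scenario: PopulationScenario) -> pd.DataFrame:
    cp = scenario.covariates
    n = scenario.n_participants
    rng = lambda name: stream_rng(scenario.seed, scenario.study, scenario.population, "covariate", name)
    female = rng("sex").random(n) < cp.female_fraction
    age = np.clip(rng("age").normal(cp.age_mean, cp.age_sd, n), *cp.age_range)
    bmi = np.clip(rng("bmi").normal(cp.bmi_mean, cp.bmi_sd, n), 12.0, 70.0)
    smoking = rng("smoking").random(n) < cp.smoking_rate
    t2d = rng("t2d").random(n) < cp.t2d_rate
    menopause = np.where(female, rng("menopause").random(n) < cp.menopause_rate, np.nan)
    hormone = np.where(female, rng("hormone").random(n) < cp.hormone_rate, np.nan)
    prior_mi = rng("prior_mi").random(n) < cp.prior_mi_rate
    nonfasting = rng("fasting").random(n) < scenario.fasting_nonfasting_rate
    fasting_hours = np.where(
        nonfasting,
        rng("fasting_hours").uniform(0.0, 8.0, n),
        rng("fasting_hours").uniform(8.0, 16.0, n),
    )
    on_med = rng("medication").random(n) < scenario.medication_rate
    return pd.DataFrame(
        {
            "sex": np.where(female, "F", "M"),
            "age": age,
            "bmi": bmi,
            "smoking": smoking,
            "t2d": t2d,
            "menopause": menopause,
            "hormone_use": hormone,
            "prior_mi": prior_mi,
            "fasting_hours": fasting_hours,
            "on_lipid_med": on_med,
        }
    )


_COVARIATE_VARIANCES = {
    "sex": lambda cp: cp.female_fraction * (1 - cp.female_fraction),
    "age": lambda cp: cp.age_sd**2,
    "bmi": lambda cp: cp.bmi_sd**2,
    "smoking": lambda cp: cp.smoking_rate * (1 - cp.smoking_rate),
    "t2d": lambda cp: cp.t2d_rate * (1 - cp.t2d_rate),
    "prior_mi": lambda cp: cp.prior_mi_rate * (1 - cp.prior_mi_rate),
}


def _covariate_numeric(cov: str, covariates: pd.DataFrame) -> np.ndarray:
    if cov == "sex":
        return (covariates["sex"].to_numpy() == "F").astype(float)
    if cov not in covariates.columns:
        raise ConfigurationError(f"unknown covariate {cov!r} in covariate_effects")
    return covariates[cov].to_numpy(dtype=float)


def _genetic_freq(scenario: PopulationScenario, snp: str) -> float:
    if snp in scenario.snp_freqs:
        return scenario.snp_freqs[snp]
    for pair in scenario.linked_pairs:
        if snp == pair.causal_snp:
            return pair.p_causal
        if snp == pair.tag_snp:
            return pair.p_tag
    raise ConfigurationError(f"snp_effects refers to unknown SNP {snp!r}")


def simulate_phenotypes(
    genotypes: Mapping[str, np.ndarray], scenario: PopulationScenario
) -> pd.DataFrame:
    """Build a full participant table from genotype vectors and a scenario.

    Each trait is ``mean + sum(beta * g) + covariate effects + N(0, sigma_e)``
    with sigma_e chosen so the marginal SD equals the scenario's trait SD
    (additive variance decomposition: sigma_e^2 = sd^2 - var_genetic -
    var_covariate, using scenario frequencies and covariate moments). A
    scenario whose genetic plus covariate variance meets or exceeds the trait
    variance is rejected.
    """
    n = scenario.n_participants
    for snp, g in genotypes.items():
        if len(g) != n:
            raise ConfigurationError(f"genotype vector for {snp} has length {len(g)} != {n}")
    covariates = _covariate_frame(scenario)

    analysis_values: dict[str, np.ndarray] = {}
    for trait in (HDL, LDL, LNTG):
        if trait not in scenario.trait_means:
            raise ConfigurationError(f"scenario must specify a mean and SD for {trait}")
        mean = scenario.trait_means[trait]
        sd = scenario.trait_sds[trait]
        systematic = np.zeros(n)
        var_explained = 0.0
        for (snp, t), beta in scenario.snp_effects.items():
            if t != trait:
                continue
            if snp not in genotypes:
                raise ConfigurationError(f"snp_effects refers to {snp!r} but no genotypes given")
            p = _genetic_freq(scenario, snp)
            systematic = systematic + beta * genotypes[snp]
            var_explained += 2.0 * p * (1.0 - p) * beta**2
            mean = mean - beta * 2.0 * p  # keep the marginal mean at trait_mean
        for (cov, t), slope in scenario.covariate_effects.items():
            if t != trait:
                continue
            if cov not in _COVARIATE_VARIANCES:
                raise ConfigurationError(
                    f"covariate {cov!r} cannot act on traits (sex-conditional or unknown)"
                )
            x = _covariate_numeric(cov, covariates)
            systematic = systematic + slope * (x - x.mean())
            var_explained += slope**2 * _COVARIATE_VARIANCES[cov](scenario.covariates)
        if var_explained >= sd**2:
            raise ConfigurationError(
                f"genetic+covariate variance {var_explained:.3g} >= trait variance "
                f"{sd**2:.3g} for {trait}"
            )
        noise_rng = stream_rng(scenario.seed, scenario.study, scenario.population, "noise", trait)
        sigma_e = np.sqrt(sd**2 - var_explained)
        analysis_values[trait] = mean + systematic + noise_rng.normal(0.0, sigma_e, n)

    hdl = analysis_values[HDL]
    ldl = analysis_values[LDL]
    tg = np.exp(analysis_values[LNTG])

    on_med = covariates["on_lipid_med"].to_numpy()
    if scenario.medication_offset:
        offsets = scenario.medication_offset
        hdl = np.where(on_med, hdl + offsets.get(HDL, 0.0), hdl)
        ldl = np.where(on_med, ldl + offsets.get(LDL, 0.0), ldl)
        tg = np.where(on_med, np.maximum(tg + offsets.get(TG_MGDL, 0.0), 1e-6), tg)
    hdl = np.maximum(hdl, 1e-6)
    ldl = np.maximum(ldl, 1e-6)
    tc = ldl + hdl + tg / 5.0

    table = pd.DataFrame(
        {
            "participant_id": [
                f"{scenario.study}-{scenario.population}-{i:06d}" for i in range(n)
            ],
            "population": scenario.population,
            "study": scenario.study,
        }
    )
    table = pd.concat([table, covariates], axis=1)
    miss_rng = stream_rng(scenario.seed, scenario.study, scenario.population, "missingness")
    for snp, g in genotypes.items():
        col = g.astype(float)
        if scenario.missing_genotype_rate > 0:
            col[miss_rng.random(n) < scenario.missing_genotype_rate] = np.nan
        table[snp] = col
    table["tc"] = tc
    table["hdl"] = hdl
    table["tg"] = tg
    return table


def simulate_study(scenario: PopulationScenario) -> pd.DataFrame:
    """Draw all genotypes declared by a scenario and build its participant table."""
    genotypes: dict[str, np.ndarray] = {}
    for snp, freq in scenario.snp_freqs.items():
        rng = stream_rng(scenario.seed, scenario.study, scenario.population, "genotype", snp)
        genotypes[snp] = simulate_genotypes(freq, scenario.n_participants, rng=rng)
    for pair in scenario.linked_pairs:
        rng = stream_rng(
            scenario.seed, scenario.study, scenario.population, "linked", pair.causal_snp, pair.tag_snp
        )
        result = simulate_linked_pair(pair, scenario.n_participants, rng=rng)
        genotypes[pair.causal_snp] = result.g_causal
        genotypes[pair.tag_snp] = result.g_tag
    return simulate_phenotypes(genotypes, scenario)
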