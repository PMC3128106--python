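"""Per-stratum linear regression of a lipid trait on coded-allele dose.

The genetic model is additive: the trait regresses on the 0/1/2 count of the
coded allele, optionally with covariate adjustment. Four covariate models are
supported:

1. unadjusted;
2. age and sex;
3. age, BMI, current smoking, type-2 diabetes, post-menopausal status and
   current hormone use — fitted within sex strata because the last two are
   defined for females only (males get age, BMI, smoking, T2D);
4. model 3 plus previous myocardial infarction.

Study site can enter any model as a categorical fixed effect. Missing data
are handled by complete-case analysis. p-values use the t reference with the
residual degrees of freedom; the pooling layer (``meta_analysis``) uses the
normal reference, as is conventional for inverse-variance meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, SchemaError
from .phenotypes import trait_values

__all__ = ["ModelSpec", "AssocResult", "compute_caf", "fit_additive_model", "results_to_frame"]

_MODEL_COVARIATES = {
    1: (),
    2: ("age", "sex"),
    3: ("age", "bmi", "smoking", "t2d", "menopause", "hormone_use"),
    4: ("age", "bmi", "smoking", "t2d", "menopause", "hormone_use", "prior_mi"),
}
_FEMALE_ONLY = ("menopause", "hormone_use")


@dataclass(frozen=True)
class ModelSpec:
    """Covariate model 1-4, with an optional site-of-ascertainment factor."""

    model_id: int = 2
    include_site: bool = False

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_COVARIATES:
            raise DomainError(f"model_id must be 1-4, got {self.model_id}")

    @property
    def covariates(self) -> tuple[str, ...]:
        return _MODEL_COVARIATES[self.model_id]

    @property
    def sex_stratified(self) -> bool:
        return self.model_id in (3, 4)


@dataclass
class AssocResult:
    """One SNP x trait x stratum association record (the summary-row schema)."""

    snp: str
    trait: str
    population: str
    study: str
    stratum: str
    model_id: int
    n: int
    caf: float
    beta: float
    se: float
    p: float
    df: int
    coded_allele: str = "coded"
    estimable: bool = True


def compute_caf(genotypes) -> float:
    """Coded-allele frequency: (sum of dosages) / (2 x non-missing count)."""
    g = np.asarray(genotypes, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise DomainError("cannot compute CAF: all genotypes missing")
    return float(g.sum() / (2.0 * g.size))


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Least-squares fit returning (coef, se, residual df); X includes intercept."""
    n, p = x.shape
    xtx = x.T @ x
    coef = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ coef
    df = n - p
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(np.linalg.inv(xtx)) * sigma2)
    return coef, se, df


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    involved = []
    for j in range(x.shape[1]):
        reduced = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            involved.append(names[j])
    raise SchemaError(f"design matrix is rank-deficient; collinear columns: {involved}")


def _design(frame: pd.DataFrame, snp: str, covariates: tuple[str, ...], include_site: bool):
    cols: list[np.ndarray] = [np.ones(len(frame)), frame[snp].to_numpy(dtype=float)]
    names = ["intercept", snp]
    for cov in covariates:
        if cov == "sex":
            cols.append((frame["sex"].to_numpy() == "F").astype(float))
        else:
            cols.append(frame[cov].to_numpy(dtype=float))
        names.append(cov)
    if include_site:
        sites = sorted(frame["study"].unique())
        for site in sites[1:]:  # first level is the reference
            cols.append((frame["study"].to_numpy() == site).astype(float))
            names.append(f"site[{site}]")
    return np.column_stack(cols), names


def fit_additive_model(
    participants: pd.DataFrame, snp: str, trait_kind: str, model: ModelSpec = ModelSpec(2)
) -> list[AssocResult]:
    """OLS of the trait on coded-allele dose under the given covariate model.

    Expects an exclusion-filtered participant table. Returns one result for
    models 1-2, or one per sex stratum for the sex-stratified models 3-4.
    Complete cases only; monomorphic SNPs yield a result flagged
    ``estimable=False`` rather than an error.
    """
    if snp not in participants.columns:
        raise SchemaError(f"no genotype column {snp!r} in participant table")
    work = participants.copy()
    work["_y"] = trait_values(work, trait_kind)

    def _complete(frame: pd.DataFrame, covs: tuple[str, ...]) -> pd.DataFrame:
        cols = ["_y", snp, *covs]
        return frame.dropna(subset=[c for c in cols if c in frame.columns])

    if not model.sex_stratified:
        frame = _complete(work, model.covariates)
        return [_fit_strat(frame, snp, trait_kind, model, "all", model.covariates)]
    results = []
    for sex in ("F", "M"):
        covs = (
            model.covariates
            if sex == "F"
            else tuple(c for c in model.covariates if c not in _FEMALE_ONLY)
        )
        sub = _complete(work[work["sex"] == sex], covs)
        results.append(_fit_strat(sub, snp, trait_kind, model, sex, covs))
    return results


def _fit_strat(frame, snp, trait_kind, model, label, covs) -> AssocResult:
    population = str(frame["population"].iloc[0]) if len(frame) else ""
    g = frame[snp].to_numpy(dtype=float)
    if np.nanvar(g) == 0.0 or len(frame) == 0:
        return AssocResult(
            snp=snp,
            trait=trait_kind,
            population=population,
            study="+".join(sorted(frame["study"].unique())) if len(frame) else "",
            stratum=label,
            model_id=model.model_id,
            n=len(frame),
            caf=compute_caf(g) if len(frame) else np.nan,
            beta=np.nan,
            se=np.nan,
            p=np.nan,
            df=0,
            estimable=False,
        )
    x, names = _design(frame, snp, covs, model.include_site)
    y = frame["_y"].to_numpy(dtype=float)
    if len(frame) < x.shape[1] + 2:
        raise DomainError(f"too few complete cases in sex stratum {label} for {snp}")
    _check_rank(x, names)
    coef, se, df = _ols(y, x)
    t = float(coef[1] / se[1])
    return AssocResult(
        snp=snp,
        trait=trait_kind,
        population=population,
        study="+".join(sorted(frame["study"].unique())),
        stratum=label,
        model_id=model.model_id,
        n=len(frame),
        caf=compute_caf(g),
        beta=float(coef[1]),
        se=float(se[1]),
        p=float(2.0 * stats.t.sf(abs(t), df)),
        df=df,
    )


def results_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    """Summary-row table: snp, coded_allele, trait, population, study, model, n, caf, beta, se, p, df."""
    return pd.DataFrame(
        {
            "snp": [r.snp for r in results],
            "coded_allele": [r.coded_allele for r in results],
            "trait": [r.trait for r in results],
            "population": [r.population for r in results],
            "study": [r.study for r in results],
            "stratum": [r.stratum for r in results],
            "model": [r.model_id for r in results],
            "n": [r.n for r in results],
            "caf": [r.caf for r in results],
            "beta": [r.beta for r in results],
            "se": [r.se for r in results],
            "p": [r.p for r in results],
            "df": [r.df for r in results],
        }
    )
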