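"""Bundled summary-statistic fixtures, table I/O, scenario configuration,
and the end-to-end reproduction report.

The package ships a transcribed panel of published meta-analysis summary
statistics for 49 GWAS lipid SNPs — 27 HDL-C, 19 LDL-C and 14 ln(TG)
SNP-trait rows — across four populations (European American EA, African
American AA, American Indian AI, Mexican American/Hispanic MAH), each with
coded-allele frequency, beta (SE), p-value and a published
generalized-yes/no label, plus the published observed-versus-expected
significance table. ``reproduce`` re-derives every classification and
descriptive statistic from those rows and diffs them against the published
labels.

P-values are stored as printed text and parsed on demand so the printed
precision is preserved; "NA" and "-" denote missing cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import generalization as gen
from . import pop_structure, power_calibration
from .association import ModelSpec, fit_additive_model
from .errors import ConfigurationError, SchemaError
from .meta_analysis import ivw_meta
from .phenotypes import HDL, LDL, LNTG, apply_exclusions
from .synthetic_cohorts import LinkedPairSpec, PopulationScenario, CovariateParams, simulate_study

__all__ = [
    "POPULATIONS",
    "TRAITS",
    "FixtureSet",
    "SummaryEntry",
    "load_summary_table",
    "load_fixtures",
    "write_summary_rows",
    "read_summary_rows",
    "load_scenario",
    "reproduce",
    "tag_transfer_experiment",
]

POPULATIONS = ("EA", "AA", "AI", "MAH")
TRAITS = (HDL, LDL, LNTG)
_TRAIT_FILES = {HDL: "hdl_summary.tsv", LDL: "ldl_summary.tsv", LNTG: "tg_summary.tsv"}
_EXPECTED_ROWS = {HDL: 27, LDL: 19, LNTG: 14}

#: smallest positive double; used for p-values printed below representable range
_P_UNDERFLOW = 5e-324


@dataclass
class SummaryEntry:
    """One SNP x trait x population record from a summary table."""

    snp: str
    trait: str
    population: str
    beta: float
    p: float
    se: float = float("nan")
    caf: float = float("nan")


@dataclass
class FixtureSet:
    """The bundled published panel in long form, plus sizes and the
    observed/expected table."""

    tables: dict[str, pd.DataFrame]
    expected_observed: pd.DataFrame
    population_sizes: pd.DataFrame
    sources: dict[str, str] = field(default_factory=dict)

    def n_rows(self) -> int:
        return sum(df["snp"].nunique() for df in self.tables.values())


def _parse_p(text: object, where: str) -> tuple[float, bool]:
    if pd.isna(text) or text in ("", "NA", "-", "–"):
        return float("nan"), False
    try:
        value = float(str(text))
    except ValueError as exc:
        raise SchemaError(f"malformed p-value {text!r} at {where}") from exc
    if value == 0.0 and any(ch in "123456789" for ch in str(text)):
        return _P_UNDERFLOW, True  # printed positive but below double range
    if not 0.0 <= value <= 1.0:
        raise SchemaError(f"p-value {value} outside (0, 1] at {where}")
    return value, False


def load_summary_table(path, trait: str) -> pd.DataFrame:
    """Read a wide per-SNP summary table into long (snp x population) form.

    The wide layout mirrors the published tables: one row per SNP with
    ``{POP}_caf/_beta/_se/_p`` blocks and a ``generalized`` Y/N label.
    Returns columns snp, gene, coded_allele, trait, population, caf, beta,
    se, p, p_text, p_underflow, generalized. Missing cells ("NA"/"-") give
    NaN; scientific-notation p-values are parsed, and a printed value below
    the representable range is replaced by the smallest positive double and
    flagged.
    """
    wide = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", "-", "–"])
    if len(wide) == 0:
        raise SchemaError(f"{path}: empty summary table")
    required = {"snp", "coded_allele", "generalized"} | {
        f"{pop}_{f}" for pop in POPULATIONS for f in ("caf", "beta", "se", "p")
    }
    missing = required - set(wide.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    dup = wide["snp"][wide["snp"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate SNPs {sorted(dup)}")
    records = []
    for i, row in wide.iterrows():
        if row["generalized"] not in ("Y", "N"):
            raise SchemaError(f"{path} row {i}: generalized label must be Y or N")
        for pop in POPULATIONS:
            p, underflow = _parse_p(row[f"{pop}_p"], f"{path} row {i} ({pop})")
            caf = float(row[f"{pop}_caf"]) if pd.notna(row[f"{pop}_caf"]) else np.nan
            if pd.notna(caf) and not 0.0 <= caf <= 1.0:
                raise SchemaError(f"{path} row {i}: CAF {caf} outside [0, 1]")
            records.append(
                {
                    "snp": row["snp"],
                    "gene": row.get("gene", ""),
                    "coded_allele": row["coded_allele"],
                    "trait": trait,
                    "population": pop,
                    "caf": caf,
                    "beta": float(row[f"{pop}_beta"]) if pd.notna(row[f"{pop}_beta"]) else np.nan,
                    "se": float(row[f"{pop}_se"]) if pd.notna(row[f"{pop}_se"]) else np.nan,
                    "p": p,
                    "p_text": row[f"{pop}_p"] if pd.notna(row[f"{pop}_p"]) else "NA",
                    "p_underflow": underflow,
                    "generalized": row["generalized"],
                }
            )
    return pd.DataFrame.from_records(records)


def load_fixtures() -> FixtureSet:
    """Load the bundled published summary panel."""
    root = resources.files("lipidgen") / "data"
    tables = {
        trait: load_summary_table(root / fname, trait) for trait, fname in _TRAIT_FILES.items()
    }
    for trait, df in tables.items():
        n = df["snp"].nunique()
        if n != _EXPECTED_ROWS[trait]:
            raise SchemaError(f"{trait} fixture has {n} SNPs, expected {_EXPECTED_ROWS[trait]}")
    eo = pd.read_csv(root / "expected_observed.tsv", sep="\t")
    sizes = pd.read_csv(root / "population_sizes.tsv", sep="\t")
    return FixtureSet(
        tables=tables,
        expected_observed=eo,
        population_sizes=sizes,
        sources={t: f for t, f in _TRAIT_FILES.items()},
    )


def write_summary_rows(frame: pd.DataFrame, path) -> None:
    """Write a long summary-row table as UTF-8 TSV with 'NA' for missing."""
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_summary_rows(path) -> pd.DataFrame:
    """Read back a long summary-row table written by :func:`write_summary_rows`.

    The ``p_text`` column (if present) is kept verbatim — it records the
    p-value at its printed precision and must survive round trips.
    """
    header = pd.read_csv(path, sep="\t", nrows=0).columns
    na = {col: ["NA"] for col in header if col != "p_text"}
    dtype = {"p_text": str} if "p_text" in header else None
    return pd.read_csv(path, sep="\t", na_values=na, keep_default_na=False, dtype=dtype)


def _entries_by_pop(table: pd.DataFrame, snp: str, trait: str) -> dict[str, SummaryEntry]:
    out: dict[str, SummaryEntry] = {}
    for _, row in table[table["snp"] == snp].iterrows():
        if pd.isna(row["p"]) or pd.isna(row["beta"]):
            continue
        out[row["population"]] = SummaryEntry(
            snp=snp,
            trait=trait,
            population=row["population"],
            beta=float(row["beta"]),
            p=float(row["p"]),
            se=float(row["se"]) if pd.notna(row["se"]) else float("nan"),
            caf=float(row["caf"]) if pd.notna(row["caf"]) else float("nan"),
        )
    return out


def classify_fixture_table(table: pd.DataFrame, trait: str, alpha: float = 0.05):
    """Generalization calls for every SNP of one long-format fixture table."""
    calls = []
    for snp in table["snp"].unique():
        by_pop = _entries_by_pop(table, snp, trait)
        calls.append(gen.classify_generalization(by_pop, alpha=alpha))
    return calls


def reproduce(fixtures: FixtureSet | None = None, alpha: float = 0.05) -> dict:
    """Recompute every classification and descriptive from the bundled panel.

    Returns a report dict with: reference (EA) replication counts, per-trait
    per-population significant counts, generalization calls and their diff
    against the published Y/N labels, the generalized-count summaries,
    CAF concordance (Pearson r) and F_ST descriptives versus EA, and the
    observed-vs-expected binomial p-values recomputed from the printed
    (m, k, E) triples. Deterministic: no RNG is touched.
    """
    fx = fixtures or load_fixtures()

    ea_total = ea_replicated = 0
    significant_counts: dict[str, dict[str, str]] = {}
    all_calls = []
    g_diff = []
    for trait, table in fx.tables.items():
        for pop in POPULATIONS:
            sub = table[(table["population"] == pop)][["p"]]
            k, m, _ = gen.count_significant(sub, alpha=alpha)
            significant_counts.setdefault(trait, {})[pop] = f"{k}/{m}"
        ea = table[table["population"] == "EA"]
        ea_total += len(ea)
        ea_replicated += int((ea["p"] < alpha).sum())
        printed = dict(zip(ea["snp"], ea["generalized"]))
        calls = classify_fixture_table(table, trait, alpha=alpha)
        for call in calls:
            label = "Y" if call.generalized else "N"
            if label != printed[call.snp]:
                g_diff.append((call.snp, trait, printed[call.snp], label))
        all_calls.extend(calls)
    summary = gen.summarize_generalization(all_calls)

    # per-population observed significant among EA-replicated tests (the
    # observed/expected table's k and m)
    observed: dict[str, dict[str, str]] = {}
    for trait, table in fx.tables.items():
        ea = table[(table["population"] == "EA") & (table["p"] < alpha)]
        replicated_snps = set(ea["snp"])
        for pop in [p for p in POPULATIONS if p != "EA"]:
            sub = table[
                (table["population"] == pop)
                & table["snp"].isin(replicated_snps)
                & table["p"].notna()
            ]
            k = int((sub["p"] < alpha).sum())
            observed.setdefault(trait, {})[pop] = f"{k}/{len(sub)}"

    long_concat = {t: df for t, df in fx.tables.items()}
    caf = pop_structure.build_caf_table(long_concat, populations=POPULATIONS)
    correlations = {}
    for pop in [p for p in POPULATIONS if p != "EA"]:
        r, n_used = pop_structure.caf_correlation(caf, "EA", pop)
        correlations[pop] = {"r": round(r, 2), "n_snps": n_used}
    n_by_pop = fx.population_sizes.groupby("population")["n_max"].max().to_dict()
    fst_panel = pop_structure.fst_panel_summary(caf, "EA", n_by_pop, threshold=0.15)

    sizes_hdl = fx.population_sizes[fx.population_sizes["trait"] == HDL].set_index("population")
    fst_rs174547 = pop_structure.weir_cockerham_fst(
        0.66, float(sizes_hdl.loc["EA", "n_max"]), 0.91, float(sizes_hdl.loc["AA", "n_max"])
    ).theta

    eo = fx.expected_observed.copy()
    eo["p_recomputed"] = [
        round(
            power_calibration.binomial_test_observed(
                int(r.n_observed), int(r.n_tests), float(r.n_expected), sided="two-sided"
            ),
            2,
        )
        for r in eo.itertuples()
    ]
    eo["match"] = eo["p_recomputed"] == eo["p_printed"].round(2)

    return {
        "alpha": alpha,
        "ea_replicated": ea_replicated,
        "ea_total": ea_total,
        "significant_counts": significant_counts,
        "observed_among_replicated": observed,
        "generalized_per_trait": summary["generalized_per_trait"],
        "generalized_associations": summary["generalized_associations"],
        "generalized_unique_snps": summary["generalized_unique_snps"],
        "generalized_pairs": summary["generalized_pairs"],
        "near_misses": summary["near_misses"],
        "g_diff": g_diff,
        "caf_correlations": correlations,
        "fst_panel": fst_panel.to_dict(orient="records"),
        "fst_rs174547_ea_aa": round(fst_rs174547, 2),
        "expected_observed": eo.to_dict(orient="records"),
    }


def report_to_json(report: dict) -> str:
    """Serialize a reproduction report, converting sets/tuples for JSON."""

    def _default(obj):
        if isinstance(obj, set):
            return sorted(obj)
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    return json.dumps(report, indent=2, default=_default)


def load_scenario(path) -> PopulationScenario:
    """Build a PopulationScenario from a YAML config file.

    Nested keys mirror the dataclass fields; ``snp_effects`` is a list of
    {snp, trait, beta} mappings, ``linked_pairs`` a list of
    {causal_snp, tag_snp, p_causal, p_tag, target_r2}.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: scenario config must be a mapping")
    effects = {
        (e["snp"], e["trait"]): float(e["beta"]) for e in raw.pop("snp_effects", [])
    }
    cov_effects = {
        (e["covariate"], e["trait"]): float(e["slope"])
        for e in raw.pop("covariate_effects", [])
    }
    pairs = tuple(LinkedPairSpec(**p) for p in raw.pop("linked_pairs", []))
    covariates = CovariateParams(**raw.pop("covariates", {}))
    try:
        return PopulationScenario(
            snp_effects=effects,
            covariate_effects=cov_effects,
            linked_pairs=pairs,
            covariates=covariates,
            **raw,
        )
    except TypeError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def tag_transfer_experiment(
    seed: int,
    n: int = 4000,
    beta: float = 2.0,
    p_causal: float = 0.3,
    p_tag: float = 0.3,
    r2_pop1: float = 0.9,
    r2_pop2: float = 0.0,
    alpha: float = 0.05,
) -> dict:
    """Mechanistic tag-SNP transferability demonstration.

    A causal SNP carries a true HDL-C effect in a reference population (EA)
    and two target populations. The genotyped tag SNP sits at LD r2 =
    ``r2_pop1`` with the causal SNP in the reference and first target
    population but at ``r2_pop2`` (default: no LD) in the second. With LD
    broken, the tag association is expected to fail in population 2 while
    the causal SNP generalizes to both — the classic reason a replicated
    association does not transfer across ancestries.

    Returns generalization calls for the causal and tag SNPs plus the
    per-population pooled results.
    """
    meta = {"causal": {}, "tag": {}}
    for pop, r2 in (("EA", r2_pop1), ("P1", r2_pop1), ("P2", r2_pop2)):
        scenario = PopulationScenario(
            population=pop,
            study=f"SIM-{pop}",
            n_participants=n,
            linked_pairs=(
                LinkedPairSpec("causal", "tag", p_causal, p_tag, r2),
            ),
            snp_effects={("causal", HDL): beta},
            seed=seed,
        )
        table = simulate_study(scenario)
        kept, _ = apply_exclusions(table, HDL)
        for snp in ("causal", "tag"):
            res = fit_additive_model(kept, snp, HDL, ModelSpec(2))
            meta[snp][pop] = ivw_meta(res)
    calls = {
        snp: gen.classify_generalization(meta[snp], alpha=alpha, nonea_pops=("P1", "P2"))
        for snp in ("causal", "tag")
    }
    return {"calls": calls, "meta": meta}
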