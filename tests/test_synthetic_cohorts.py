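"""Simulator correctness: HWE sampling, LD calibration, variance budgeting,
medication effects, and seed reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidgen.errors import ConfigurationError, DomainError
from lipidgen.phenotypes import HDL, LDL, LNTG
from lipidgen.pop_structure import ld_r2
from lipidgen.synthetic_cohorts import (
    LinkedPairSpec,
    PopulationScenario,
    haplotype_frequencies,
    simulate_genotypes,
    simulate_linked_pair,
    simulate_phenotypes,
    simulate_study,
)


def _scenario(**kw):
    defaults = dict(population="EA", study="S", n_participants=1000, seed=7)
    defaults.update(kw)
    return PopulationScenario(**defaults)


class TestGenotypes:
    def test_degenerate_frequencies(self):
        assert np.all(simulate_genotypes(0.0, 100, seed=1) == 0)
        assert np.all(simulate_genotypes(1.0, 100, seed=1) == 2)

    def test_frequency_out_of_range(self):
        with pytest.raises(DomainError):
            simulate_genotypes(1.2, 10, seed=1)

    def test_mean_and_hwe_at_large_n(self):
        n, p = 50_000, 0.3
        g = simulate_genotypes(p, n, seed=123)
        # mean dosage: 3 Monte-Carlo SEs around 2p
        se = np.sqrt(2 * p * (1 - p) / n)
        assert abs(g.mean() - 2 * p) < 3 * se
        observed = np.bincount(g, minlength=3)
        expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=2) > 0.001


class TestLinkedPair:
    def test_perfect_ld_equal_frequencies_gives_identical_vectors(self):
        res = simulate_linked_pair(LinkedPairSpec("c", "t", 0.3, 0.3, 1.0), 5000, seed=3)
        assert np.array_equal(res.g_causal, res.g_tag)
        assert res.realized_r2 == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "pa,pb,r2",
        [(0.3, 0.3, 0.5), (0.2, 0.4, 0.3), (0.5, 0.5, 1.0), (0.1, 0.3, 0.15), (0.3, 0.3, 0.0)],
    )
    def test_realized_r2_matches_feasible_target(self, pa, pb, r2):
        n = 100_000
        res = simulate_linked_pair(LinkedPairSpec("c", "t", pa, pb, r2), n, seed=11)
        assert not res.clipped
        emp = ld_r2(res.hap_counts).r2
        root = np.sqrt(r2)
        tol = max(3 * 2 * root * (1 - r2) / np.sqrt(2 * n), 0.005)
        assert emp == pytest.approx(res.realized_r2, abs=tol)

    def test_infeasible_target_is_clipped_with_warning(self):
        # max attainable r2 for frequencies (0.2, 0.4) is 0.12^2/(0.16*0.24)
        spec = LinkedPairSpec("c", "t", 0.2, 0.4, 0.5)
        with pytest.warns(UserWarning, match="infeasible"):
            res = simulate_linked_pair(spec, 1000, seed=5)
        assert res.clipped
        assert res.realized_r2 == pytest.approx(0.12**2 / (0.16 * 0.24))

    def test_haplotype_frequencies_sum_to_one(self):
        freqs, _, _ = haplotype_frequencies(LinkedPairSpec("c", "t", 0.25, 0.6, 0.2))
        assert freqs.sum() == pytest.approx(1.0)
        assert np.all(freqs >= 0)


class TestPhenotypes:
    def test_marginal_moments_match_scenario(self):
        sc = _scenario(
            n_participants=30_000,
            snp_freqs={"rsX": 0.32},
            snp_effects={("rsX", HDL): 3.64},
        )
        table = simulate_study(sc)
        assert table["hdl"].mean() == pytest.approx(52.0, abs=0.5)
        assert table["hdl"].std() == pytest.approx(15.0, rel=0.03)
        assert np.log(table["tg"]).std() == pytest.approx(0.50, rel=0.03)

    def test_effect_recovered_by_regression(self):
        sc = _scenario(
            n_participants=25_000,
            snp_freqs={"rsX": 0.32},
            snp_effects={("rsX", HDL): 3.64},
            seed=99,
        )
        table = simulate_study(sc)
        g = table["rsX"].to_numpy()
        slope, _, _, _, se = stats.linregress(g, table["hdl"])[:5]
        assert abs(slope - 3.64) < 3 * se

    def test_friedewald_recovers_intended_ldl(self):
        table = simulate_study(_scenario(n_participants=5000))
        valid = table["tg"] <= 400
        ldl = table["tc"] - table["hdl"] - table["tg"] / 5.0
        assert ldl[valid].mean() == pytest.approx(122.0, abs=1.5)

    def test_medication_offset_shifts_mean(self):
        base = _scenario(n_participants=20_000)
        medicated = _scenario(
            n_participants=20_000,
            medication_rate=1.0,
            medication_offset={LDL: -40.0},
        )
        t0, t1 = simulate_study(base), simulate_study(medicated)
        ldl0 = t0["tc"] - t0["hdl"] - t0["tg"] / 5.0
        ldl1 = t1["tc"] - t1["hdl"] - t1["tg"] / 5.0
        assert (ldl1.mean() - ldl0.mean()) == pytest.approx(-40.0, abs=1.0)

    def test_excess_genetic_variance_rejected(self):
        sc = _scenario(snp_freqs={"rsX": 0.5}, snp_effects={("rsX", HDL): 40.0})
        with pytest.raises(ConfigurationError, match="variance"):
            simulate_study(sc)

    def test_genotype_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_phenotypes({"rsX": np.zeros(5)}, _scenario(snp_freqs={"rsX": 0.5}))

    def test_missing_genotypes_injected_at_rate(self):
        sc = _scenario(
            n_participants=20_000, snp_freqs={"rsX": 0.4}, missing_genotype_rate=0.1
        )
        table = simulate_study(sc)
        frac = table["rsX"].isna().mean()
        assert frac == pytest.approx(0.1, abs=0.01)
        assert set(table["rsX"].dropna().unique()) <= {0.0, 1.0, 2.0}

    def test_sex_conditional_covariates_missing_for_males(self):
        table = simulate_study(_scenario(n_participants=500))
        males = table[table["sex"] == "M"]
        assert males["menopause"].isna().all()
        assert males["hormone_use"].isna().all()


class TestReproducibility:
    def test_identical_seed_gives_identical_table(self):
        sc = _scenario(snp_freqs={"rsX": 0.3}, snp_effects={("rsX", HDL): 1.0})
        pd.testing.assert_frame_equal(simulate_study(sc), simulate_study(sc))

    def test_adding_a_snp_does_not_perturb_existing_streams(self):
        sc1 = _scenario(snp_freqs={"rsX": 0.3})
        sc2 = _scenario(snp_freqs={"rsX": 0.3, "rsY": 0.4})
        t1, t2 = simulate_study(sc1), simulate_study(sc2)
        assert np.array_equal(t1["rsX"], t2["rsX"])
        assert np.array_equal(t1["age"], t2["age"])

    def test_confounding_hook_changes_trait_but_not_covariate(self):
        plain = _scenario()
        confounded = _scenario(covariate_effects={("bmi", LNTG): 0.02})
        t1, t2 = simulate_study(plain), simulate_study(confounded)
        assert np.array_equal(t1["bmi"], t2["bmi"])
        assert not np.allclose(t1["tg"], t2["tg"])
        corr = np.corrcoef(t2["bmi"], np.log(t2["tg"]))[0, 1]
        assert corr > 0.1
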