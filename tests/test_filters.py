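"""Locus filter rules: thresholds, boundaries, HWE test calibration."""
from __future__ import annotations

import numpy as np
import pytest

from snpresample.filters import (
    FilterSettings,
    apply_outlier_list,
    call_rate_filter,
    filter_pipeline,
    hwe_chi2,
    hwe_filter,
    maf_filter,
)
from snpresample.genotype import MISSING, GenotypeMatrix


def one_pop(calls):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(
        [f"s{i}" for i in range(calls.shape[0])],
        ["A"] * calls.shape[0],
        [f"L{j}" for j in range(calls.shape[1])],
        calls,
    )


class TestMafFilter:
    def test_single_heterozygote_in_twenty_retained(self):
        # p = 1/40 = 0.025 >= 0.01
        calls = np.zeros((20, 1), dtype=np.int8)
        calls[0, 0] = 1
        rep = maf_filter(one_pop(calls), 0.01)
        assert rep.surviving_ids == ["L0"]

    def test_monomorphic_removed(self):
        rep = maf_filter(one_pop(np.zeros((10, 1))), 0.01)
        assert rep.removed["maf"] == 1 and not rep.surviving_ids

    def test_zero_threshold_keeps_everything_but_all_missing(self):
        calls = np.zeros((4, 2), dtype=np.int8)
        calls[:, 1] = MISSING
        rep = maf_filter(one_pop(calls), 0.0)
        assert rep.surviving_ids == ["L0"]
        assert rep.removed["call_rate_zero"] == 1

    def test_pooled_across_populations(self):
        # pop A fixed ref, pop B fixed alt -> pooled p = 0.5, retained
        calls = np.array([[0], [0], [2], [2]], dtype=np.int8)
        g = GenotypeMatrix(["a", "b", "c", "d"], ["A", "A", "B", "B"], ["L0"], calls)
        assert maf_filter(g, 0.2).surviving_ids == ["L0"]


class TestCallRateFilter:
    def test_boundary_is_strict(self):
        # 32/40 = 0.80 exactly -> removed; 33/40 -> retained
        calls = np.zeros((40, 2), dtype=np.int8)
        calls[:8, 0] = MISSING
        calls[:7, 1] = MISSING
        rep = call_rate_filter(one_pop(calls), 0.80)
        assert rep.surviving_ids == ["L1"]
        assert rep.removed["call_rate"] == 1

    def test_zero_rate_keeps_anything_typed(self):
        calls = np.full((5, 2), MISSING, dtype=np.int8)
        calls[0, 0] = 1
        rep = call_rate_filter(one_pop(calls), 0.0)
        assert rep.surviving_ids == ["L0"]


class TestHweChi2:
    def test_exact_proportions_give_zero(self):
        chi2, p = hwe_chi2(25, 50, 25)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_heterozygotes_extreme(self):
        # (50, 0, 50): expected (25, 50, 25) -> 25 + 50 + 25 = 100
        chi2, _ = hwe_chi2(50, 0, 50)
        assert chi2 == pytest.approx(100.0, rel=1e-12)

    def test_monomorphic_convention(self):
        chi2, p = hwe_chi2(90, 0, 0)
        assert (chi2, p) == (0.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_chi2(-1, 2, 3)

    def test_vectorised_matches_scalar(self):
        aa = np.array([25, 50, 90])
        ab = np.array([50, 0, 0])
        bb = np.array([25, 50, 0])
        chi2, p = hwe_chi2(aa, ab, bb)
        for i in range(3):
            c, pv = hwe_chi2(int(aa[i]), int(ab[i]), int(bb[i]))
            assert chi2[i] == pytest.approx(c) and p[i] == pytest.approx(pv)


class TestHweFilter:
    def test_type_one_error_near_alpha(self):
        """Strict-HWE loci are removed at ≈ alpha (moderate counts)."""
        rng = np.random.default_rng(42)
        L, N = 4000, 100
        p = rng.uniform(0.2, 0.8, L)
        calls = rng.binomial(2, p[None, :], size=(N, L)).astype(np.int8)
        frac = hwe_filter(one_pop(calls), 0.05).n_removed / L
        # 99% binomial band around 0.05 for 4000 trials
        assert abs(frac - 0.05) < 2.58 * np.sqrt(0.05 * 0.95 / L) + 0.002

    def test_tiny_alpha_removes_nothing(self):
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, 0.5, size=(30, 200)).astype(np.int8)
        assert hwe_filter(one_pop(calls), 1e-12).n_removed == 0

    def test_power_under_heterozygote_deficit(self):
        """F = 0.5 with 20 individuals is detected far above the 5% level."""
        rng = np.random.default_rng(2)
        L, N, F = 2000, 20, 0.5
        p = rng.uniform(0.2, 0.8, L)
        q = 1 - p
        c0 = q * q + F * p * q
        c1 = c0 + 2 * p * q * (1 - F)
        u = rng.random((N, L))
        calls = ((u > c0) .astype(np.int8) + (u > c1).astype(np.int8))
        frac = hwe_filter(one_pop(calls), 0.05).n_removed / L
        assert frac > 0.3

    def test_any_population_rule(self):
        # locus polymorphic with zero heterozygotes in pop B only -> removed
        rng = np.random.default_rng(3)
        ok = rng.binomial(2, 0.5, size=(50, 1)).astype(np.int8)
        bad = np.zeros((50, 1), dtype=np.int8)
        bad[:25] = 1            # pop A: all heterozygous? no - keep HWE-ish
        bad[:25] = rng.binomial(2, 0.5, size=(25, 1))  # pop A near HWE
        bad[25:38] = 0          # pop B: 13 ref hom, 12 alt hom, no hets
        bad[38:] = 2
        calls = np.hstack([ok, bad])
        labels = ["A"] * 25 + ["B"] * 25
        g = GenotypeMatrix([f"s{i}" for i in range(50)], labels,
                           ["good", "bad"], calls)
        rep = hwe_filter(g, 0.05)
        assert "bad" not in rep.surviving_ids
        assert rep.per_population_failures["hwe_B"] >= 1


class TestOutlierList:
    def test_empty_list_is_identity(self, small_two_pop):
        rep = apply_outlier_list(small_two_pop, [])
        assert rep.surviving_ids == small_two_pop.locus_ids

    def test_known_ids_removed(self, small_two_pop):
        rep = apply_outlier_list(small_two_pop, ["L0", "L5"])
        assert rep.removed["outlier"] == 2
        assert "L0" not in rep.surviving_ids

    def test_unknown_id_ignored_with_warning(self, small_two_pop, caplog):
        with caplog.at_level("WARNING"):
            rep = apply_outlier_list(small_two_pop, ["nope"])
        assert rep.surviving_ids == small_two_pop.locus_ids
        assert "unknown" in caplog.text


class TestPipeline:
    def test_counts_partition_input(self, rng):
        from .conftest import random_matrix
        g = random_matrix(rng, 30, 400, missing_rate=0.15)
        res = filter_pipeline(g)
        rep = res.report
        assert rep.n_removed + rep.n_surviving == g.n_loci
        assert list(rep.rules)[:2] == ["call_rate_zero", "maf"] or rep.rules[0] == "maf"

    def test_idempotent_on_survivors(self, rng):
        from .conftest import random_matrix
        g = random_matrix(rng, 40, 300, missing_rate=0.05)
        res = filter_pipeline(g)
        again = filter_pipeline(res.shared)
        assert again.shared.locus_ids == res.shared.locus_ids

    def test_per_population_panels_superset_of_shared(self, rng):
        from .conftest import random_matrix
        g = random_matrix(rng, 40, 300, missing_rate=0.05)
        res = filter_pipeline(g)
        shared = set(res.shared.locus_ids)
        for pop, m in res.per_population.items():
            assert shared <= set(m.locus_ids)
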