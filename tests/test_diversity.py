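"""Diversity and differentiation statistics against brute-force oracles."""
from __future__ import annotations

import numpy as np
import pytest

from snpresample.diversity import (
    allele_frequency,
    locus_diversity,
    locus_stats,
    nei_fst_from_freqs,
    pairwise_fst,
    panel_stats,
    population_summary,
    weir_cockerham_fst,
)
from snpresample.genotype import MISSING, GenotypeMatrix
from .conftest import random_matrix


def brute_pop_stats(calls):
    """Loop-and-count recomputation of p, N, Ae, Ho, He, uHe per locus."""
    calls = np.asarray(calls)
    out = []
    for j in range(calls.shape[1]):
        col = [int(c) for c in calls[:, j] if c >= 0]
        n = len(col)
        if n == 0:
            out.append(dict(p=np.nan, N=0, Ae=np.nan, Ho=np.nan,
                            He=np.nan, uHe=np.nan))
            continue
        p = sum(col) / (2.0 * n)
        q = 1.0 - p
        het = sum(1 for c in col if c == 1)
        he = 2.0 * p * q
        out.append(dict(
            p=p, N=n, Ae=1.0 / (p * p + q * q), Ho=het / n, He=he,
            uHe=he * 2 * n / (2 * n - 1.0),
        ))
    return out


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "calls,p,n",
        [
            ([0, 1, 2], 0.5, 3),
            ([2, 2, MISSING], 1.0, 2),
            ([1] * 20, 0.5, 20),
        ],
    )
    def test_examples(self, calls, p, n):
        got_p, got_n = allele_frequency(np.array(calls, dtype=np.int8))
        assert (got_p, got_n) == (pytest.approx(p), n)

    def test_all_missing_is_undefined(self):
        p, n = allele_frequency(np.array([MISSING, MISSING], dtype=np.int8))
        assert np.isnan(p) and n == 0


class TestLocusDiversity:
    def test_maximal_diversity(self):
        ae, ho, he, uhe = locus_diversity(0.5, 10, 5)
        assert ae == pytest.approx(2.0)
        assert he == pytest.approx(0.5)
        assert uhe == pytest.approx(0.5 * 20 / 19)

    def test_skewed_frequency(self):
        ae, ho, he, uhe = locus_diversity(0.9, 5, 1)
        assert ae == pytest.approx(1 / 0.82)
        assert he == pytest.approx(0.18)
        assert uhe == pytest.approx(0.2)
        assert ho == pytest.approx(0.2)

    def test_monomorphic(self):
        ae, ho, he, uhe = locus_diversity(1.0, 8, 0)
        assert (ae, he, uhe) == (pytest.approx(1.0), 0.0, 0.0)


class TestPopulationSummary:
    def test_constant_values(self):
        s = population_summary([0.5, 0.5, 0.5], "uHe")
        assert (s.mean, s.sd, s.se) == (0.5, 0.0, 0.0)

    def test_hand_arithmetic(self):
        s = population_summary([0.2, 0.4], "Ho")
        assert s.mean == pytest.approx(0.3)
        assert s.sd == pytest.approx(np.sqrt(0.02), rel=1e-9)
        assert s.se == pytest.approx(0.1)

    def test_undefined_excluded_and_counted(self):
        s = population_summary([0.2, np.nan, 0.4], "Ae")
        assert s.n_loci == 2 and s.n_undefined == 1

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError, match="Ae"):
            population_summary([np.nan], "Ae")


class TestBruteForceEquivalence:
    def test_panel_stats_match_loops(self, rng):
        """Vectorised stats equal the loop-and-count oracle to 1e-12."""
        for _ in range(20):
            g = random_matrix(rng, 15, 40, missing_rate=0.2)
            s = panel_stats(g.calls)
            brute = brute_pop_stats(g.calls)
            for j, b in enumerate(brute):
                for key in ("p", "Ae", "Ho", "He", "uHe"):
                    got = s[key][j]
                    if np.isnan(b[key]):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(b[key], abs=1e-12)

    def test_uhe_he_ratio_identity(self, rng):
        """uHe/He = 2N/(2N−1) exactly wherever He > 0."""
        g = random_matrix(rng, 18, 60, missing_rate=0.3)
        s = panel_stats(g.calls)
        mask = (s["He"] > 0) & (s["N"] > 0)
        np.testing.assert_allclose(
            s["uHe"][mask] / s["He"][mask],
            2.0 * s["N"][mask] / (2.0 * s["N"][mask] - 1.0),
            rtol=1e-14,
        )


class TestPairwiseFst:
    def two_pop(self, calls_a, calls_b):
        a = np.asarray(calls_a, dtype=np.int8)
        b = np.asarray(calls_b, dtype=np.int8)
        calls = np.vstack([a, b])
        labels = ["A"] * a.shape[0] + ["B"] * b.shape[0]
        return GenotypeMatrix([f"s{i}" for i in range(calls.shape[0])], labels,
                              [f"L{j}" for j in range(calls.shape[1])], calls)

    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (0.3, 0.3, 0.0),
            (1.0, 0.0, 1.0),            # fixed difference: Hs=0, Ht=0.5
            (0.8, 0.4, 1.0 / 6.0),      # Hs=0.4, Ht=0.48
        ],
    )
    def test_frequency_level_examples(self, p1, p2, expected):
        assert nei_fst_from_freqs(p1, p2) == pytest.approx(expected, abs=1e-12)

    def test_identical_populations_zero(self):
        calls = [[0, 1], [1, 2], [2, 0]]
        overall, per = pairwise_fst(self.two_pop(calls, calls), corrected=False)
        assert overall == pytest.approx(0.0, abs=1e-12)

    def test_plugin_per_locus_in_unit_interval(self, rng):
        for _ in range(10):
            g = random_matrix(rng, 16, 40, missing_rate=0.2)
            _, per = pairwise_fst(g, corrected=False)
            vals = per[np.isfinite(per)]
            assert ((vals >= -1e-12) & (vals <= 1 + 1e-12)).all()

    def test_plugin_matches_frequency_formula(self, rng):
        """Matrix-level plug-in Fst equals the frequency-level identity."""
        g = random_matrix(rng, 14, 30, missing_rate=0.1)
        pops = g.populations
        s1 = panel_stats(g.pop_calls(pops[0]))
        s2 = panel_stats(g.pop_calls(pops[1]))
        _, per = pairwise_fst(g, corrected=False)
        expect = nei_fst_from_freqs(s1["p"], s2["p"])
        both = np.isfinite(per)
        np.testing.assert_allclose(per[both], expect[both], atol=1e-12)

    def test_invariant_to_locus_and_label_order(self, rng):
        g = random_matrix(rng, 16, 40, missing_rate=0.1)
        overall, _ = pairwise_fst(g)
        perm = list(rng.permutation(g.n_loci))
        assert pairwise_fst(g.subset_loci(perm))[0] == pytest.approx(overall, rel=1e-12)
        swapped = g.restrict_populations(list(reversed(g.populations)))
        assert pairwise_fst(swapped)[0] == pytest.approx(overall, rel=1e-12)

    def test_corrected_estimator_unbiased_at_small_n(self):
        """Subsampling 3 individuals leaves the corrected Fst near truth.

        Frequencies p1 = 0.3, p2 = 0.5 imply a plug-in (frequency-level)
        Fst of (0.01/2)/0.48 ≈ 0.0208; the corrected estimator from n = 3
        genotype draws should average near that, while the naive plug-in
        inflates several-fold.
        """
        rng = np.random.default_rng(8)
        L, n = 4000, 3
        a = rng.binomial(2, 0.3, size=(n, L)).astype(np.int8)
        b = rng.binomial(2, 0.5, size=(n, L)).astype(np.int8)
        g = self.two_pop(a, b)
        truth = nei_fst_from_freqs(0.3, 0.5)
        corrected, _ = pairwise_fst(g, corrected=True)
        naive, _ = pairwise_fst(g, corrected=False)
        assert corrected == pytest.approx(truth, abs=0.02)
        assert naive > truth + 0.05

    def test_estimators_recover_their_own_targets(self):
        """On Balding–Nichols data, WC θ estimates θ and Nei Fst θ(d−1)/(d−θ).

        The two estimators target different parameters for d = 2 random
        populations: Weir–Cockerham θ is the variance-standardised
        divergence itself, while Nei's (Ht−Hs)/Ht over the 2-population
        mean frequency equals θ/(2−θ) in expectation (≈ θ/2 when small).
        """
        rng = np.random.default_rng(9)
        theta = 0.10
        L, n = 8000, 40
        scale = (1 - theta) / theta
        p0 = rng.uniform(0.2, 0.8, L)
        p1 = rng.beta(p0 * scale, (1 - p0) * scale)
        p2 = rng.beta(p0 * scale, (1 - p0) * scale)
        a = rng.binomial(2, p1[None, :], size=(n, L)).astype(np.int8)
        b = rng.binomial(2, p2[None, :], size=(n, L)).astype(np.int8)
        g = self.two_pop(a, b)
        wc, _ = weir_cockerham_fst(g)
        nei, _ = pairwise_fst(g, corrected=True)
        assert wc == pytest.approx(theta, rel=0.10)
        assert nei == pytest.approx(theta / (2 - theta), rel=0.10)

    def test_requires_two_populations(self, one_pop_matrix):
        with pytest.raises(ValueError):
            pairwise_fst(one_pop_matrix)


def test_locus_stats_table_shape(small_two_pop):
    df = locus_stats(small_two_pop)
    assert len(df) == 2 * small_two_pop.n_loci
    assert {"population", "locus_id", "Ae", "Ho", "He", "uHe"} <= set(df.columns)
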