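"""Synthetic two-population SNP panels under the Balding–Nichols model.

The generator emulates the post-QC product of a reduced-representation
(2b-RAD-style) SNP survey of two diploid populations: an ancestral allele
frequency p0 is drawn per locus from a truncated Beta law, each population's
frequency is drawn from the Balding–Nichols Beta distribution

    p_i ~ Beta(p0 (1-θ)/θ,  (1-p0)(1-θ)/θ),

whose mean is p0 and variance p0 q0 θ, and genotypes are then drawn per
individual.  θ plays the role of Fst; :func:`calibrate_theta` maps a target
Nei-scale differentiation onto it in closed form, so the pipeline's Fst
estimate can be checked against a known truth.

Loci flagged as Hardy–Weinberg violators are drawn with a heterozygote
deficit (inbreeding coefficient F): genotype probabilities
(q² + Fpq, 2pq(1−F), p² + Fpq).  The deficit direction matches what
low-diversity invasive-beetle panels actually show (Ho below uHe).

Randomness is split per 1024-locus block from one root seed, so extending
``n_loci`` never reshuffles the loci already generated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .genotype import MISSING, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "calibrate_theta",
    "draw_allele_frequencies",
    "simulate_genotypes",
    "simulate_dataset",
    "expected_mean_he",
    "beta_params_for_mean_he",
]

_BLOCK = 1024  # loci per RNG stream block


@dataclass
class SimulationConfig:
    """Parameters of the two-population genotype generator.

    Defaults emulate the study panel this package was built around: two
    populations of 20 diploid individuals each, ~14,000 biallelic SNPs after
    QC, mean expected heterozygosity ≈ 0.087 and between-population
    Fst ≈ 0.036.

    Attributes
    ----------
    n_pops, n_individuals, n_loci
        Population count, diploid individuals per population, locus count.
    target_fst
        Nei-scale differentiation in [0, 1); converted to the
        Balding–Nichols θ by :func:`calibrate_theta`.
    ancestral_beta
        (a, b) of the Beta law for the ancestral frequency p0, truncated to
        ``freq_bounds`` and renormalised.  ``None`` selects Beta(0.5, b)
        with b solved numerically so the expected within-population
        heterozygosity equals ``target_mean_he`` (a rare-alt-allele
        spectrum, mimicking the low-MAF-dominated product of RAD
        genotyping).
    target_mean_he
        Desired E[2 p q] within populations; only used when
        ``ancestral_beta`` is None.
    hwe_violation_fraction, inbreeding_f
        Fraction of loci drawn with a heterozygote deficit, and the F used
        for them.
    missing_rate
        Independent per-call missingness probability.
    """

    n_pops: int = 2
    n_individuals: int = 20
    n_loci: int = 14000
    target_fst: float = 0.036
    ancestral_beta: tuple[float, float] | None = None
    target_mean_he: float = 0.087
    freq_bounds: tuple[float, float] = (0.01, 0.99)
    hwe_violation_fraction: float = 0.0
    inbreeding_f: float = 0.0
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must lie in [0, 1)")
        for name in ("hwe_violation_fraction", "inbreeding_f", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.freq_bounds
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("freq_bounds must satisfy 0 < lo < hi < 1")

    @property
    def theta(self) -> float:
        """Balding–Nichols divergence implied by ``target_fst``."""
        if self.n_pops < 2:
            return 0.0
        return calibrate_theta(self.target_fst, self.n_pops)

    def resolved_beta(self) -> tuple[float, float]:
        """The (a, b) actually used for the ancestral frequency law."""
        if self.ancestral_beta is not None:
            return self.ancestral_beta
        return beta_params_for_mean_he(self.target_mean_he, self.theta,
                                       self.freq_bounds)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def calibrate_theta(target_fst: float, n_pops: int = 2) -> float:
    """Balding–Nichols θ giving an expected Nei differentiation of ``target_fst``.

    With d populations, E[Hs] = 2 p0 q0 (1−θ) and E[Ht] = 2 p0 q0 (1−θ/d)
    (the θ/d term is the variance of the mean of d independent population
    frequencies), so

        Fst = (Ht − Hs)/Ht = θ (d−1) / (d − θ)

    which inverts to θ = d·Fst / (d − 1 + Fst).  For d = 2 this is the
    closed form θ = 2 Fst / (1 + Fst).
    """
    if not 0.0 <= target_fst < 1.0:
        raise ValueError("target_fst must lie in [0, 1)")
    if n_pops < 2:
        raise ValueError("n_pops must be >= 2 to define differentiation")
    return n_pops * target_fst / (n_pops - 1 + target_fst)


# ---------------------------------------------------------------------------
# Ancestral-law calibration oracles
# ---------------------------------------------------------------------------

def _trunc_beta_mean_pq(a: float, b: float, bounds: tuple[float, float]) -> float:
    """E[p(1−p)] under Beta(a, b) truncated to ``bounds`` (numeric integral)."""
    lo, hi = bounds
    dist = stats.beta(a, b)
    z = dist.cdf(hi) - dist.cdf(lo)
    val, _ = integrate.quad(lambda p: p * (1.0 - p) * dist.pdf(p), lo, hi,
                            limit=200)
    return val / z


def expected_mean_he(cfg: SimulationConfig) -> float:
    """Analytic mean within-population expected heterozygosity E[2 p_i q_i].

    Equals 2 E[p0 q0] (1−θ) with E[p0 q0] integrated numerically under the
    configured truncated-Beta ancestral law.  Serves as the oracle for the
    generator's heterozygosity calibration.
    """
    a, b = cfg.resolved_beta()
    return 2.0 * _trunc_beta_mean_pq(a, b, cfg.freq_bounds) * (1.0 - cfg.theta)


def beta_params_for_mean_he(
    target_he: float,
    theta: float,
    bounds: tuple[float, float] = (0.01, 0.99),
    a: float = 0.5,
) -> tuple[float, float]:
    """Solve Beta(a, b) truncated to ``bounds`` so E[2 p q](1−θ) = target_he.

    The first shape is held at ``a`` (default 0.5, an x^{-1/2} ascertainment
    spike at rare alt alleles) and the second shape ``b`` is solved
    numerically: larger ``b`` piles ancestral frequencies onto the lower
    bound, driving the mean heterozygosity down — the spectrum shape of a
    low-diversity RAD SNP panel where most loci carry a rare alternate
    allele.  A symmetric law cannot reach low targets because truncation at
    the bounds floors E[pq] near 0.107.
    """
    if not 0.0 < target_he < 0.5:
        raise ValueError("target mean He must lie in (0, 0.5)")

    def gap(b: float) -> float:
        return 2.0 * _trunc_beta_mean_pq(a, b, bounds) * (1.0 - theta) - target_he

    lo_b, hi_b = 1e-2, 2000.0
    if gap(lo_b) < 0.0 or gap(hi_b) > 0.0:
        raise ValueError(
            f"target mean He {target_he} unreachable with a={a} on {bounds}"
        )
    b = optimize.brentq(gap, lo_b, hi_b, xtol=1e-10)
    return (a, b)


# ---------------------------------------------------------------------------
# Frequency and genotype draws
# ---------------------------------------------------------------------------

def _block_rngs(root: np.random.SeedSequence, stream: int, n_blocks: int):
    ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=(stream,))
    return [np.random.default_rng(c) for c in ss.spawn(n_blocks)]


def draw_allele_frequencies(cfg: SimulationConfig) -> pd.DataFrame:
    """Draw per-locus truth: ancestral and per-population allele frequencies.

    Returns a DataFrame with one row per locus: ``locus_id``, ``p0``,
    ``p_pop1`` … ``p_popd``, ``theta``, ``violates_hwe``, ``f``.  θ = 0
    degenerates to p_i = p0 exactly.  Same seed → identical frequencies, and
    the first loci are unchanged when n_loci grows (block-split streams).
    """
    a, b = cfg.resolved_beta()
    lo, hi = cfg.freq_bounds
    theta = cfg.theta
    dist = stats.beta(a, b)
    c_lo, c_hi = dist.cdf(lo), dist.cdf(hi)

    root = np.random.SeedSequence(cfg.seed)
    n_blocks = math.ceil(cfg.n_loci / _BLOCK)
    rngs = _block_rngs(root, 0, n_blocks)

    p0 = np.empty(cfg.n_loci)
    p_pops = np.empty((cfg.n_pops, cfg.n_loci))
    violates = np.zeros(cfg.n_loci, dtype=bool)
    for blk, rng in enumerate(rngs):
        sl = slice(blk * _BLOCK, min((blk + 1) * _BLOCK, cfg.n_loci))
        m = sl.stop - sl.start
        u = rng.uniform(c_lo, c_hi, size=m)
        p0_blk = dist.ppf(u)
        p0[sl] = p0_blk
        if theta == 0.0:
            p_pops[:, sl] = p0_blk[None, :]
        else:
            scale = (1.0 - theta) / theta
            p_pops[:, sl] = rng.beta(
                np.broadcast_to(p0_blk * scale, (cfg.n_pops, m)),
                np.broadcast_to((1.0 - p0_blk) * scale, (cfg.n_pops, m)),
            )
        if cfg.hwe_violation_fraction > 0.0:
            violates[sl] = rng.random(m) < cfg.hwe_violation_fraction

    out = {
        "locus_id": [f"L{j:06d}" for j in range(cfg.n_loci)],
        "p0": p0,
    }
    for i in range(cfg.n_pops):
        out[f"p_pop{i + 1}"] = p_pops[i]
    out["theta"] = np.full(cfg.n_loci, theta)
    out["violates_hwe"] = violates
    out["f"] = np.where(violates, cfg.inbreeding_f, 0.0)
    return pd.DataFrame(out)


def simulate_genotypes(truth: pd.DataFrame, cfg: SimulationConfig) -> GenotypeMatrix:
    """Draw diploid genotypes from per-locus population frequencies.

    Non-violating loci follow Hardy–Weinberg (dosage ~ Binomial(2, p));
    violating loci use the inbreeding genotype law with the per-locus ``f``.
    Each call is then independently knocked out with ``missing_rate``.
    """
    if len(truth) != cfg.n_loci:
        raise ValueError(
            f"truth has {len(truth)} loci, config expects {cfg.n_loci}"
        )
    root = np.random.SeedSequence(cfg.seed)
    n_blocks = math.ceil(cfg.n_loci / _BLOCK)
    geno_rngs = _block_rngs(root, 1, n_blocks)
    miss_rngs = _block_rngs(root, 2, n_blocks)

    n_ind = cfg.n_individuals
    total = n_ind * cfg.n_pops
    calls = np.empty((total, cfg.n_loci), dtype=np.int8)
    f_loc = truth["f"].to_numpy()

    for blk in range(n_blocks):
        sl = slice(blk * _BLOCK, min((blk + 1) * _BLOCK, cfg.n_loci))
        m = sl.stop - sl.start
        rng = geno_rngs[blk]
        f = f_loc[sl]
        for i in range(cfg.n_pops):
            p = truth[f"p_pop{i + 1}"].to_numpy()[sl]
            q = 1.0 - p
            # genotype law (q²+Fpq, 2pq(1−F), p²+Fpq); F=0 is plain HWE
            c0 = q * q + f * p * q
            c1 = c0 + 2.0 * p * q * (1.0 - f)
            u = rng.random((n_ind, m))
            g = (u > c0[None, :]).astype(np.int8) + (u > c1[None, :]).astype(np.int8)
            calls[i * n_ind:(i + 1) * n_ind, sl] = g
        if cfg.missing_rate > 0.0:
            miss = miss_rngs[blk].random((total, m)) < cfg.missing_rate
            blk_calls = calls[:, sl]
            blk_calls[miss] = MISSING
            calls[:, sl] = blk_calls

    sample_ids = [
        f"pop{i + 1}_{j + 1:02d}" for i in range(cfg.n_pops) for j in range(n_ind)
    ]
    pop_labels = [
        f"pop{i + 1}" for i in range(cfg.n_pops) for _ in range(n_ind)
    ]
    return GenotypeMatrix(sample_ids, pop_labels, list(truth["locus_id"]), calls)


def simulate_dataset(cfg: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Convenience: frequencies + genotypes in one call (shared seed)."""
    truth = draw_allele_frequencies(cfg)
    return simulate_genotypes(truth, cfg), truth
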