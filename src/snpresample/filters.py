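"""Locus-level quality filters applied before resampling.

The pipeline order is fixed: minor-allele frequency (pooled across
populations) → call rate (strict "more than" threshold) → Hardy–Weinberg
equilibrium (chi-square, tested within each population separately) → an
externally supplied outlier-locus list (e.g. from a Bayesian outlier scan,
which is out of scope here and consumed as a plain id list).

Each filter returns a :class:`FilterReport`; :func:`filter_pipeline` chains
them and additionally produces the per-population panels (a locus is dropped
from a population's panel only if it fails HWE in that population) and the
shared panel used for between-population differentiation (dropped if it
fails HWE in any population).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genotype import GenotypeMatrix

__all__ = [
    "FilterReport",
    "FilterSettings",
    "FilterResult",
    "maf_filter",
    "call_rate_filter",
    "hwe_chi2",
    "hwe_filter",
    "apply_outlier_list",
    "filter_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Outcome of one or more locus filters.

    ``removed`` maps rule name → count; ``removed_ids`` maps rule name →
    locus ids (a locus is charged to the first rule that removed it, in the
    declared order).  removed + surviving always partition the input loci.
    """

    rules: tuple[str, ...]
    removed: dict[str, int]
    removed_ids: dict[str, list[str]]
    surviving_ids: list[str]

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_ids)

    def check(self, n_input: int) -> None:
        assert self.n_removed + self.n_surviving == n_input

    def to_frame(self):
        import pandas as pd
        rows = [{"rule": r, "removed": self.removed.get(r, 0)} for r in self.rules]
        rows.append({"rule": "surviving", "removed": self.n_surviving})
        return pd.DataFrame(rows)


def _report(rule: str, locus_ids: Sequence[str], keep: np.ndarray,
            extra: dict[str, np.ndarray] | None = None) -> FilterReport:
    """Build a single-rule report; ``extra`` charges some removals elsewhere."""
    removed_ids: dict[str, list[str]] = {}
    rules: list[str] = []
    claimed = np.zeros(len(locus_ids), dtype=bool)
    if extra:
        for r, mask in extra.items():
            ids = [locus_ids[j] for j in np.flatnonzero(mask & ~claimed)]
            if ids:
                rules.append(r)
                removed_ids[r] = ids
                claimed |= mask
    main = ~keep & ~claimed
    rules.append(rule)
    removed_ids[rule] = [locus_ids[j] for j in np.flatnonzero(main)]
    surviving = [locus_ids[j] for j in np.flatnonzero(keep)]
    return FilterReport(
        tuple(rules),
        {r: len(ids) for r, ids in removed_ids.items()},
        removed_ids,
        surviving,
    )


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------

def maf_filter(g: GenotypeMatrix, threshold: float = 0.01) -> FilterReport:
    """Remove loci with pooled minor-allele frequency below ``threshold``.

    The frequency is computed over all non-missing calls pooled across
    populations (this is genotyping-level QC, upstream of any population
    analysis).  A locus is removed iff min(p, 1−p) < threshold.  Loci with
    zero non-missing calls are removed and charged to ``call_rate_zero``.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    typed = g.calls >= 0
    n = typed.sum(axis=0)
    dos = np.where(typed, g.calls, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, dos / (2.0 * np.maximum(n, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)
    all_missing = n == 0
    if all_missing.any():
        log.warning("%d loci with zero non-missing calls removed (call_rate_zero)",
                    int(all_missing.sum()))
    keep = ~all_missing & (maf >= threshold)
    return _report("maf", g.locus_ids, keep, {"call_rate_zero": all_missing})


def call_rate_filter(g: GenotypeMatrix, min_rate: float = 0.80) -> FilterReport:
    """Retain loci genotyped in *more than* ``min_rate`` of all samples.

    The inequality is strict, so at min_rate = 0.80 a locus typed in exactly
    80% of individuals is removed.
    """
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must lie in [0, 1]")
    rate = (g.calls >= 0).sum(axis=0) / g.n_samples
    keep = rate > min_rate
    return _report("call_rate", g.locus_ids, keep)


def hwe_chi2(aa, ab, bb):
    """Chi-square goodness-of-fit test of Hardy–Weinberg genotype proportions.

    ``aa, ab, bb`` are genotype counts (scalars or arrays).  The expected
    counts are (N p̂², 2N p̂ q̂, N q̂²) with p̂ = (2·aa + ab)/(2N); the
    statistic sums (obs − exp)²/exp over the three cells with no continuity
    correction, and the p-value comes from the chi-square law with 1 degree
    of freedom.  Monomorphic loci (p̂ ∈ {0, 1}) return (0, 1) by convention.
    """
    aa = np.asarray(aa, dtype=float)
    ab = np.asarray(ab, dtype=float)
    bb = np.asarray(bb, dtype=float)
    if (aa < 0).any() or (ab < 0).any() or (bb < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = aa + ab + bb
    if (n < 1).any():
        raise ValueError("need at least one genotyped individual")
    p = (2.0 * aa + ab) / (2.0 * n)
    q = 1.0 - p
    exp_aa = n * p * p
    exp_ab = 2.0 * n * p * q
    exp_bb = n * q * q
    poly = (p > 0.0) & (p < 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(
            poly,
            (aa - exp_aa) ** 2 / np.where(poly, exp_aa, 1.0)
            + (ab - exp_ab) ** 2 / np.where(poly, exp_ab, 1.0)
            + (bb - exp_bb) ** 2 / np.where(poly, exp_bb, 1.0),
            0.0,
        )
    pval = np.where(poly, stats.chi2.sf(chi2, df=1), 1.0)
    if chi2.ndim == 0:
        return float(chi2), float(pval)
    return chi2, pval


def _hwe_pvalues(calls: np.ndarray) -> np.ndarray:
    """Per-locus HWE p-values for one population's calls (NaN-safe)."""
    aa = (calls == 0).sum(axis=0)
    ab = (calls == 1).sum(axis=0)
    bb = (calls == 2).sum(axis=0)
    n = aa + ab + bb
    pvals = np.ones(calls.shape[1])
    typed = n >= 1
    if typed.any():
        _, pv = hwe_chi2(aa[typed], ab[typed], bb[typed])
        pvals[typed] = np.atleast_1d(pv)
    return pvals


def hwe_filter(g: GenotypeMatrix, alpha: float = 0.05) -> FilterReport:
    """Remove loci deviating from Hardy–Weinberg equilibrium.

    The chi-square test runs separately within each population on
    non-missing calls; a locus is removed iff its p-value falls below
    ``alpha`` in ANY population (for a single-population matrix this is just
    that population's test).  No multiple-testing correction is applied.
    Per-population removal counts are reported under ``hwe_<pop>``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    fails = {}
    for pop in g.populations:
        fails[pop] = _hwe_pvalues(g.pop_calls(pop)) < alpha
    any_fail = np.logical_or.reduce(list(fails.values()))
    keep = ~any_fail
    # charge each removed locus to every population it failed in is ambiguous;
    # report per-population failure counts, removal charged to first failure
    removed_ids: dict[str, list[str]] = {}
    rules: list[str] = []
    claimed = np.zeros(g.n_loci, dtype=bool)
    counts: dict[str, int] = {}
    for pop in g.populations:
        rule = f"hwe_{pop}"
        rules.append(rule)
        counts[rule] = int(fails[pop].sum())
        mask = fails[pop] & ~claimed
        removed_ids[rule] = [g.locus_ids[j] for j in np.flatnonzero(mask)]
        claimed |= fails[pop]
    surviving = [g.locus_ids[j] for j in np.flatnonzero(keep)]
    report = FilterReport(
        tuple(rules),
        {r: len(removed_ids[r]) for r in rules},
        removed_ids,
        surviving,
    )
    # stash raw per-population failure counts (a locus can fail in several)
    report.per_population_failures = counts  # type: ignore[attr-defined]
    return report


def apply_outlier_list(g: GenotypeMatrix, outlier_ids: Iterable[str]) -> FilterReport:
    """Remove loci named in an externally produced outlier list.

    Unknown ids are logged and ignored.  An empty list is the identity.
    """
    wanted = set(outlier_ids)
    known = set(g.locus_ids)
    unknown = sorted(wanted - known)
    if unknown:
        log.warning("outlier list names %d unknown loci (ignored): %s",
                    len(unknown), unknown[:5])
    keep = np.array([lid not in wanted for lid in g.locus_ids])
    return _report("outlier", g.locus_ids, keep)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class FilterSettings:
    """Thresholds of the fixed filter pipeline (maf → call_rate → hwe → outlier)."""

    maf: float = 0.01
    min_call_rate: float = 0.80
    hwe_alpha: float = 0.05
    outlier_ids: tuple[str, ...] = ()


@dataclass
class FilterResult:
    """Panels surviving the pipeline.

    ``pooled`` passed MAF + call rate + outlier removal; ``per_population``
    additionally passed that population's own HWE test; ``shared`` passed
    HWE in every population (the panel resampled for Fst).
    """

    pooled: GenotypeMatrix
    per_population: dict[str, GenotypeMatrix]
    shared: GenotypeMatrix
    report: FilterReport


def filter_pipeline(g: GenotypeMatrix, settings: FilterSettings | None = None) -> FilterResult:
    """Apply the full locus-filter pipeline in its fixed order."""
    s = settings or FilterSettings()
    rules: list[str] = []
    removed: dict[str, int] = {}
    removed_ids: dict[str, list[str]] = {}

    def absorb(rep: FilterReport) -> None:
        for r in rep.rules:
            rules.append(r)
            removed[r] = rep.removed.get(r, 0)
            removed_ids[r] = rep.removed_ids.get(r, [])

    rep = maf_filter(g, s.maf)
    absorb(rep)
    cur = g.subset_loci(rep.surviving_ids)

    rep = call_rate_filter(cur, s.min_call_rate)
    absorb(rep)
    cur = cur.subset_loci(rep.surviving_ids)

    if s.outlier_ids:
        rep = apply_outlier_list(cur, s.outlier_ids)
        absorb(rep)
        cur = cur.subset_loci(rep.surviving_ids)
    else:
        rules.append("outlier")
        removed["outlier"] = 0
        removed_ids["outlier"] = []

    hwe_rep = hwe_filter(cur, s.hwe_alpha)
    absorb(hwe_rep)
    shared = cur.subset_loci(hwe_rep.surviving_ids)

    per_pop: dict[str, GenotypeMatrix] = {}
    for pop in cur.populations:
        sub = cur.restrict_populations([pop])
        own = hwe_filter(sub, s.hwe_alpha)
        per_pop[pop] = sub.subset_loci(own.surviving_ids)

    report = FilterReport(tuple(rules), removed, removed_ids,
                          list(shared.locus_ids))
    report.per_population_failures = getattr(  # type: ignore[attr-defined]
        hwe_rep, "per_population_failures", {})
    report.per_population_surviving = {  # type: ignore[attr-defined]
        pop: m.n_loci for pop, m in per_pop.items()}
    return FilterResult(cur, per_pop, shared, report)
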