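"""The resampling engine: repeated draws of k SNPs × n individuals.

One *replicate* draws k loci and n individuals per population, both
uniformly without replacement, and estimates the requested parameters from
the subsample alone (allele frequencies are recomputed from the drawn
individuals — exactly what an investigator who genotyped only n individuals
would observe).  Replicates are independent; overlap between them is
allowed and, for small panels, inevitable.

Two grid analyses mirror the protocol's two stages: vary the replicate
count x at fixed n (to find how many replicates stabilise the estimates),
then vary n at the chosen x (to find the minimal sufficient sample size).
Summaries report the mean, SD, SE and a t-based 95% confidence interval of
each parameter across replicates.

Everything is reproducible bit-for-bit from (matrix, design, seed): each
grid point gets its own RNG stream derived from the design seed, so adding
grid points never reshuffles the draws of existing ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diversity import _fst_from_stats, panel_stats
from .genotype import GenotypeMatrix

__all__ = [
    "ResamplingDesign",
    "CISummary",
    "GridRun",
    "draw_replicate",
    "run_grid",
    "summarize_ci",
]

DIVERSITY_PARAMETERS = ("Ae", "Ho", "uHe")


@dataclass
class ResamplingDesign:
    """The resampling grid: k SNPs, sample sizes n, replicate counts x.

    ``mode`` is ``"within"`` (diversity parameters inside one population) or
    ``"between"`` (pairwise Fst on the shared panel of two populations).
    ``fixed_n`` is the sample size held constant while optimising the
    replicate count (default 3); ``fixed_x`` is the replicate count used
    while varying n (chosen by the ΔK stage when run through the protocol).
    With ``fix_snp_panel`` the k loci are drawn once per grid point instead
    of once per replicate.
    """

    k: int = 3000
    n_grid: tuple[int, ...] = (2, 4, 6, 8, 10, 15)
    x_grid: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
    parameters: tuple[str, ...] = DIVERSITY_PARAMETERS
    mode: str = "within"
    fixed_n: int = 3
    fixed_x: int | None = None
    fix_snp_panel: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for name in ("n_grid", "x_grid"):
            grid = tuple(getattr(self, name))
            setattr(self, name, grid)
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if any(n < 2 for n in self.n_grid):
            raise ValueError("every n must be >= 2")
        if self.mode not in ("within", "between"):
            raise ValueError("mode must be 'within' or 'between'")
        if self.mode == "between":
            self.parameters = ("Fst",)
        bad = [p for p in self.parameters if p not in ("Ae", "Ho", "He", "uHe", "Fst")]
        if bad:
            raise ValueError(f"unknown parameters: {bad}")

    def validate_against(self, g: GenotypeMatrix) -> None:
        if self.k > g.n_loci:
            raise ValueError(f"k={self.k} exceeds available loci ({g.n_loci})")
        part = g.partition()
        if self.mode == "between" and len(part) != 2:
            raise ValueError("between mode needs exactly two populations")
        smallest = min(len(ix) for ix in part.values())
        needs = max(self.n_grid + (self.fixed_n,))
        if needs > smallest:
            raise ValueError(
                f"sample size {needs} exceeds smallest population ({smallest})"
            )


@dataclass
class CISummary:
    """Mean, SD, SE and a t-based confidence interval across replicates."""

    mean: float
    sd: float
    se: float
    ci_lo: float
    ci_hi: float
    n: int
    level: float = 0.95


def summarize_ci(values: Sequence[float], level: float = 0.95) -> CISummary:
    """Replicate-level summary: CI = mean ± t(level, x−1) · SD/√x."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicate values")
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    se = sd / np.sqrt(v.size)
    tcrit = float(sps.t.ppf(0.5 + level / 2.0, df=v.size - 1))
    return CISummary(mean, sd, se, mean - tcrit * se, mean + tcrit * se,
                     int(v.size), level)


# ---------------------------------------------------------------------------
# Draws
# ---------------------------------------------------------------------------

def draw_replicate(
    g: GenotypeMatrix, k: int, n: int, rng: np.random.Generator, mode: str = "within"
) -> GenotypeMatrix:
    """One replicate: k distinct loci and n distinct individuals per population.

    Both draws are uniform without replacement and fully determined by
    ``rng``'s state.  In ``within`` mode ``g`` should hold one population;
    in ``between`` mode n individuals are drawn from each of the two
    populations, from the shared locus panel.
    """
    if k > g.n_loci:
        raise ValueError(f"k={k} exceeds available loci ({g.n_loci})")
    part = g.partition()
    for pop, ix in part.items():
        if n > len(ix):
            raise ValueError(f"n={n} exceeds population {pop!r} ({len(ix)})")
    loci = np.sort(rng.choice(g.n_loci, size=k, replace=False))
    samp = np.concatenate(
        [np.sort(ix[rng.choice(len(ix), size=n, replace=False)]) for ix in part.values()]
    )
    return g.subset_samples(samp).subset_loci(loci)


def _grid_point_rng(seed: int, stage: str, grid_value: int) -> np.random.Generator:
    tag = 0 if stage == "x" else 1
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(tag, grid_value))
    )


def _batched_indices(rng, pool: int, draw: int, reps: int) -> np.ndarray:
    """(reps, draw) without-replacement draws via per-replicate permutation."""
    out = np.empty((reps, draw), dtype=np.intp)
    for r in range(reps):
        out[r] = rng.choice(pool, size=draw, replace=False)
    return out


def _replicate_means_within(
    calls: np.ndarray, loci_idx: np.ndarray, samp_idx: np.ndarray,
    parameters: Sequence[str],
) -> dict[str, np.ndarray]:
    """Per-replicate means over loci of each diversity parameter.

    ``calls``: (m, L) one population; ``loci_idx``: (x, k); ``samp_idx``:
    (x, n).  Loci untyped in a subsample are excluded from that replicate's
    mean (NaN-mean), matching how monomorphic loci are *retained* (Ae = 1,
    He = 0) but untyped ones cannot contribute.
    """
    sub = calls[samp_idx[:, :, None], loci_idx[:, None, :]]  # (x, n, k)
    s = panel_stats(sub)
    return {p: np.nanmean(s[p], axis=-1) for p in parameters}


def _replicate_fst_between(
    g: GenotypeMatrix, loci_idx: np.ndarray, samp_idx: dict[str, np.ndarray],
    corrected: bool = True,
) -> np.ndarray:
    """Per-replicate overall Fst (ratio of sums over the k drawn loci)."""
    pops = g.populations
    part = g.partition()
    stats_by_pop = []
    for pop in pops:
        calls = g.calls[part[pop], :]
        sub = calls[samp_idx[pop][:, :, None], loci_idx[:, None, :]]
        stats_by_pop.append(panel_stats(sub))
    s1, s2 = stats_by_pop
    x = loci_idx.shape[0]
    out = np.empty(x)
    for r in range(x):
        sl1 = {key: val[r] for key, val in s1.items()}
        sl2 = {key: val[r] for key, val in s2.items()}
        out[r], _ = _fst_from_stats(sl1, sl2, corrected)
    return out


# ---------------------------------------------------------------------------
# Grid runs
# ---------------------------------------------------------------------------

@dataclass
class GridRun:
    """Tidy result of one grid analysis.

    ``replicates`` has columns (grid, parameter, replicate, value);
    ``summary`` has (grid, parameter, x, mean, sd, se, ci_lo, ci_hi).
    ``vary`` records which symbol the grid ranges over ("x" or "n").
    """

    vary: str
    fixed: int
    design: ResamplingDesign
    replicates: pd.DataFrame
    summary: pd.DataFrame

    def series(self, parameter: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(grid, means, sds, x counts) for one parameter, grid-ordered."""
        df = (self.summary[self.summary["parameter"] == parameter]
              .sort_values("grid"))
        if df.empty:
            raise KeyError(f"parameter {parameter!r} not in this run")
        return (df["grid"].to_numpy(), df["mean"].to_numpy(),
                df["sd"].to_numpy(), df["x"].to_numpy())


def run_grid(
    g: GenotypeMatrix,
    design: ResamplingDesign,
    vary: str = "x",
    level: float = 0.95,
) -> GridRun:
    """Run one stage of the protocol over its grid.

    ``vary="x"``: the replicate count ranges over ``design.x_grid`` with the
    sample size fixed at ``design.fixed_n``.  ``vary="n"``: the sample size
    ranges over ``design.n_grid`` with the replicate count fixed at
    ``design.fixed_x`` (which must be set).  In ``between`` mode the only
    parameter is the overall pairwise Fst of each replicate.
    """
    if vary not in ("x", "n"):
        raise ValueError("vary must be 'x' or 'n'")
    design.validate_against(g)
    if vary == "n" and design.fixed_x is None:
        raise ValueError("vary='n' requires design.fixed_x")

    grid = design.x_grid if vary == "x" else design.n_grid
    part = g.partition()
    pops = g.populations

    rep_rows = []
    sum_rows = []
    for gv in grid:
        x = gv if vary == "x" else int(design.fixed_x)  # type: ignore[arg-type]
        n = design.fixed_n if vary == "x" else gv
        rng = _grid_point_rng(design.seed, vary, gv)
        if design.fix_snp_panel:
            one = rng.choice(g.n_loci, size=design.k, replace=False)
            loci_idx = np.broadcast_to(one, (x, design.k)).copy()
        else:
            loci_idx = _batched_indices(rng, g.n_loci, design.k, x)
        samp_idx = {
            pop: _batched_indices(rng, len(part[pop]), n, x) for pop in pops
        }
        if design.mode == "within":
            if len(pops) != 1:
                raise ValueError("within mode expects a single-population matrix")
            values = _replicate_means_within(
                g.calls[part[pops[0]], :], loci_idx, samp_idx[pops[0]],
                design.parameters,
            )
        else:
            values = {"Fst": _replicate_fst_between(g, loci_idx, samp_idx)}
        for param, vals in values.items():
            for r, v in enumerate(vals):
                rep_rows.append((gv, param, r, float(v)))
            ci = summarize_ci(vals, level)
            sum_rows.append((gv, param, ci.n, ci.mean, ci.sd, ci.se,
                             ci.ci_lo, ci.ci_hi))

    replicates = pd.DataFrame(rep_rows,
                              columns=["grid", "parameter", "replicate", "value"])
    summary = pd.DataFrame(sum_rows,
                           columns=["grid", "parameter", "x", "mean", "sd",
                                    "se", "ci_lo", "ci_hi"])
    fixed = design.fixed_n if vary == "x" else int(design.fixed_x)  # type: ignore[arg-type]
    return GridRun(vary, fixed, replace(design), replicates, summary)
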