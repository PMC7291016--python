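"""Sample-size optimisation as a model/results pair.

:class:`SampleSizeModel` holds a genotype matrix plus the filter and
resampling settings; :meth:`SampleSizeModel.fit` runs the full two-stage
protocol and returns a :class:`SampleSizeResults` with every intermediate
table, the ΔK series, the per-parameter recommendations and a ``summary()``
text report.

The protocol, per parameter:

1. Filter loci (MAF → call rate → outliers → HWE per population).
2. Stage 1 — replicate-count optimisation: fix the sample size at a small
   ``fixed_n`` (default 3), vary the replicate count x over its grid, and
   take the ΔK peak as the per-parameter replicate count x*.
3. Stage 2 — sample-size optimisation: fix x = x*, vary n over its grid,
   and take the ΔK peak as the recommended minimal sample size n*.

Diversity parameters (Ae, Ho, uHe) run within each population on that
population's own post-HWE panel; Fst runs between the two populations on
the shared panel.  Because stage-1 peaks may differ across parameters, the
driver honours a separate x* per parameter.
"""
from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .deltak import DeltaKSeries, Recommendation, recommend, series_from_run
from .filters import FilterResult, FilterSettings, filter_pipeline
from .genotype import GenotypeMatrix, read_genalex, read_vcf
from .resample import DIVERSITY_PARAMETERS, GridRun, ResamplingDesign, run_grid
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["SampleSizeModel", "SampleSizeResults", "ProtocolConfig", "run_protocol"]

log = logging.getLogger(__name__)


class SampleSizeModel:
    """Minimal-sample-size estimation for SNP diversity and differentiation.

    Parameters
    ----------
    genotypes
        The post-genotyping matrix (one or more populations).
    design
        The resampling grid; its ``mode`` and ``parameters`` fields are
        managed internally, its k, grids, ``fixed_n`` and seed are honoured.
    filter_settings
        Locus-filter thresholds; ``None`` uses the defaults
        (MAF 0.01, call rate > 0.80, HWE alpha 0.05, no outliers).
    parameters
        Diversity parameters to optimise within populations.
    fst
        Whether to also optimise the between-population Fst stage
        (requires exactly two populations).
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        design: ResamplingDesign | None = None,
        filter_settings: FilterSettings | None = None,
        parameters: tuple[str, ...] = DIVERSITY_PARAMETERS,
        fst: bool = True,
        deltak_denominator: str = "sd",
        fix_panel: bool = True,
    ) -> None:
        self.genotypes = genotypes
        self.design = design or ResamplingDesign()
        self.filter_settings = filter_settings or FilterSettings()
        self.parameters = tuple(parameters)
        self.fst = fst and len(genotypes.populations) == 2
        self.deltak_denominator = deltak_denominator
        #: Select the k-SNP panel once per analysis unit and resample only
        #: individuals across replicates and grid points.  This mirrors a
        #: one-off random locus selection per population (and per shared
        #: panel) and keeps replicate dispersion a pure function of the
        #: individuals drawn; ``False`` redraws the k loci independently for
        #: every replicate instead.
        self.fix_panel = fix_panel

    @classmethod
    def from_simulation(
        cls, cfg: SimulationConfig | None = None, **kwargs
    ) -> "SampleSizeModel":
        """Build the model on a freshly simulated two-population panel."""
        cfg = cfg or SimulationConfig()
        g, truth = simulate_dataset(cfg)
        m = cls(g, **kwargs)
        m.truth = truth  # type: ignore[attr-defined]
        return m

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int | None = None) -> "SampleSizeResults":
        """Run filters and both protocol stages; return the results object."""
        seed = self.design.seed if seed is None else seed
        filt = filter_pipeline(self.genotypes, self.filter_settings)

        stage1: dict[tuple[str, str], GridRun] = {}
        stage2: dict[tuple[str, str], GridRun] = {}
        deltak_x: dict[tuple[str, str], DeltaKSeries] = {}
        deltak_n: dict[tuple[str, str], DeltaKSeries] = {}
        chosen_x: dict[tuple[str, str], Recommendation] = {}
        recommended_n: dict[tuple[str, str], Recommendation] = {}

        units: list[tuple[str, str, GenotypeMatrix]] = []
        for i, pop in enumerate(self.genotypes.populations):
            units.append(("within", pop, filt.per_population[pop]))
        if self.fst:
            units.append(("between", "Fst", filt.shared))

        for unit_idx, (mode, label, panel) in enumerate(units):
            params = self.parameters if mode == "within" else ("Fst",)
            pop_tag = unit_idx
            if self.fix_panel and self.design.k < panel.n_loci:
                panel_rng = np.random.default_rng(np.random.SeedSequence(
                    entropy=seed, spawn_key=(3, pop_tag)))
                loci = np.sort(panel_rng.choice(
                    panel.n_loci, size=self.design.k, replace=False))
                panel = panel.subset_loci(loci)
            d1 = replace(
                self.design,
                mode=mode,
                parameters=params,
                seed=int(np.random.SeedSequence(
                    entropy=seed, spawn_key=(1, pop_tag)).generate_state(1)[0] % (2**31)),
            )
            run1 = run_grid(panel, d1, vary="x")
            for p in params:
                key = (label, p)
                stage1[key] = run1
                s = series_from_run(run1, p, self.deltak_denominator)
                deltak_x[key] = s
                chosen_x[key] = recommend(s)

            # stage 2: one run per distinct chosen x among this unit's params
            runs_by_x: dict[int, GridRun] = {}
            for p in params:
                key = (label, p)
                xstar = chosen_x[key].value
                if xstar not in runs_by_x:
                    d2 = replace(
                        self.design,
                        mode=mode,
                        parameters=params,
                        fixed_x=xstar,
                        seed=int(np.random.SeedSequence(
                            entropy=seed, spawn_key=(2, pop_tag, xstar)
                        ).generate_state(1)[0] % (2**31)),
                    )
                    runs_by_x[xstar] = run_grid(panel, d2, vary="n")
                run2 = runs_by_x[xstar]
                stage2[key] = run2
                s = series_from_run(run2, p, self.deltak_denominator)
                deltak_n[key] = s
                recommended_n[key] = recommend(s)

        return SampleSizeResults(
            model=self,
            seed=seed,
            filter_result=filt,
            stage1=stage1,
            stage2=stage2,
            deltak_x=deltak_x,
            deltak_n=deltak_n,
            chosen_x=chosen_x,
            recommended_n=recommended_n,
        )


@dataclass
class SampleSizeResults:
    """Fitted protocol: filter report, grid runs, ΔK series, recommendations.

    Keys of the per-parameter dicts are ``(unit, parameter)`` where unit is
    a population label for within-population diversity or ``"Fst"`` for the
    between-population stage.
    """

    model: SampleSizeModel
    seed: int
    filter_result: FilterResult
    stage1: Mapping[tuple[str, str], GridRun]
    stage2: Mapping[tuple[str, str], GridRun]
    deltak_x: Mapping[tuple[str, str], DeltaKSeries]
    deltak_n: Mapping[tuple[str, str], DeltaKSeries]
    chosen_x: Mapping[tuple[str, str], Recommendation]
    recommended_n: Mapping[tuple[str, str], Recommendation]

    # -- views -------------------------------------------------------------

    def recommendations_frame(self) -> pd.DataFrame:
        rows = []
        for (unit, param), rec_n in self.recommended_n.items():
            rec_x = self.chosen_x[(unit, param)]
            rows.append({
                "unit": unit, "parameter": param,
                "chosen_x": rec_x.value, "x_peak_delta_k": rec_x.peak_delta_k,
                "recommended_n": rec_n.value,
                "n_peak_delta_k": rec_n.peak_delta_k,
                "n_flatness": rec_n.flatness, "n_tie": rec_n.tie,
            })
        return pd.DataFrame(rows)

    def deltak_frame(self) -> pd.DataFrame:
        rows = []
        for stage, coll in (("x", self.deltak_x), ("n", self.deltak_n)):
            for (unit, param), s in coll.items():
                for gv, v in zip(s.grid, s.values):
                    rows.append({"stage": stage, "unit": unit,
                                 "parameter": param, "grid": int(gv),
                                 "delta_k": float(v)})
        return pd.DataFrame(rows)

    def _stage_frames(self, stage) -> tuple[pd.DataFrame, pd.DataFrame]:
        reps, sums = [], []
        seen: set[int] = set()
        for (unit, param), run in stage.items():
            if id(run) in seen:
                continue
            seen.add(id(run))
            r = run.replicates.copy()
            r.insert(0, "unit", unit)
            r.insert(1, "fixed", run.fixed)
            s = run.summary.copy()
            s.insert(0, "unit", unit)
            s.insert(1, "fixed", run.fixed)
            reps.append(r)
            sums.append(s)
        return (pd.concat(reps, ignore_index=True),
                pd.concat(sums, ignore_index=True))

    def summary(self) -> str:
        """Human-readable report in the spirit of a model results summary."""
        g = self.model.genotypes
        filt = self.filter_result
        lines = [
            "Minimal sample size for SNP diversity estimation",
            "=" * 60,
            f"Input: {g.n_samples} individuals / {len(g.populations)} "
            f"population(s), {g.n_loci} loci; seed {self.seed}",
            f"Filters: MAF<{self.model.filter_settings.maf} | call rate "
            f">{self.model.filter_settings.min_call_rate} | HWE alpha "
            f"{self.model.filter_settings.hwe_alpha}",
        ]
        for rule in filt.report.rules:
            lines.append(f"  removed by {rule}: {filt.report.removed.get(rule, 0)}")
        per_pop = getattr(filt.report, "per_population_surviving", {})
        for pop, n in per_pop.items():
            lines.append(f"  surviving panel ({pop}): {n} loci")
        lines.append(f"  shared panel: {filt.shared.n_loci} loci")
        lines.append("-" * 60)
        lines.append(f"{'unit':<12}{'param':<8}{'x*':>6}{'n*':>6}"
                     f"{'peak dK':>12}{'flatness':>10}")
        for (unit, param), rec in self.recommended_n.items():
            xstar = self.chosen_x[(unit, param)].value
            lines.append(f"{unit:<12}{param:<8}{xstar:>6}{rec.value:>6}"
                         f"{rec.peak_delta_k:>12.3f}{rec.flatness:>10.2f}")
        lines.append("=" * 60)
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, outdir: str | Path) -> Path:
        """Write the full report bundle (CSV tables + JSON summary + log)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.filter_result.report.to_frame().to_csv(
            outdir / "filter_report.csv", index=False)
        for stage_name, stage in (("stage1", self.stage1), ("stage2", self.stage2)):
            reps, sums = self._stage_frames(stage)
            reps.to_csv(outdir / f"{stage_name}_replicates.csv", index=False)
            sums.to_csv(outdir / f"{stage_name}_summary.csv", index=False)
        self.deltak_frame().to_csv(outdir / "deltak.csv", index=False)
        self.recommendations_frame().to_csv(
            outdir / "recommendations.csv", index=False)
        summary = {
            "seed": self.seed,
            "chosen_x": {f"{u}/{p}": r.value for (u, p), r in self.chosen_x.items()},
            "recommended_n": {f"{u}/{p}": r.value
                              for (u, p), r in self.recommended_n.items()},
            "surviving_loci": {
                "shared": self.filter_result.shared.n_loci,
                **getattr(self.filter_result.report,
                          "per_population_surviving", {}),
            },
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                        sort_keys=True))
        run_log = {
            "package": "snpresample",
            "version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": self.seed,
            "design": asdict(self.model.design),
            "filters": asdict(self.model.filter_settings),
            "parameters": list(self.model.parameters),
            "fst": self.model.fst,
            "deltak_denominator": self.model.deltak_denominator,
            "fix_panel": self.model.fix_panel,
        }
        (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2,
                                                        sort_keys=True))
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        return outdir

    def plot_deltak(self, path: str | Path | None = None):
        """Line charts of every ΔK series (one panel per unit/parameter)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        items = [("x", k, s) for k, s in self.deltak_x.items()]
        items += [("n", k, s) for k, s in self.deltak_n.items()]
        ncol = 3
        nrow = -(-len(items) // ncol)
        fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                                 squeeze=False)
        for ax, (stage, (unit, param), s) in zip(axes.ravel(), items):
            ax.plot(s.grid, s.values, "o-")
            ax.set_title(f"{unit} {param} (vary {stage})", fontsize=9)
            ax.set_xlabel(stage)
            ax.set_ylabel("ΔK")
        for ax in axes.ravel()[len(items):]:
            ax.set_visible(False)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return None
        return fig


# ---------------------------------------------------------------------------
# Protocol configuration / driver
# ---------------------------------------------------------------------------

@dataclass
class ProtocolConfig:
    """End-to-end run configuration with exactly one input source.

    Set exactly one of ``simulation``, ``vcf`` (+ ``pop_map``) or
    ``genalex``.  Both protocol stages share the seed root.
    """

    simulation: SimulationConfig | None = None
    vcf: str | None = None
    pop_map: dict[str, str] | None = None
    genalex: str | None = None
    filters: FilterSettings = field(default_factory=FilterSettings)
    design: ResamplingDesign = field(default_factory=ResamplingDesign)
    parameters: tuple[str, ...] = DIVERSITY_PARAMETERS
    fst: bool = True
    deltak_denominator: str = "sd"
    fix_panel: bool = True
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        sources = [s is not None for s in (self.simulation, self.vcf, self.genalex)]
        if sum(sources) != 1:
            raise ValueError("exactly one input source must be set")
        if self.vcf is not None and not self.pop_map:
            raise ValueError("a VCF source requires pop_map")


def run_protocol(cfg: ProtocolConfig) -> SampleSizeResults:
    """Load or simulate the input, run both stages, optionally save a bundle.

    Any stage failure is re-raised with the stage name prepended; partial
    outputs written before the failure are left in place.
    """
    stage = "load"
    try:
        if cfg.simulation is not None:
            sim = cfg.simulation.with_seed(cfg.seed)
            g, truth = simulate_dataset(sim)
        elif cfg.vcf is not None:
            g = read_vcf(cfg.vcf, cfg.pop_map or {})
            truth = None
        else:
            g = read_genalex(cfg.genalex)  # type: ignore[arg-type]
            truth = None
        stage = "fit"
        model = SampleSizeModel(
            g,
            design=replace(cfg.design, seed=cfg.seed),
            filter_settings=cfg.filters,
            parameters=cfg.parameters,
            fst=cfg.fst,
            deltak_denominator=cfg.deltak_denominator,
            fix_panel=cfg.fix_panel,
        )
        results = model.fit(seed=cfg.seed)
        stage = "save"
        if cfg.outdir is not None:
            results.save(cfg.outdir)
            if truth is not None:
                truth.to_csv(Path(cfg.outdir) / "simulation_truth.csv",
                             index=False)
        return results
    except Exception as e:
        raise RuntimeError(f"protocol failed during stage {stage!r}: {e}") from e
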