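"""Pipeline orchestration: simulate -> prep -> fit -> classify -> report.

Every figure written by the pipeline has a machine-readable twin table;
tables (CSV) are the test surface, figures are decoration.  A single
master seed deterministically derives per-stage seeds so stages can be
rerun in isolation and full runs are byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml
from matplotlib.colors import ListedColormap

from . import cohort as cohort_mod
from .cohort import CohortGenConfig, TruthParams, generate_cohort, read_cohort
from .design import build_design, complete_cases
from .model import MCMCConfig, PriorSpec, diagnostics, posterior_summary, sample_posterior
from .subgroups import (
    CovariateGrid,
    CredibleSubgroupPair,
    MaxLevelSurface,
    SimultaneousBand,
    apply_to_cohort,
    bracket_probability,
    classification_table,
    classify,
    compute_pte,
    default_ranges,
    make_grid,
    max_credible_level,
    simultaneous_band,
)

logger = logging.getLogger(__name__)

_REGION_COLORS = {"D": "#1b9e77", "S\\D": "#e6c84c", "Sc": "#d95f02"}
_REGION_GREYS = {"D": "0.15", "S\\D": "0.60", "Sc": "0.90"}
_REGION_ORDER = ("D", "S\\D", "Sc")


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from YAML via :meth:`from_yaml`."""

    outdir: str = "out"
    seed: int = 0
    cohort_path: str | None = None
    generator: CohortGenConfig = field(default_factory=CohortGenConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    grid_resolution: int = 20
    grid_ranges: dict | None = None
    levels: tuple = (0.5, 0.65, 0.8)
    threshold: float = 0.0
    scale: str = "log-odds"
    greyscale: bool = False

    def __post_init__(self):
        if not self.levels:
            raise ValueError("at least one credible level is required")
        if any(not 0.0 < lv < 1.0 for lv in self.levels):
            raise ValueError("levels must lie in (0, 1)")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        gen_raw = dict(raw.pop("generator", {}))
        truth_raw = gen_raw.pop("truth", None)
        if truth_raw is not None:
            gen_raw["truth"] = TruthParams(**truth_raw)
        kwargs = {
            "generator": CohortGenConfig(**gen_raw),
            "prior": PriorSpec(**raw.pop("prior", {})),
            "mcmc": MCMCConfig(**raw.pop("mcmc", {})),
        }
        if "levels" in raw:
            kwargs["levels"] = tuple(raw.pop("levels"))
        grid_raw = raw.pop("grid", {})
        if "resolution" in grid_raw:
            kwargs["grid_resolution"] = int(grid_raw["resolution"])
        if grid_raw.get("ranges"):
            kwargs["grid_ranges"] = {
                k: tuple(v) for k, v in grid_raw["ranges"].items()
            }
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run plus the artifact paths."""

    summary: pd.DataFrame
    diagnostics: object
    pairs: dict  # level -> CredibleSubgroupPair
    bracket_probs: dict  # level -> float
    fractions: dict  # level -> {"D":..., "S\\D":..., "Sc":...}
    surface: MaxLevelSurface
    files: list


def stage_seeds(master_seed: int) -> dict:
    """Deterministic per-stage seeds derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    gen, mcmc, extra = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3))
    return {"generate": gen, "mcmc": mcmc, "extra": extra}


def _save_fig(fig, path, files):
    fig.savefig(path, dpi=120, metadata={"Software": None, "Date": None})
    plt.close(fig)
    files.append(Path(path))


def _region_cmap(greyscale: bool) -> ListedColormap:
    palette = _REGION_GREYS if greyscale else _REGION_COLORS
    return ListedColormap([palette[r] for r in _REGION_ORDER])


def plot_trichotomy(
    pair: CredibleSubgroupPair,
    grid: CovariateGrid,
    greyscale: bool = False,
    axes: tuple = ("sf36_gh", "hba1c"),
    facet: str = "age",
    path=None,
) -> pd.DataFrame:
    """Region map over two continuous axes, faceted by sex and by slices
    of the remaining continuous covariate (quartile/median/quartile).

    Returns the twin table of plotted points (one row per point of the
    selected slices) and, when ``path`` is given, writes the figure.
    """
    if not grid.is_factorial:
        raise ValueError("trichotomy plot requires a factorial grid")
    from .subgroups import GRID_AXIS_ORDER

    known = set(GRID_AXIS_ORDER) - {"sex"}
    for name in (*axes, facet):
        if name not in known:
            raise ValueError(f"unknown axis name {name!r}")
    if len({*axes, facet}) != 3:
        raise ValueError("axes and facet must name three distinct covariates")

    full = pd.DataFrame({name: grid.raw[name].to_numpy() for name in GRID_AXIS_ORDER})
    full["region"] = pair.region_labels()

    # facet slices at (quartile, median, quartile) of the facet axis
    n_facet = len(grid.axis_raw[facet])
    if n_facet <= 3:
        facet_idx = list(range(n_facet))
    else:
        facet_idx = sorted({n_facet // 4, n_facet // 2, (3 * n_facet) // 4})
    facet_vals = grid.axis_raw[facet][facet_idx]
    table = full[full[facet].isin(facet_vals)].reset_index(drop=True)
    table = table[["sex", facet, axes[0], axes[1], "region"]]

    if path is not None:
        code = {r: i for i, r in enumerate(_REGION_ORDER)}
        fig, axarr = plt.subplots(
            2, len(facet_vals), figsize=(3.2 * len(facet_vals), 6.0),
            squeeze=False, sharex=True, sharey=True,
        )
        for si, sex in enumerate((0, 1)):
            for ci, fv in enumerate(facet_vals):
                sub = table[(table["sex"] == sex) & (table[facet] == fv)]
                z = (
                    sub.pivot(index=axes[1], columns=axes[0], values="region")
                    .map(code.get)
                )
                ax = axarr[si][ci]
                ax.pcolormesh(
                    z.columns.to_numpy(), z.index.to_numpy(), z.to_numpy(dtype=float),
                    cmap=_region_cmap(greyscale), vmin=-0.5, vmax=2.5, shading="nearest",
                )
                ax.set_title(f"sex={sex}, {facet}={fv:.1f}", fontsize=9)
                if si == 1:
                    ax.set_xlabel(axes[0])
                if ci == 0:
                    ax.set_ylabel(axes[1])
        fig.suptitle(f"Credible subgroup trichotomy, level {pair.level:.2f}")
        fig.tight_layout()
        _save_fig(fig, path, [])
    return table


def plot_funnel(
    band: SimultaneousBand, pair: CredibleSubgroupPair, greyscale: bool = False, path=None
) -> pd.DataFrame:
    """Posterior mean effect vs pointwise sd, coloured by region.

    Returns the twin table (mean, sd, lower, upper, region) whose value
    columns equal the band's arrays exactly.
    """
    table = pd.DataFrame(
        {
            "mean_effect": band.mean,
            "sd": band.sd,
            "lower": band.lower,
            "upper": band.upper,
            "region": pair.region_labels(),
        }
    )
    if path is not None:
        palette = _REGION_GREYS if greyscale else _REGION_COLORS
        fig, ax = plt.subplots(figsize=(6, 5))
        for region in _REGION_ORDER:
            sub = table[table["region"] == region]
            ax.scatter(sub["mean_effect"], sub["sd"], s=4, label=region,
                       color=palette[region], alpha=0.6)
        ax.set_xlabel("posterior mean effect (benefit-positive)")
        ax.set_ylabel("pointwise posterior sd")
        ax.legend(title=f"level {pair.level:.2f}")
        fig.tight_layout()
        _save_fig(fig, path, [])
    return table


def plot_level_contours(
    surface: MaxLevelSurface,
    grid: CovariateGrid,
    axes: tuple = ("sf36_gh", "hba1c"),
    path=None,
) -> pd.DataFrame:
    """Signed maximum-credible-level contours per sex (other continuous
    covariates at their middle grid value).  Returns the full signed
    surface export (one row per grid point)."""
    if not grid.is_factorial:
        raise ValueError("contour plot requires a factorial grid")
    from .subgroups import GRID_AXIS_ORDER

    table = pd.DataFrame(
        {name: grid.raw[name].to_numpy() for name in GRID_AXIS_ORDER}
    )
    table["max_credible_level"] = surface.values

    if path is not None:
        others = [a for a in GRID_AXIS_ORDER if a not in axes and a != "sex"]
        sub = table
        for other in others:
            mid = grid.axis_raw[other][len(grid.axis_raw[other]) // 2]
            sub = sub[sub[other] == mid]
        fig, axarr = plt.subplots(1, 2, figsize=(10, 4.2), sharey=True)
        cs = None
        for sex, ax in zip((0, 1), axarr):
            panel = (
                sub[sub["sex"] == sex]
                .pivot(index=axes[1], columns=axes[0], values="max_credible_level")
            )
            cs = ax.contourf(
                panel.columns.to_numpy(), panel.index.to_numpy(), panel.to_numpy(),
                levels=np.linspace(-1, 1, 21), cmap="RdYlGn",
            )
            ax.set_title(f"sex={sex}")
            ax.set_xlabel(axes[0])
        axarr[0].set_ylabel(axes[1])
        fig.colorbar(cs, ax=axarr, label="signed max credible level")
        _save_fig(fig, path, [])
    return table


def _load_or_generate(cfg: PipelineConfig, seeds: dict) -> pd.DataFrame:
    if cfg.cohort_path is not None:
        logger.info("loading cohort from %s", cfg.cohort_path)
        return read_cohort(cfg.cohort_path)
    gen = CohortGenConfig(
        **{
            **{k: getattr(cfg.generator, k) for k in (
                "n_subjects", "age_mean", "age_sd", "male_prob", "hba1c_mean",
                "hba1c_sd", "sf36_mean", "sf36_sd", "allocation_prob", "truth",
                "continuous_corr",
            )},
            "seed": seeds["generate"],
        }
    )
    logger.info("generating synthetic cohort (n=%d)", gen.n_subjects)
    return generate_cohort(gen)


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute the full pipeline under ``cfg``.

    Stages: cohort (load or simulate), complete-case prep, posterior
    sampling, grid classification at every requested level, maximum
    credible level surface, membership fractions, figures and exports.
    On any stage failure, artifacts written so far are removed and a
    RuntimeError naming the stage is raised.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    files: list[Path] = []
    stage = "setup"
    t_start = time.time()
    try:
        stage = "cohort"
        raw_cohort = _load_or_generate(cfg, seeds)
        cohort_mod.write_cohort(raw_cohort, outdir / "cohort.csv")
        files.append(outdir / "cohort.csv")

        stage = "prep"
        cc, removed = complete_cases(raw_cohort)
        logger.info("complete cases: kept %d rows, removed %d", len(cc), removed)
        dm = build_design(cc)

        stage = "fit"
        t0 = time.time()
        mcmc = MCMCConfig(
            iterations=cfg.mcmc.iterations,
            burn_in=cfg.mcmc.burn_in,
            seed=seeds["mcmc"],
            init=cfg.mcmc.init,
        )
        logger.info(
            "sampling posterior: %d draws after %d burn-in, prior variances %g/%g",
            mcmc.iterations, mcmc.burn_in,
            cfg.prior.prognostic_variance, cfg.prior.predictive_variance,
        )
        draws = sample_posterior(dm, cfg.prior, mcmc)
        draws.to_csv(outdir / "draws.csv")
        files.append(outdir / "draws.csv")
        summary = posterior_summary(draws)
        summary.to_csv(outdir / "summary.csv", index_label="coefficient")
        files.append(outdir / "summary.csv")
        diag = diagnostics(draws)
        diag.to_frame().to_csv(outdir / "diagnostics.csv", index_label="coefficient")
        files.append(outdir / "diagnostics.csv")
        logger.info("fit stage took %.1fs", time.time() - t0)

        stage = "subgroups"
        ranges = cfg.grid_ranges or default_ranges(cc)
        grid = make_grid(dm.std, ranges, cfg.grid_resolution)
        pte = compute_pte(draws, grid, scale=cfg.scale, threshold=cfg.threshold)
        pairs, brackets, fractions = {}, {}, {}
        for level in sorted(cfg.levels):
            band = simultaneous_band(pte, level)
            pair = classify(band, cfg.threshold)
            pairs[level] = pair
            brackets[level] = bracket_probability(pte, pair)
            fractions[level] = apply_to_cohort(pair, cc, dm.std)
            tag = f"{int(round(level * 100)):02d}"
            table = classification_table(grid, band, pair)
            table.to_csv(outdir / f"classification_{tag}.csv", index=False)
            files.append(outdir / f"classification_{tag}.csv")
            tri = plot_trichotomy(
                pair, grid, greyscale=cfg.greyscale,
                path=outdir / f"trichotomy_{tag}.png",
            )
            tri.to_csv(outdir / f"trichotomy_{tag}.csv", index=False)
            files.extend([outdir / f"trichotomy_{tag}.png", outdir / f"trichotomy_{tag}.csv"])
            logger.info(
                "level %.2f: |D|=%d, |S\\D|=%d, |Sc|=%d, bracket prob %.3f",
                level, int(pair.D.sum()), int(pair.uncertainty.sum()),
                int(pair.S_complement.sum()), brackets[level],
            )

        top_level = max(cfg.levels)
        band_top = simultaneous_band(pte, top_level)
        funnel = plot_funnel(
            band_top, pairs[top_level], greyscale=cfg.greyscale,
            path=outdir / "funnel.png",
        )
        funnel.to_csv(outdir / "funnel.csv", index=False)
        files.extend([outdir / "funnel.png", outdir / "funnel.csv"])

        stage = "max-level"
        surface = max_credible_level(pte, cfg.threshold)
        contour = plot_level_contours(surface, grid, path=outdir / "max_level.png")
        contour.to_csv(outdir / "max_level.csv", index=False)
        files.extend([outdir / "max_level.png", outdir / "max_level.csv"])

        stage = "report"
        report = {
            "n_input": int(len(raw_cohort)),
            "n_complete": int(len(cc)),
            "n_removed": int(removed),
            "levels": {
                f"{lv:g}": {
                    "bracket_probability": brackets[lv],
                    "fractions": fractions[lv],
                }
                for lv in cfg.levels
            },
            "seconds": round(time.time() - t_start, 2),
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        files.append(outdir / "report.json")
    except Exception as exc:
        for f in files:
            f.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return ReportBundle(
        summary=summary,
        diagnostics=diag,
        pairs=pairs,
        bracket_probs=brackets,
        fractions=fractions,
        surface=surface,
        files=files,
    )
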