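"""End-to-end pipeline: simulate/load, fit, compare, ANOVA, rank, report."""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anova as anova_mod
from . import factors as factors_mod
from . import fitting, io, reference
from .fitting import FIRST_ORDER, PLATEAU, FitOptions
from .simulate import SimulationConfig, default_truth_set, simulate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "fit_all_conditions",
           "compare_all_conditions", "rank_from_fits", "run_pipeline",
           "render_report"]

log = logging.getLogger("soildecay")

FIT_COLUMNS = [
    "condition_id", "soil_site", "temperature_C", "water_content_pct",
    "sterilized", "model_kind", "y0", "a", "b", "r_squared", "p_value",
    "dt50_days", "n_obs", "ss_res", "converged", "note",
]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (simulation or file input)."""

    input_path: str | None = None  # None -> simulate
    outdir: str = "results"
    seed: int = 0
    sites: tuple[str, ...] = reference.SITES
    include_sterilized: bool = True
    replicates: int = 3
    noise_cv: float = 0.10
    noise_floor_sd: float = 2.0
    use_means: bool = False
    between: tuple[str, ...] = (
        "soil_site", "water_content_pct", "temperature_C",
    )
    max_poly_order: int = 3
    poly_spacing: str = "rank"
    plots: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sites"] = list(self.sites)
        d["between"] = list(self.between)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sites" in d:
            d["sites"] = tuple(d["sites"])
        if "between" in d:
            d["between"] = tuple(d["between"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(io.read_yaml(path))


@dataclass
class PipelineResult:
    outdir: Path
    paths: dict
    n_conditions: int
    n_nonconverged: int
    fits: pd.DataFrame
    comparisons: pd.DataFrame
    rankings: pd.DataFrame


def _condition_groups(table: pd.DataFrame):
    cols = ["condition_id", "soil_site", "temperature_C",
            "water_content_pct", "sterilized"]
    for keys, group in table.groupby(cols, sort=True):
        yield dict(zip(cols, keys)), group


def fit_all_conditions(
    table: pd.DataFrame, options: FitOptions | None = None
) -> tuple[pd.DataFrame, dict]:
    """Fit both models to every condition in a measurement table.

    Returns the long fit-results frame (two rows per condition) and a dict
    ``condition_id -> (first_order FitResult, plateau FitResult)``.
    """
    options = options or FitOptions()
    rows, objects = [], {}
    for info, group in _condition_groups(table):
        t = group["time_days"].to_numpy()
        y = group["concentration_ng_per_g"].to_numpy()
        pair = []
        for kind in (FIRST_ORDER, PLATEAU):
            fit = fitting.fit_model(
                t, y, kind, options=options, condition_id=info["condition_id"]
            )
            pair.append(fit)
            p = fit.params
            rows.append(
                {
                    **info,
                    "model_kind": kind,
                    "y0": getattr(p, "y0", 0.0),
                    "a": p.a,
                    "b": p.b,
                    "r_squared": fit.r_squared,
                    "p_value": fit.p_value,
                    "dt50_days": fit.dt50_days,
                    "n_obs": fit.n_obs,
                    "ss_res": fit.ss_res,
                    "converged": fit.converged,
                    "note": fit.note,
                }
            )
        objects[info["condition_id"]] = tuple(pair)
    return pd.DataFrame(rows, columns=FIT_COLUMNS), objects


def compare_all_conditions(objects: dict) -> pd.DataFrame:
    rows = []
    for cid, (fit_fo, fit_pl) in sorted(objects.items()):
        cmp = fitting.compare_models(fit_fo, fit_pl)
        rows.append(
            {
                "condition_id": cid,
                "r2_first_order": cmp.r2_first_order,
                "r2_plateau": cmp.r2_plateau,
                "delta_r2": cmp.delta_r2,
                "preferred": cmp.preferred,
            }
        )
    return pd.DataFrame(rows)


def rank_from_fits(fits: pd.DataFrame) -> pd.DataFrame:
    """Two-stage factor ranking; factors that cannot be evaluated are skipped."""
    rows = []
    for stage in factors_mod.STAGES:
        influences = []
        nonsterile = fits[~fits["sterilized"].astype(bool)]
        for factor in factors_mod.FACTORS:
            try:
                if factor == "sterilization":
                    sub = factors_mod._sterilization_slice(fits)
                else:
                    sub = nonsterile
                metric = factors_mod.STAGE_METRIC[stage][0]
                means = factors_mod.level_means(sub, factor, metric)
                influences.append(
                    factors_mod.FactorInfluence(
                        factor=factor,
                        stage=stage,
                        level_means=means,
                        range=factors_mod.influence_range(means),
                    )
                )
            except (ValueError, KeyError) as exc:
                log.warning("skipping factor %s at stage %s: %s",
                            factor, stage, exc)
        for fi in factors_mod.rank_factors(influences):
            rows.append(
                {
                    "stage": fi.stage,
                    "factor": fi.factor,
                    "range": fi.range,
                    "rank": fi.rank,
                    "tie": fi.tie,
                    "level_means": "; ".join(
                        f"{k}={v:.4g}" for k, v in fi.level_means.items()
                    ),
                }
            )
    return pd.DataFrame(rows)


def _format_p(p: float) -> str:
    if not np.isfinite(p):
        return "NA"
    return "<0.0001" if p < 1e-4 else f"{p:.4g}"


def _equation(row: pd.Series) -> str:
    if row["model_kind"] == FIRST_ORDER:
        return f"Y = {row['a']:.2f}*exp(-{row['b']:.4g} t)"
    return f"Y = {row['y0']:.2f} + {row['a']:.2f}*exp(-{row['b']:.4g} t)"


def render_report(fits: pd.DataFrame, comparisons: pd.DataFrame,
                  rankings: pd.DataFrame | None = None) -> str:
    """Markdown report mirroring the per-condition model-table layout."""
    lines = ["# Degradation model fits", ""]
    lines.append(
        "| Condition | Degradation model | R^2 | p | DT50 (d) |"
    )
    lines.append("|---|---|---|---|---|")
    for cid, group in fits.groupby("condition_id", sort=True):
        for i, (_, row) in enumerate(group.iterrows()):
            label = cid if i == 0 else ""
            dt50 = (
                f"{row['dt50_days']:.1f}"
                if row["model_kind"] == FIRST_ORDER
                else ""
            )
            lines.append(
                f"| {label} | {_equation(row)} | {row['r_squared']:.4f} "
                f"| {_format_p(row['p_value'])} | {dt50} |"
            )
    lines += ["", "## Model comparison", ""]
    lines.append("| Condition | R^2 first-order | R^2 plateau | delta R^2 "
                 "| preferred |")
    lines.append("|---|---|---|---|---|")
    for _, row in comparisons.iterrows():
        lines.append(
            f"| {row['condition_id']} | {row['r2_first_order']:.4f} "
            f"| {row['r2_plateau']:.4f} | {row['delta_r2']:.4f} "
            f"| {row['preferred']} |"
        )
    if rankings is not None and not rankings.empty:
        lines += ["", "## Factor influence ranking", ""]
        for stage, group in rankings.groupby("stage", sort=True):
            group = group.sort_values("rank")
            chain = " > ".join(
                f"{r['factor']} ({r['range']:.1f})" for _, r in group.iterrows()
            )
            lines.append(f"- {stage} stage: {chain}")
    return "\n".join(lines) + "\n"


def _plot_conditions(fits: pd.DataFrame, table: pd.DataFrame, outdir: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .models import FirstOrderParams, PlateauParams, eval_first_order, eval_plateau

    plot_dir = outdir / "plots"
    plot_dir.mkdir(parents=True, exist_ok=True)
    for cid, group in table.groupby("condition_id"):
        sub = fits[fits["condition_id"] == cid]
        tmax = group["time_days"].max()
        grid = np.linspace(0, tmax, 200)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(group["time_days"], group["concentration_ng_per_g"],
                "o", ms=3, alpha=0.6, label="observed")
        for _, row in sub.iterrows():
            if row["model_kind"] == FIRST_ORDER:
                curve = eval_first_order(
                    FirstOrderParams(row["a"], row["b"]), grid)
            else:
                curve = eval_plateau(
                    PlateauParams(row["y0"], row["a"], row["b"]), grid)
            ax.plot(grid, curve, label=row["model_kind"])
        ax.set_xlabel("time (d)")
        ax.set_ylabel("concentration (ng/g)")
        ax.set_title(cid, fontsize=9)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(plot_dir / f"{cid}.png", dpi=100)
        plt.close(fig)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle to ``config.outdir``."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    # hash only analysis-relevant fields so moving the output directory
    # does not change the provenance stamp
    chash = io.config_hash(
        {k: v for k, v in cfg_dict.items() if k not in ("outdir", "plots")}
    )
    meta = {"config_hash": chash, "seed": config.seed}
    paths: dict[str, Path] = {}

    # --- stage: data ---
    if config.input_path is None:
        sim = SimulationConfig(
            truth=default_truth_set(
                sites=tuple(config.sites),
                include_sterilized=config.include_sterilized,
            ),
            replicates=config.replicates,
            noise_cv=config.noise_cv,
            noise_floor_sd=config.noise_floor_sd,
            seed=config.seed,
        )
        table = simulate_dataset(sim)
        io.write_yaml(
            {"pipeline": cfg_dict, "simulation": sim.to_dict()},
            outdir / "config.yaml",
        )
    else:
        table = io.read_measurements(config.input_path)
        io.write_yaml({"pipeline": cfg_dict}, outdir / "config.yaml")
    paths["config"] = outdir / "config.yaml"
    paths["measurements"] = outdir / "measurements.csv"
    io.write_measurements(table, paths["measurements"], {**meta,
                                                         "stage": "measurements"})
    log.info("data: %d records, %d conditions (%.2fs)", len(table),
             table["condition_id"].nunique(), time.time() - t0)

    # --- stage: fitting ---
    t1 = time.time()
    options = FitOptions(use_means=config.use_means, seed=config.seed)
    fits, objects = fit_all_conditions(table, options)
    paths["fits"] = outdir / "fit_results.csv"
    io.write_table(fits, paths["fits"], {**meta, "stage": "fit_results"})
    n_nonconverged = int((~fits["converged"]).sum())
    log.info("fitting: %d fits, %d non-converged (%.2fs)", len(fits),
             n_nonconverged, time.time() - t1)

    # --- stage: model comparison ---
    comparisons = compare_all_conditions(objects)
    paths["comparisons"] = outdir / "model_comparison.csv"
    io.write_table(comparisons, paths["comparisons"],
                   {**meta, "stage": "model_comparison"})

    # --- stage: repeated-measures ANOVA ---
    t2 = time.time()
    nonsterile = table[~table["sterilized"].astype(bool)]
    between = [b for b in config.between
               if nonsterile[b].nunique() > 1]
    res = anova_mod.rm_anova(
        nonsterile, between,
        max_poly_order=config.max_poly_order,
        poly_spacing=config.poly_spacing,
    )
    paths["anova_between"] = outdir / "anova_between.csv"
    paths["anova_within"] = outdir / "anova_within.csv"
    paths["anova_contrasts"] = outdir / "anova_contrasts.csv"
    io.write_table(res.between, paths["anova_between"],
                   {**meta, "stage": "anova_between"})
    io.write_table(res.within, paths["anova_within"],
                   {**meta, "stage": "anova_within"})
    io.write_table(res.contrasts, paths["anova_contrasts"],
                   {**meta, "stage": "anova_contrasts"})
    if table["sterilized"].astype(bool).any():
        try:
            pair = factors_mod._sterilization_slice(table)
            res_st = anova_mod.rm_anova(
                pair, ["sterilized"],
                max_poly_order=config.max_poly_order,
                poly_spacing=config.poly_spacing,
            )
            paths["anova_sterilization"] = (
                outdir / "anova_sterilization_between.csv")
            io.write_table(res_st.between, paths["anova_sterilization"],
                           {**meta, "stage": "anova_sterilization_between"})
            io.write_table(
                res_st.within, outdir / "anova_sterilization_within.csv",
                {**meta, "stage": "anova_sterilization_within"})
        except (ValueError, KeyError) as exc:
            log.warning("sterilization ANOVA skipped: %s", exc)
    log.info("anova: %d subjects x %d times (%.2fs)", res.n_subjects,
             res.n_time_levels, time.time() - t2)

    # --- stage: factor ranking ---
    rankings = rank_from_fits(fits)
    paths["rankings"] = outdir / "ranking.csv"
    io.write_table(rankings, paths["rankings"], {**meta, "stage": "ranking"})

    # --- stage: report ---
    report = render_report(fits, comparisons, rankings)
    paths["report"] = outdir / "report.md"
    paths["report"].write_text(
        f"<!-- config_hash: {chash} seed: {config.seed} -->\n" + report
    )

    if config.plots:
        _plot_conditions(fits, table, outdir)

    log.info("pipeline done in %.2fs -> %s", time.time() - t0, outdir)
    return PipelineResult(
        outdir=outdir,
        paths=paths,
        n_conditions=table["condition_id"].nunique(),
        n_nonconverged=n_nonconverged,
        fits=fits,
        comparisons=comparisons,
        rankings=rankings,
    )
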