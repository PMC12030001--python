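"""End-to-end analysis pipeline.

Simulate (or ingest) a balanced multi-year trial, derive the JIP-test
parameter tables, fit cross-validated PLS models for grain yield and
grain moisture from both predictor blocks (biophysical parameters and
raw transients), push the cross-validated predictions through the same
variance-component machinery as the observed traits, and report the
efficiency of indirect selection on the predicted traits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ojip, pls, quantgen, synthetic
from .ojip import PLOT_KEYS

logger = logging.getLogger(__name__)

OBSERVED_TRAITS = {"gy": "gy_t_ha", "gm": "gm_pct",
                   "fvfm": "phi_Po", "piabs": "PI_ABS"}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"                      # simulate | ingest
    transients_csv: str | None = None
    agro_csv: str | None = None
    traits: tuple[str, ...] = ("gy", "gm")
    predictor_sets: tuple[str, ...] = ("parameters", "transients")
    folds: int = 10
    seed_sim: int = 1
    seed_cv: int = 1
    max_components: int | None = None
    param_preset: str = "extended58"
    out_dir: str = "fluorosel_out"
    figures: bool = False
    config_yaml: str | None = None              # generator config override

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if not self.traits or not self.predictor_sets:
            raise ValueError("need at least one trait x predictor-set combination")
        if self.mode == "ingest" and not (self.transients_csv and self.agro_csv):
            raise ValueError("ingest mode requires transients_csv and agro_csv")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("traits", "predictor_sets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SelectionReport:
    """Machine-readable result of a run, plus in-memory artifacts."""

    report: dict
    table: pd.DataFrame = field(repr=False)
    curves: dict = field(repr=False, default_factory=dict)
    models: dict = field(repr=False, default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.report, sort_keys=True, indent=2)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("ingest")
def _load_tables(config: RunConfig):
    if config.mode == "simulate":
        if config.config_yaml:
            design, effects = synthetic.load_config(config.config_yaml)
        else:
            design, effects = synthetic.default_paper_config()
        trial = synthetic.generate_trial(design, effects, seed=config.seed_sim)
        return trial.transients, trial.agro, design
    transients = ojip.read_transients_csv(config.transients_csv)
    agro = pd.read_csv(config.agro_csv, comment="#")
    required = set(PLOT_KEYS) | {"gy_t_ha", "gm_pct"}
    missing = required - set(agro.columns)
    if missing:
        raise ValueError(f"agro table missing columns {sorted(missing)}")
    design = synthetic.TrialDesign(
        n_genotypes=agro["genotype"].nunique(),
        n_years=agro["year"].nunique(),
        n_reps=agro["rep"].nunique(),
        n_plants_per_plot=transients.groupby(PLOT_KEYS).size().max(),
        n_timepoints=sum(c.startswith("t_") for c in transients.columns),
    )
    return transients, agro, design


def run(config: RunConfig) -> SelectionReport:
    """Execute the full workflow and write all artifacts to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    transients, agro, design = _load_tables(config)

    plant_params, plot_params = ojip.jip_table(
        transients, preset=config.param_preset,
        design_plants_per_plot=design.n_plants_per_plot)
    plot_trans = ojip.plot_mean_transients(transients)
    plant_params.to_csv(out / "jip_parameters.csv", index=False)
    plot_params.to_csv(out / "jip_parameters_plot.csv", index=False)
    plot_trans.to_csv(out / "transients_plot.csv", index=False)

    table = (agro.merge(plot_params, on=PLOT_KEYS, validate="one_to_one")
                 .merge(plot_trans, on=PLOT_KEYS, validate="one_to_one")
                 .sort_values(PLOT_KEYS, kind="mergesort")
                 .reset_index(drop=True))

    param_cols = ojip.PARAM_PRESETS[config.param_preset]
    trans_cols = [c for c in plot_trans.columns if c.startswith("t_")]
    predictor_blocks = {
        "parameters": (param_cols, True),    # heterogeneous units: autoscale
        "transients": (trans_cols, False),   # homogeneous units: center only
    }

    report: dict = {
        "seeds": {"simulation": config.seed_sim, "cross_validation": config.seed_cv},
        "design": {"n_genotypes": design.n_genotypes, "n_years": design.n_years,
                   "n_reps": design.n_reps,
                   "n_plants_per_plot": int(design.n_plants_per_plot)},
        "observed": {}, "correlations": {}, "models": {},
    }

    # --- observed traits --------------------------------------------------
    varcomp_rows = []
    for trait, col in OBSERVED_TRAITS.items():
        vc = quantgen.estimate_variance_components(table, col)
        h2 = vc.heritability()
        report["observed"][trait] = {
            "sigma2_G": vc.sigma2_g, "sigma2_E": vc.sigma2_env,
            "sigma2_GxE": vc.sigma2_gxe, "sigma2_e": vc.sigma2_e,
            "H2": h2, "se_H2": vc.se_h2,
        }
        varcomp_rows.append({"trait": trait, "sigma2_G": vc.sigma2_g,
                             "sigma2_E": vc.sigma2_env,
                             "sigma2_GxE": vc.sigma2_gxe,
                             "sigma2_e": vc.sigma2_e, "H2": h2,
                             "se_H2": vc.se_h2})
    pd.DataFrame(varcomp_rows).to_csv(out / "varcomp.csv", index=False)

    corr_rows = []
    names = list(OBSERVED_TRAITS)
    for i, ta in enumerate(names):
        for tb in names[i + 1:]:
            r, p, stars = quantgen.pearson(
                table, OBSERVED_TRAITS[ta], OBSERVED_TRAITS[tb])
            gc = quantgen.genetic_covariance(
                table, OBSERVED_TRAITS[ta], OBSERVED_TRAITS[tb])
            corr_rows.append({"trait_x": ta, "trait_y": tb,
                              "pearson_r": r, "p": p, "stars": stars,
                              "r_G": gc.r_g, "se_r_G": gc.se_r_g})
    corr = pd.DataFrame(corr_rows)
    corr.to_csv(out / "correlations.csv", index=False)
    report["correlations"] = corr.to_dict(orient="records")

    # --- prediction models ------------------------------------------------
    sel_rows = []
    result = SelectionReport(report=report, table=table)
    for trait in config.traits:
        y_col = OBSERVED_TRAITS[trait]
        y = table[y_col].to_numpy()
        h2_obs = report["observed"][trait]["H2"]
        for pset in config.predictor_sets:
            cols, scale = predictor_blocks[pset]
            X = table[cols]
            curve = pls.cross_validate(
                X, y, max_components=config.max_components,
                folds=config.folds, seed=config.seed_cv, scale=scale)
            k = curve.selected
            oof = curve.oof[:, k]
            evp = pls.explained_variance(y, oof)
            model = pls.fit_pls(X, y, n_components=k, scale=scale)
            tag = f"{trait}_{pset}"
            pred_col = f"pred_{tag}"
            table[pred_col] = oof

            vc = quantgen.estimate_variance_components(table, pred_col)
            h2_pred = vc.heritability()
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                gc = quantgen.genetic_covariance(table, y_col, pred_col)
            if not np.isfinite(h2_pred) or h2_pred <= 0 or not np.isfinite(gc.r_g):
                ei = quantgen.SelectionEfficiency(
                    r_g=gc.r_g, h_x=0.0, h_y=float(np.sqrt(h2_obs)),
                    ei_percent=0.0)
            else:
                ei = quantgen.indirect_selection_efficiency(
                    gc.r_g, h2_pred, h2_obs)

            curve.to_frame().to_csv(out / f"rmsep_{tag}.csv", index=False)
            pd.DataFrame({"predictor": cols, "coefficient": model.coef_}) \
                .to_csv(out / f"coefficients_{tag}.csv", index=False)
            pd.DataFrame(model.x_loadings_,
                         index=pd.Index(cols, name="predictor"),
                         columns=[f"lv{i + 1}" for i in range(model.n_components_)]) \
                .to_csv(out / f"loadings_{tag}.csv")
            table[[*PLOT_KEYS, y_col, pred_col]].to_csv(
                out / f"predictions_{tag}.csv", index=False)

            report["models"][tag] = {
                "trait": trait, "predictors": pset,
                "selected_lv": int(k), "min_rmsep": curve.min_rmsep(),
                "explained_variance_pct": evp,
                "sigma2_G": vc.sigma2_g, "sigma2_E": vc.sigma2_env,
                "sigma2_GxE": vc.sigma2_gxe, "sigma2_e": vc.sigma2_e,
                "H2": h2_pred, "se_H2": vc.se_h2,
                "r_G_with_source": gc.r_g, "se_r_G": gc.se_r_g,
                "H2_observed": h2_obs,
                "EI_percent": ei.ei_percent,
            }
            sel_rows.append({"model": tag, **report["models"][tag]})
            result.curves[tag] = curve
            result.models[tag] = model

    pd.DataFrame(sel_rows).to_csv(out / "selection_efficiency.csv", index=False)
    (out / "report.json").write_text(result.to_json())
    _write_summary(out / "summary.txt", report)
    if config.figures:
        make_figures(result, out)
    return result


def _write_summary(path: Path, report: dict) -> None:
    lines = ["fluorosel run summary", "=" * 21, ""]
    lines.append("Observed traits (variance components and heritability):")
    for trait, d in report["observed"].items():
        lines.append(
            f"  {trait:6s} sigma2_G={d['sigma2_G']:.4g}  "
            f"sigma2_GxE={d['sigma2_GxE']:.4g}  sigma2_e={d['sigma2_e']:.4g}  "
            f"H2={d['H2']:.2f} +/- {d['se_H2']:.2f}")
    lines.append("")
    lines.append("Prediction models:")
    for tag, d in report["models"].items():
        lines.append(
            f"  {tag:22s} LV={d['selected_lv']:3d}  RMSEP={d['min_rmsep']:.3f}  "
            f"var.expl={d['explained_variance_pct']:.2f}%  "
            f"H2={d['H2']:.2f}  rG={d['r_G_with_source']:.2f}  "
            f"EI={d['EI_percent']:.2f}%")
    path.write_text("\n".join(lines) + "\n")


def make_figures(result: SelectionReport, out_dir: str | Path) -> list[Path]:
    """RMSEP curves (minimum marked), coefficient/loading profiles,
    observed-vs-predicted scatters, and the EI bar chart."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for tag, curve in result.curves.items():
        d = result.report["models"][tag]
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(curve.ks[1:], curve.rmsep[1:], "-o", ms=3)
        ax.axvline(d["selected_lv"], color="red", lw=1)
        ax.set_xlabel("latent variables")
        ax.set_ylabel("RMSEP")
        ax.set_title(tag)
        fig.tight_layout()
        p = out / f"fig_rmsep_{tag}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

        model = result.models.get(tag)
        if model is not None:
            fig, ax = plt.subplots(figsize=(5, 3.5))
            ax.plot(model.coef_, lw=0.8)
            ax.set_xlabel("predictor index")
            ax.set_ylabel("coefficient")
            ax.set_title(tag)
            fig.tight_layout()
            p = out / f"fig_coefficients_{tag}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths.append(p)

        pred_col = f"pred_{tag}"
        y_col = OBSERVED_TRAITS[d["trait"]]
        if pred_col in result.table.columns:
            fig, ax = plt.subplots(figsize=(4, 4))
            ax.scatter(result.table[y_col], result.table[pred_col], s=8)
            ax.set_xlabel(f"observed {d['trait']}")
            ax.set_ylabel("cross-validated prediction")
            ax.set_title(f"{tag}: {d['explained_variance_pct']:.1f}% explained")
            fig.tight_layout()
            p = out / f"fig_predicted_{tag}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths.append(p)

    if result.report["models"]:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        tags = list(result.report["models"])
        eis = [result.report["models"][t]["EI_percent"] for t in tags]
        ax.bar(range(len(tags)), eis)
        ax.set_xticks(range(len(tags)), tags, rotation=30, ha="right")
        ax.set_ylabel("indirect selection efficiency (%)")
        fig.tight_layout()
        p = out / "fig_selection_efficiency.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
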