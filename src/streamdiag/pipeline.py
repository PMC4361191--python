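"""End-to-end workflow: simulate -> standardize -> train -> validate -> diagnose.

The pipeline binds the stages into the cross-scale diagnosis: a mesocosm
experiment quantifies how 11 biological responses react to nutrient and
fine-sediment treatments; two 50-member network ensembles learn to read the
treatment level back off the (integer-coded) responses; the validated
ensembles are applied to gradient-survey sites, and the resulting stress
scores are regressed on the catchment grazing proportion.

All randomness flows from three named seeds (mesocosm, survey, ensemble
base); rerunning with the same configuration reproduces every artifact
byte-identically. Every intermediate table is written to the output
directory, together with a run manifest recording the configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, prep, synthdata
from .diagnose import diagnose_report, plot_scores, regress_scores, score_sites
from .ensemble import Ensemble, error_rate, predict, save_ensemble, train_ensemble
from .errors import ConfigError, StreamDiagError
from .stats import anova2

log = logging.getLogger("streamdiag")

__all__ = ["PipelineConfig", "run_pipeline"]

TARGETS = ("nutrient", "sediment")
#: Offset separating the two ensembles' seed streams.
_TARGET_SEED_OFFSET = {"nutrient": 0, "sediment": 500_017}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; defaults are the study conditions."""

    mesocosm: synthdata.MesocosmConfig
    survey: synthdata.SurveyConfig
    ensemble_seed: int = 0
    standardization_mode: str = "ratio"
    k_discard: int = 2
    n_priority: int = 3
    n_members: int = 50
    mse_goal: float = 0.2
    max_epochs: int = 1000
    max_restarts_per_member: int = 20
    hidden: tuple[int, ...] = (6, 3)
    classification_threshold: float = 1.5
    field_control_grazing_cutoff: float = 0.01
    alpha: float = 0.05
    regress_on: str = "score"  # "score" (clipped, default) or "raw_mean"
    make_plots: bool = False

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "PipelineConfig":
        """Default configuration; the three stage seeds derive from ``seed``."""
        cfg = cls(
            mesocosm=synthdata.MesocosmConfig.default(seed=seed),
            survey=synthdata.SurveyConfig.default(seed=seed + 1),
            ensemble_seed=seed + 2,
        )
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        """Load a config file layered over the packaged defaults.

        The file mirrors defaults.yaml (``mesocosm:``, ``survey:``,
        ``pipeline:`` sections plus optional ``seeds:`` with keys mesocosm,
        survey, ensemble). ``seed``, when given, overrides all three.
        """
        try:
            user = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        known = {"mesocosm", "survey", "pipeline", "seeds"}
        unknown = set(user) - known
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        seeds = user.get("seeds", {})
        base = cls.default(seed=int(seeds.get("master", 0)))
        meso_over = dict(user.get("mesocosm", {}))
        for key in ("nutrient_effect", "sediment_effect", "light_effect", "year_effect"):
            if key in meso_over:
                meso_over[key] = synthdata._full_effect_map(
                    {**getattr(base.mesocosm, key), **meso_over[key]},
                    base.mesocosm.response_names,
                )
        try:
            mesocosm = replace(base.mesocosm, **meso_over)
            survey = replace(base.survey, **{
                k: tuple(v) if k == "grazing_range" else v
                for k, v in user.get("survey", {}).items()
            })
            pipe = user.get("pipeline", {})
            if "hidden" in pipe:
                pipe["hidden"] = tuple(pipe["hidden"])
            cfg = replace(base, mesocosm=mesocosm, survey=survey, **pipe)
        except TypeError as exc:
            raise ConfigError(f"invalid config key: {exc}") from exc
        if "mesocosm" in seeds:
            cfg = replace(cfg, mesocosm=replace(cfg.mesocosm, seed=int(seeds["mesocosm"])))
        if "survey" in seeds:
            cfg = replace(cfg, survey=replace(cfg.survey, seed=int(seeds["survey"])))
        if "ensemble" in seeds:
            cfg = replace(cfg, ensemble_seed=int(seeds["ensemble"]))
        if seed is not None:
            cfg = replace(
                cfg,
                mesocosm=replace(cfg.mesocosm, seed=seed),
                survey=replace(cfg.survey, seed=seed + 1),
                ensemble_seed=seed + 2,
            )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.mesocosm.validate()
        self.survey.validate()
        if self.standardization_mode not in ("ratio", "zscore"):
            raise ConfigError(f"unknown standardization mode {self.standardization_mode!r}")
        if self.n_members < 1:
            raise ConfigError("n_members must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.mse_goal <= 0:
            raise ConfigError("mse_goal must be positive")
        if self.regress_on not in ("score", "raw_mean"):
            raise ConfigError(f"regress_on must be 'score' or 'raw_mean'")
        n_vars = len(self.mesocosm.response_names)
        if self.k_discard < 0 or n_vars - self.k_discard < self.n_priority:
            raise ConfigError("k_discard/n_priority incompatible with variable count")

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["mesocosm"]["response_names"] = list(self.mesocosm.response_names)
        doc["survey"]["grazing_range"] = list(self.survey.grazing_range)
        doc["hidden"] = list(self.hidden)
        return doc

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _write_json(doc: dict, path: Path) -> None:
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def mesocosm_anova_summary(mesocosm: pd.DataFrame, response_names) -> dict:
    """Two-way ANOVA (nutrients x sediments) for every response variable."""
    out = {}
    for v in response_names:
        table = anova2(
            mesocosm[v],
            mesocosm["nutrient_level"],
            mesocosm["sediment_level"],
            names=("nutrient", "sediment"),
        )
        out[v] = {
            "nutrient": {"F": table.factor_a.F, "p": table.factor_a.p},
            "sediment": {"F": table.factor_b.F, "p": table.factor_b.p},
            "interaction": {"F": table.interaction.F, "p": table.interaction.p},
        }
    return out


def prepare_mesocosm_features(
    config: PipelineConfig, mesocosm: pd.DataFrame
) -> pd.DataFrame:
    """Standardize mesocosm responses against same-year low/low controls."""
    controls = prep.mesocosm_control_ids(mesocosm)
    features = prep.standardize(
        mesocosm,
        controls,
        config.mesocosm.response_names,
        mode=config.standardization_mode,
    )
    return features.merge(
        mesocosm[["record_id", "nutrient_level", "sediment_level"]], on="record_id"
    )


def select_and_split(
    config: PipelineConfig, features: pd.DataFrame, target_name: str
) -> tuple[tuple[str, ...], tuple[str, ...], prep.TrainingSplit]:
    """Input screening, priority ranking and the half/half split for one target."""
    target = features[f"{target_name}_level"].to_numpy()
    retained = prep.discard_low_correlation(
        features, target, config.mesocosm.response_names, k=config.k_discard
    )
    priorities = prep.rank_priority_inputs(features, target, retained, config.n_priority)
    split = prep.make_split(features, target, priorities)
    return retained, priorities, split


def train_stage(
    config: PipelineConfig, features: pd.DataFrame, outdir: Path | None = None
) -> dict[str, Ensemble]:
    """Train one ensemble per stressor on the standardized mesocosm table."""
    ensembles: dict[str, Ensemble] = {}
    for target_name in TARGETS:
        retained, priorities, split = select_and_split(config, features, target_name)
        log.info("%s: inputs=%s priorities=%s", target_name, retained, priorities)
        ens = train_ensemble(
            features,
            features[f"{target_name}_level"],
            split,
            target_name,
            retained,
            n_members=config.n_members,
            base_seed=config.ensemble_seed + _TARGET_SEED_OFFSET[target_name],
            goal=config.mse_goal,
            max_epochs=config.max_epochs,
            max_restarts_per_member=config.max_restarts_per_member,
            hidden=config.hidden,
            log=log,
        )
        ensembles[target_name] = ens
        if outdir is not None:
            save_ensemble(ens, outdir / "ensembles" / target_name)
            prep.write_split_csv(split, outdir / f"split_{target_name}.csv")
    return ensembles


def validate_stage(
    config: PipelineConfig,
    features: pd.DataFrame,
    ensembles: dict[str, Ensemble],
    outdir: Path | None = None,
) -> dict:
    """Apply each ensemble to its training and validation halves."""
    out = {}
    for target_name, ens in ensembles.items():
        truth = features.set_index("record_id")[f"{target_name}_level"]
        summary = {
            "input_vars": list(ens.input_vars),
            "priority_inputs": list(ens.split.priority_inputs),
            "n_members": len(ens.members),
            "median_epochs": float(np.median(ens.member_epochs)),
        }
        for part, ids in (
            ("training", sorted(ens.split.train_ids)),
            ("validation", sorted(ens.split.validation_ids)),
        ):
            sub = features[features["record_id"].isin(ids)]
            preds = predict(ens, sub, threshold=config.classification_threshold)
            preds["true_level"] = truth.loc[preds["record_id"]].to_numpy()
            rate = error_rate(preds["classified_level"], preds["true_level"])
            n_miss = int((preds["classified_level"] != preds["true_level"]).sum())
            summary[f"{part}_error_pct"] = rate
            summary[f"{part}_misclassified"] = n_miss
            if outdir is not None:
                preds.to_csv(outdir / f"predictions_{target_name}_{part}.csv", index=False)
        out[target_name] = summary
        log.info(
            "%s ensemble: training error %.1f%%, validation error %.1f%%",
            target_name, summary["training_error_pct"], summary["validation_error_pct"],
        )
    return out


def diagnose_stage(
    config: PipelineConfig,
    ensembles: dict[str, Ensemble],
    survey: pd.DataFrame,
    outdir: Path | None = None,
) -> dict:
    """Score survey sites, regress on grazing, and render the verdict."""
    controls = prep.survey_control_ids(survey, config.field_control_grazing_cutoff)
    site_features = prep.standardize(
        survey,
        controls,
        config.mesocosm.response_names,
        id_col="site_id",
        mode=config.standardization_mode,
    )
    results, score_tables = {}, []
    for target_name, ens in ensembles.items():
        scores = score_sites(
            ens, site_features, survey["grazing_proportion"],
            threshold=config.classification_threshold,
        )
        score_tables.append(scores)
        results[target_name] = regress_scores(scores, value_col=config.regress_on)
        if outdir is not None and config.make_plots:
            plot_scores(scores, results[target_name], outdir / f"scores_{target_name}.png")
    report = diagnose_report(results["nutrient"], results["sediment"], alpha=config.alpha)

    # conventional univariate companion metric: %EPT vs grazing
    ept = pd.DataFrame(
        {
            "grazing_proportion": survey["grazing_proportion"],
            "pct_ept": 100.0
            * survey["ept_count"]
            / (survey["ept_count"] + survey["non_ept_count"]),
        }
    )
    report["pct_ept_regression"] = regress_scores(ept, value_col="pct_ept").to_dict()

    if outdir is not None:
        pd.concat(score_tables, ignore_index=True).to_csv(outdir / "scores.csv", index=False)
    return report


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full workflow into ``outdir``; returns the report dict.

    On a stage failure, partial outputs are kept and a ``FAILED`` marker
    naming the stage is written before the exception propagates.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        stage = "simulate"
        mesocosm = synthdata.generate_mesocosm(config.mesocosm)
        synthdata.write_mesocosm_csv(mesocosm, outdir / "mesocosm.csv")
        survey, truth = synthdata.generate_survey(config.survey, config.mesocosm)
        synthdata.write_survey_csv(survey, outdir / "survey.csv")
        synthdata.write_truth_csv(truth, outdir / "survey_truth.csv")

        stage = "standardize"
        anova_summary = mesocosm_anova_summary(mesocosm, config.mesocosm.response_names)
        features = prepare_mesocosm_features(config, mesocosm)
        prep.write_features_csv(features, outdir / "features_mesocosm.csv")

        stage = "train"
        ensembles = train_stage(config, features, outdir)

        stage = "validate"
        validation = validate_stage(config, features, ensembles, outdir)

        stage = "diagnose"
        report = {
            "anova": anova_summary,
            "ensembles": validation,
            "survey": diagnose_stage(config, ensembles, survey, outdir),
        }
        _write_json(report, outdir / "report.json")
        _write_json(
            {
                "config_hash": config.config_hash(),
                "seeds": {
                    "mesocosm": config.mesocosm.seed,
                    "survey": config.survey.seed,
                    "ensemble": config.ensemble_seed,
                },
                "version": __version__,
                "config": config.to_dict(),
            },
            outdir / "manifest.json",
        )
    except StreamDiagError:
        (outdir / "FAILED").write_text(stage + "\n")
        raise
    return report
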