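"""End-to-end run orchestration: synth -> extract -> classify -> redundancy.

A single :class:`RunConfig` carries every tunable; a run writes CSV/JSON
outputs (each stamped with the config hash) plus a manifest with per-stage
row counts, making re-runs byte-reproducible from (config, seed). The
global seed fans out to per-stage seeds through a fixed labelling scheme so
stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import classify, redundancy as red
from .features import FeatureConfig, extract_table
from .synth import BoutSpec, PopulationSpec, synthesize_dataset, write_dataset

logger = logging.getLogger("whoopsig")

__all__ = ["RunConfig", "read_metadata", "read_table", "write_table", "run_pipeline"]

REQUIRED_METADATA = [
    "whoop_id", "bout_id", "caller_id", "clan_id", "position_in_bout",
    "whoop_type", "age_months", "sex", "recording_method",
]

# stage labels for seed fan-out (global seed + label -> stage SeedSequence)
_STAGE = {"synth": 1, "clan": 2, "individual": 3, "redundancy": 4, "importance": 5}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full analysis run."""

    out_dir: str = "results/run"
    seed: int = 0
    sample_rate: float = 32000.0
    snr_db: Optional[float] = 15.0
    keep_audio: bool = False

    # population / bouts
    n_clans: int = 4
    individuals_per_clan: int = 5
    clan_effect_scale: float = 0.0
    individual_effect_scale: float = 0.08
    within_individual_cv: float = 0.04
    n_bouts_per_individual: int = 4
    bout_length_min: int = 2
    bout_length_max: int = 34

    # dataset filters
    min_age_months: int = 24
    min_bouts: int = 2
    min_whoops_per_bout: int = 3
    final_types: tuple = ("A", "S")

    # classification
    n_repeats: int = 1000
    n_trees: int = 500
    importance_repeats: int = 50

    # redundancy
    redundancy_k_max: int = 10
    baseline_method: str = "exact"

    def population_spec(self) -> PopulationSpec:
        ss = np.random.SeedSequence([self.seed, _STAGE["synth"]])
        return PopulationSpec(
            n_clans=self.n_clans,
            individuals_per_clan=self.individuals_per_clan,
            clan_effect_scale=self.clan_effect_scale,
            individual_effect_scale=self.individual_effect_scale,
            within_individual_cv=self.within_individual_cv,
            seed=int(ss.generate_state(1)[0] % (2**31 - 1)),
        )

    def bout_spec(self) -> BoutSpec:
        return BoutSpec(length_min=self.bout_length_min, length_max=self.bout_length_max)

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, _STAGE[stage]])
        return int(ss.generate_state(1)[0] % (2**31 - 1))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "final_types" in data:
            data["final_types"] = tuple(data["final_types"])
        return cls(**data)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a whoop metadata table.

    Enforces the schema, unique whoop ids and bout -> caller uniqueness,
    naming the offending row or bout in the error message.
    """
    table = pd.read_csv(path, comment="#")
    if table.empty:
        raise ValueError(f"{path}: empty metadata file")
    missing = [c for c in REQUIRED_METADATA if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dup = table["whoop_id"][table["whoop_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate whoop_id {dup.iloc[0]!r}")
    callers = table.groupby("bout_id")["caller_id"].nunique()
    bad = callers[callers > 1]
    if not bad.empty:
        raise ValueError(
            f"{path}: bout {bad.index[0]!r} maps to multiple callers"
        )
    return table


def write_table(table: pd.DataFrame, path: str | Path, config_hash: str) -> None:
    """CSV with a header-comment provenance line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        table.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig, feature_config: FeatureConfig = FeatureConfig()) -> dict:
    """Execute the full analysis and write all stage outputs.

    Stages: synthesize the population and bouts; extract the 16 features per
    whoop; test the clan and individual signature hypotheses (repeated CV
    against WE); compute permutation feature importance; and, when accuracy
    beats chance, the serial-redundancy prefix curve with its baselines.
    Returns the manifest (also written to ``<out_dir>/manifest.json``).
    """
    out = Path(config.out_dir)
    chash = config.config_hash()
    manifest: dict = {"config_hash": chash, "config": dataclasses.asdict(config),
                      "counts": {}, "warnings": []}

    logger.info("stage synth: generating population and bouts")
    records, params, truth = synthesize_dataset(
        config.population_spec(), config.bout_spec(),
        n_bouts_per_individual=config.n_bouts_per_individual,
        snr_db=config.snr_db, sample_rate=config.sample_rate,
    )
    manifest["counts"]["whoops_synthesized"] = len(records)
    if config.keep_audio:
        write_dataset(records, out / "dataset", params)
    write_table(truth, out / "truth.csv", chash)

    logger.info("stage extract: %d whoops", len(records))
    feats = extract_table(records, feature_config)
    write_table(feats, out / "features.csv", chash)
    n_failed = int(feats["failed"].sum())
    manifest["counts"]["features_attempted"] = len(feats)
    manifest["counts"]["features_emitted"] = len(feats) - n_failed
    manifest["counts"]["features_failed"] = n_failed
    if len(feats) != len(records):
        raise RuntimeError("row-count mismatch between synth and extract stages")

    adults = classify.filter_adults(classify.drop_failed(feats), config.min_age_months)
    manifest["counts"]["adult_whoops"] = len(adults)

    logger.info("stage classify: clan scheme")
    clan_spec = classify.SplitSpec(scheme="clan", n_repeats=config.n_repeats,
                                   n_trees=config.n_trees,
                                   seed=config.stage_seed("clan"))
    clan_summary = classify.run_repeats(adults, clan_spec, target="clan_id")
    _write_json(dict(clan_summary.to_dict(), config_hash=chash),
                out / "clan_summary.json")
    write_table(clan_summary.pooled_confusion.reset_index(names="true_class"),
                out / "clan_confusion.csv", chash)

    logger.info("stage classify: individual scheme")
    indiv = classify.prepare_individual_dataset(
        adults, config.min_bouts, config.min_whoops_per_bout)
    manifest["counts"]["individual_dataset_whoops"] = len(indiv)
    ind_spec = classify.SplitSpec(scheme="individual", n_repeats=config.n_repeats,
                                  n_trees=config.n_trees,
                                  seed=config.stage_seed("individual"))
    ind_summary = classify.run_repeats(indiv, ind_spec, target="caller_id")
    _write_json(dict(ind_summary.to_dict(), config_hash=chash),
                out / "individual_summary.json")
    write_table(ind_summary.pooled_confusion.reset_index(names="true_class"),
                out / "individual_confusion.csv", chash)

    logger.info("stage importance")
    imp_spec = classify.SplitSpec(scheme="individual",
                                  n_repeats=config.importance_repeats,
                                  n_trees=config.n_trees,
                                  seed=config.stage_seed("importance"))
    importance = classify.feature_importance(indiv, imp_spec, target="caller_id")
    write_table(importance, out / "importance.csv", chash)

    logger.info("stage redundancy")
    final = classify.subset_types(indiv, set(config.final_types))
    red_result: dict = {}
    try:
        final = classify.prepare_individual_dataset(
            final, config.min_bouts, min_whoops_per_bout=1)
        red_spec = classify.SplitSpec(scheme="individual",
                                      n_repeats=config.n_repeats,
                                      n_trees=config.n_trees,
                                      seed=config.stage_seed("redundancy"))
        summary = classify.run_repeats(final, red_spec, target="caller_id",
                                       collect_votes=True)
        curve = red.prefix_accuracy_curve(final, red_spec, summary=summary,
                                          k_max=config.redundancy_k_max)
        K = final["caller_id"].nunique()
        p_hat = min(max(curve.mean_accuracy, 1.0 / K), 1.0)
        base = red.equal_informative_baseline(
            p_hat, K, len(curve.k), method=config.baseline_method,
            seed=config.stage_seed("redundancy"))
        frame = curve.to_frame()
        frame["chance"] = red.chance_baseline(curve.mean_we, len(curve.k))
        frame["equal_informative"] = base
        write_table(frame, out / "redundancy_curve.csv", chash)
        red_result = {"ran": True, "mean_accuracy": curve.mean_accuracy,
                      "mean_we": curve.mean_we, "n_classes": int(K)}
    except (red.RedundancyGateError, ValueError) as exc:
        manifest["warnings"].append(f"redundancy stage skipped: {exc}")
        red_result = {"ran": False, "reason": str(exc)}
    manifest["redundancy"] = red_result
    manifest["clan"] = clan_summary.to_dict()
    manifest["individual"] = ind_summary.to_dict()
    _write_json(manifest, out / "manifest.json")
    return manifest
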