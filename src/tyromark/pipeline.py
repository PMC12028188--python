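"""End-to-end orchestration: simulate/load -> filter -> associate ->
impute -> embed -> multi-model (with and without age variables) ->
consensus ranking/clustering -> logistic ablation -> per-patient cut-off
analysis, with every artifact written to the output directory plus a run
manifest sufficient to reproduce the run."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ablation import ablation_scan, make_three_way_split
from .association import association_table
from .consensus import (
    build_importance_table,
    compare_importance_distributions,
    consensus_cluster,
    rank_variables,
)
from .cutoff import patient_means, roc_cutoff, screening_table
from .exceptions import ConfigurationError, StageError
from .io import load_cohort_csv
from .multimodel import INTERNAL, HyperSpace, run_multimodel
from .preprocess import build_dataset, embed_2d, filter_records
from .synthetic import COHORTS, SyntheticConfig, generate_cohorts, write_cohort_csv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative configuration for one full analysis run."""

    output_dir: str = "tyromark_out"
    input_path: Optional[str] = None
    column_map: Optional[dict] = None
    synthetic: Optional[SyntheticConfig] = None
    afp_threshold: float = 5.0
    completeness_min: float = 0.7
    n_rounds: int = 5000
    auc_threshold: float = 0.7
    hyper_space: HyperSpace = field(default_factory=HyperSpace)
    n_estimators: int = 50
    grouped_split: bool = False
    use_early_stopping: bool = False
    embed: bool = True
    embed_neighbors: int = 15
    n_clusters: int = 2
    ablation_variables: Optional[list[str]] = None
    alt_cut_reference: float = 29.0
    n_boot: int = 2000
    master_seed: int = 0

    def validate(self) -> None:
        if self.input_path is None and self.synthetic is None:
            raise ConfigurationError("either input_path or synthetic must be set")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ConfigurationError(f"input_path does not exist: {self.input_path}")
        if self.n_rounds < 1:
            raise ConfigurationError("n_rounds: must be >= 1")
        if self.synthetic is not None:
            self.synthetic.validate()
        self.hyper_space.validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file does not exist: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "synthetic" in data and data["synthetic"] is not None:
            syn = data["synthetic"]
            if isinstance(syn, dict):
                syn = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in syn.items()}
                syn = {k: tuple(tuple(e) if isinstance(e, list) else e for e in v)
                       if isinstance(v, tuple) else v for k, v in syn.items()}
                data["synthetic"] = SyntheticConfig(**syn)
        if "hyper_space" in data and isinstance(data["hyper_space"], dict):
            data["hyper_space"] = HyperSpace(
                **{k: tuple(v) for k, v in data["hyper_space"].items()})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        defaults = {f.name for f in dataclasses.fields(cls)} - set(data)
        if defaults:
            logger.info("config defaults applied for: %s", sorted(defaults))
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            raise StageError(name, str(exc)) from exc
    return wrap


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the manifest dictionary.

    Any stage failure aborts with the stage name and cause; artifacts
    written before the failure are retained for debugging.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "version": __version__,
                      "stages": {}, "artifacts": []}

    def note(stage: str, **info):
        manifest["stages"][stage] = info
        logger.info("stage %-12s %s", stage, info)

    def artifact(path: Path):
        manifest["artifacts"].append(path.name)

    # --- acquire records -------------------------------------------------
    if config.synthetic is not None:
        records = _stage("simulate")(generate_cohorts, config.synthetic)
        p = out / "records.csv"
        write_cohort_csv(records, p, config.synthetic)
        artifact(p)
        note("simulate", n_records=len(records))
    else:
        records = _stage("load")(load_cohort_csv, config.input_path, config.column_map)
        note("load", n_records=len(records), path=str(config.input_path))

    # --- filter + association screen ------------------------------------
    kept = _stage("filter")(filter_records, records, config.completeness_min)
    note("filter", n_in=len(records), n_out=len(kept))

    assoc = _stage("associate")(association_table, kept)
    p = out / "association.csv"
    assoc.to_csv(p, index=False)
    artifact(p)
    note("associate", n_variables=len(assoc))

    # --- datasets (imputed), embedding ----------------------------------
    datasets = {}
    for include_age, tag in ((False, "biochem"), (True, "with_age")):
        ds = _stage("impute")(build_dataset, kept, include_age,
                              config.afp_threshold, config.completeness_min,
                              config.master_seed)
        datasets[tag] = ds
        mat = pd.DataFrame(ds.feature_matrix, columns=ds.feature_names)
        mat.insert(0, "patient_id", ds.patient_ids)
        mat.insert(1, "cohort", ds.cohort_labels)
        mat["afp_altered"] = ds.target
        p = out / f"dataset_{tag}.csv"
        mat.to_csv(p, index=False)
        artifact(p)
    note("impute", n_records=datasets["biochem"].n_records)

    if config.embed:
        ds = datasets["with_age"]
        coords = _stage("embed")(embed_2d, ds.feature_matrix, config.master_seed,
                                 config.embed_neighbors)
        emb = pd.DataFrame(coords, columns=["umap_1", "umap_2"])
        emb.insert(0, "cohort", ds.cohort_labels)
        p = out / "embedding.csv"
        emb.to_csv(p, index=False)
        artifact(p)
        note("embed", n_records=len(emb))

    # --- multi-model runs (without and with age variables) ---------------
    results = {}
    tables = {}
    for tag, ds in datasets.items():
        cohort_of = ds.cohort_labels
        train_label = COHORTS[0]
        train_idx = np.where(cohort_of == train_label)[0]
        train_ds = ds.subset(train_idx)
        external = {c: ds.subset(np.where(cohort_of == c)[0])
                    for c in COHORTS[1:] if (cohort_of == c).any()}
        res = _stage("multimodel")(
            run_multimodel, train_ds, external,
            n_rounds=config.n_rounds, auc_threshold=config.auc_threshold,
            space=config.hyper_space, master_seed=config.master_seed,
            n_estimators=config.n_estimators, grouped=config.grouped_split,
            use_early_stopping=config.use_early_stopping)
        results[tag] = res
        p = out / f"rounds_{tag}.jsonl"
        res.write_jsonl(p)
        artifact(p)
        note(f"multimodel_{tag}", n_rounds=config.n_rounds,
             n_retained=len(res.retained),
             retention_fraction=res.retention_fraction, status=res.status)
        if res.status == "empty":
            raise StageError(f"multimodel_{tag}",
                             "no rounds passed the AUROC filter; ranking refuses to run")

        cohort_names = [INTERNAL] + sorted(external)
        table = _stage("consensus")(build_importance_table, res.retained,
                                    cohort_names, ds.feature_names)
        tables[tag] = table
        p = out / f"importance_{tag}.csv"
        table.values.to_csv(p, index_label="variable")
        artifact(p)

        ranks = {c: rank_variables(table, c).set_index("variable")["rank"]
                 for c in cohort_names}
        rank_df = pd.DataFrame(ranks)
        p = out / f"ranking_{tag}.csv"
        rank_df.to_csv(p, index_label="variable")
        artifact(p)

        cluster = _stage("consensus")(consensus_cluster, table, config.n_clusters,
                                      cluster_cohorts=True)
        _json_dump({"flat_labels": cluster.flat_labels,
                    "top_cluster": sorted(cluster.top_cluster),
                    "newick": cluster.newick,
                    "linkage": cluster.linkage.tolist()},
                   out / f"clusters_{tag}.json")
        artifact(out / f"clusters_{tag}.json")
        note(f"consensus_{tag}", top_cluster=sorted(cluster.top_cluster))

        pvals = compare_importance_distributions(res.retained, INTERNAL,
                                                 ds.feature_names)
        p = out / f"importance_pvalues_{tag}.csv"
        pvals.to_csv(p, index_label="variable")
        artifact(p)

    # --- ablation on the consensus candidate variables -------------------
    ds = datasets["with_age"]
    if config.ablation_variables:
        candidates = list(config.ablation_variables)
    else:
        # top consensus cluster, padded with the next-ranked variables to at
        # least four candidates (capped at six) so the scan stays informative
        ranking = rank_variables(tables["with_age"], INTERNAL)
        ordered = list(ranking["variable"])
        top = manifest["stages"]["consensus_with_age"]["top_cluster"]
        candidates = sorted(top, key=ordered.index)[:6]
        for v in ordered:
            if len(candidates) >= 4:
                break
            if v not in candidates:
                candidates.append(v)
    missing = [v for v in candidates if v not in ds.feature_names]
    if missing:
        raise StageError("ablate", f"candidate variables not in dataset: {missing}")
    feats = pd.DataFrame(ds.feature_matrix, columns=ds.feature_names)[candidates]
    split3 = make_three_way_split(ds.target, seed=config.master_seed)
    report = _stage("ablate")(ablation_scan, feats, ds.target, split3,
                              config.master_seed)
    p = out / "ablation.csv"
    report.rows.to_csv(p, index=False)
    artifact(p)
    note("ablate", variables=candidates, worst_omission=report.worst_omission)

    # --- per-patient cut-off + screening table ---------------------------
    alt_m = _stage("cutoff")(patient_means, kept, "alt")
    afp_m = _stage("cutoff")(patient_means, kept, "afp")
    merged = alt_m.merge(afp_m, on=["patient_id", "hcc"],
                         suffixes=("_alt", "_afp"))
    cut = _stage("cutoff")(roc_cutoff, merged["mean_value_alt"].to_numpy(),
                           merged["hcc"].to_numpy(), config.n_boot,
                           config.master_seed)
    _json_dump(cut.to_dict(), out / "cutoff.json")
    artifact(out / "cutoff.json")
    screen = _stage("cutoff")(screening_table,
                              merged["mean_value_afp"].to_numpy(),
                              merged["mean_value_alt"].to_numpy(),
                              merged["hcc"].to_numpy(),
                              (config.afp_threshold, 10.0), cut.threshold)
    p = out / "screening.csv"
    screen.to_csv(p, index=False)
    artifact(p)
    note("cutoff", threshold=cut.threshold, auc=cut.auc,
         ci=[cut.ci_low, cut.ci_high])

    manifest["artifacts"] = sorted(manifest["artifacts"])
    _json_dump(manifest, out / "manifest.json")
    return manifest
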