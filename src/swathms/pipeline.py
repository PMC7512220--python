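"""End-to-end orchestration: configuration, stage sequencing, run manifest.

``run_pipeline`` executes the stages in quantification order — simulate (or
load) fragments, rollup/normalize/average, differential tables under the
stringent and relaxed filters, PCA stratification and subgroup selection, the
subgroup-restricted differential table, the LOOCV classifier with its
permutation test, and optionally the panel-specificity test — writing every
stage's output as TSV into a run directory together with a deterministic
plain-text manifest (versions, seeds, config hash, row counts and headline
numbers).  Timings go to the log, not the manifest, so repeated runs of one
configuration produce byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import pc_logistic_loocv, permutation_test
from .differential import FilterSpec, apply_filter, format_report, t_test_protein
from .errors import ConfigurationError, StageError
from .fixtures import verify_fixtures
from .io import (
    read_fragments,
    read_key_value,
    read_table,
    write_key_value,
    write_matrix,
    write_table,
)
from .quantify import average_replicates, rollup_protein_intensity, total_sum_normalize
from .stratify import select_subgroup, sqrt_pareto_pca
from .subset import run_subset_test
from .synthetic import Cohort, CohortConfig, generate_cohort, planted_annotation

logger = logging.getLogger("swathms")

__all__ = ["PipelineConfig", "run_pipeline", "verify_fixtures"]


@dataclass(frozen=True)
class PipelineConfig:
    """Flat pipeline configuration.

    Statistical defaults follow the published analysis: stringent filter
    P < 0.01 with |log10FC| > 0.2, relaxed filter P < 0.05 with fold-change
    gates 1.3 / 0.75, three PCA components for the classifier, technical
    triplicates in the simulated design.  Empty input paths switch on
    synthetic-cohort generation.
    """

    seed: int = 0
    # inputs (empty -> simulate)
    fragments_path: str = ""
    runs_path: str = ""
    samples_path: str = ""
    annotations_path: str = ""
    # simulated-cohort design (consumed only when simulating)
    sim_n_proteins: int = 2970
    sim_n_de_proteins: int = 99
    sim_n_cases: int = 11
    sim_n_controls: int = 9
    sim_n_subgroup_cases: int = 9
    sim_n_replicates: int = 3
    sim_effect_low: float = 0.2
    sim_effect_high: float = 0.5
    # quantification
    top_peptides: int = 10
    top_fragments: int = 6
    # differential filters
    p_max: float = 0.01
    lfc_min_abs: float = 0.2
    relaxed_p_max: float = 0.05
    relaxed_fc_upper: float = 1.3
    relaxed_fc_lower: float = 0.75
    # classifier
    k_components: int = 3
    pca_policy: str = "refit_per_fold"
    n_permutations: int = 2000
    # subset test
    subset_flag: str = ""
    subset_n_draws: int = 500
    # stage toggles
    run_differential: bool = True
    run_stratify: bool = True
    run_classify: bool = True
    run_permutation: bool = True
    run_subset: bool = False

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a flat key=value file; unknown keys are rejected by name."""
        raw = read_key_value(path)
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(raw) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")
        converted = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            text = raw[f.name]
            if f.type == "bool":
                if text.lower() not in ("true", "false", "1", "0"):
                    raise ConfigurationError(
                        f"configuration key '{f.name}': expected boolean, got {text!r}"
                    )
                converted[f.name] = text.lower() in ("true", "1")
            elif f.type == "int":
                converted[f.name] = int(text)
            elif f.type == "float":
                converted[f.name] = float(text)
            else:
                converted[f.name] = text
        return cls(**converted)

    def to_mapping(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def config_hash(self) -> str:
        canon = "\n".join(f"{k}={v!r}" for k, v in sorted(self.to_mapping().items()))
        return hashlib.sha256(canon.encode()).hexdigest()

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_cases=self.sim_n_cases,
            n_controls=self.sim_n_controls,
            n_subgroup_cases=self.sim_n_subgroup_cases,
            n_proteins=self.sim_n_proteins,
            n_replicates=self.sim_n_replicates,
            n_de_proteins=self.sim_n_de_proteins,
            effect_log10fc=(self.sim_effect_low, self.sim_effect_high),
            seed=self.seed,
        )

    def primary_filter(self) -> FilterSpec:
        return FilterSpec(p_max=self.p_max, lfc_min_abs=self.lfc_min_abs)

    def relaxed_filter(self) -> FilterSpec:
        return FilterSpec(
            p_max=self.relaxed_p_max,
            fc_bounds=(self.relaxed_fc_upper, self.relaxed_fc_lower),
        )


def _stage(name):
    """Decorator-free stage wrapper: run fn, log timing, re-raise as StageError."""

    class _Ctx:
        def __init__(self):
            self.name = name

        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
                return False
            if isinstance(exc, StageError):
                return False
            raise StageError(name, str(exc)) from exc

    return _Ctx()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all enabled stages; returns the manifest mapping.

    Outputs land in ``out_dir``: matrices (raw / normalized / averaged),
    differential tables (all-case and subgroup-restricted, stringent and
    relaxed), PCA scores/loadings and the subgroup assignment, per-sample
    held-out probabilities, the permutation null, and the subset-test null
    when enabled.  Any stage failure raises :class:`StageError` naming the
    stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "swathms_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }

    with _stage("input"):
        if config.fragments_path:
            if not (config.runs_path and config.samples_path):
                raise ConfigurationError(
                    "fragments_path requires runs_path and samples_path"
                )
            fragments = read_fragments(config.fragments_path)
            runs = read_table(config.runs_path)
            samples = read_table(config.samples_path)
            truth = None
        else:
            cohort = generate_cohort(config.cohort_config())
            fragments, runs, samples, truth = cohort
            write_table(runs, out / "runs.tsv")
            write_table(samples, out / "samples.tsv")
            write_table(truth, out / "truth.tsv")
        manifest["n_fragment_rows"] = len(fragments)
        manifest["n_runs"] = len(runs)
        manifest["n_samples"] = len(samples)

    with _stage("quantify"):
        raw = rollup_protein_intensity(
            fragments, runs, config.top_peptides, config.top_fragments
        )
        normalized = total_sum_normalize(raw)
        averaged = average_replicates(normalized, runs)
        write_matrix(raw, out / "matrix_raw.tsv")
        write_matrix(normalized, out / "matrix_normalized.tsv")
        write_matrix(averaged, out / "matrix_averaged.tsv")
        manifest["n_proteins_quantified"] = len(raw.protein_ids)

    if config.run_differential:
        with _stage("differential"):
            records = t_test_protein(averaged, samples)
            write_table(format_report(records), out / "differential_all.tsv")
            primary = apply_filter(records, config.primary_filter())
            relaxed = apply_filter(records, config.relaxed_filter())
            write_table(format_report(primary), out / "differential_all_primary.tsv")
            write_table(format_report(relaxed), out / "differential_all_relaxed.tsv")
            manifest["n_differential_primary"] = len(primary)
            manifest["n_differential_primary_increased"] = int(
                (primary["direction"] == "increased").sum()
            )
            manifest["n_differential_primary_decreased"] = int(
                (primary["direction"] == "decreased").sum()
            )
            manifest["n_differential_relaxed"] = len(relaxed)

    subgroup = None
    if config.run_stratify:
        with _stage("stratify"):
            model = sqrt_pareto_pca(averaged)
            write_table(
                model.scores_frame().reset_index(names="sample_id"),
                out / "pca_scores.tsv",
            )
            write_table(
                model.loadings_frame().reset_index(names="protein_id"),
                out / "pca_loadings.tsv",
            )
            write_table(
                pd.DataFrame(
                    {
                        "component": [f"PC{i+1}" for i in range(model.n_components)],
                        "explained_pct": model.explained_pct,
                    }
                ),
                out / "pca_explained.tsv",
            )
            subgroup = select_subgroup(model, samples)
            status = [
                (s, "core" if s in subgroup.core_case_ids else "excluded")
                for s in subgroup.core_case_ids + subgroup.excluded_case_ids
            ]
            write_table(
                pd.DataFrame(status, columns=["sample_id", "status"]),
                out / "subgroup.tsv",
            )
            manifest["pc1_explained_pct"] = round(float(model.explained_pct[0]), 4)
            manifest["pc2_explained_pct"] = (
                round(float(model.explained_pct[1]), 4)
                if model.n_components > 1
                else ""
            )
            manifest["subgroup_core"] = ",".join(subgroup.core_case_ids)
            manifest["subgroup_excluded"] = ",".join(subgroup.excluded_case_ids)
            manifest["subgroup_stable"] = subgroup.stable

        if config.run_differential:
            with _stage("differential_subgroup"):
                keep = list(subgroup.core_case_ids) + [
                    s
                    for s, g in zip(samples["sample_id"], samples["group"])
                    if g == "control"
                ]
                sub_matrix = averaged.__class__(
                    averaged.data[[c for c in averaged.data.columns if c in keep]],
                    "averaged",
                )
                sub_records = t_test_protein(sub_matrix, samples)
                sub_primary = apply_filter(sub_records, config.primary_filter())
                write_table(
                    format_report(sub_primary), out / "differential_subgroup_primary.tsv"
                )
                manifest["n_differential_subgroup_primary"] = len(sub_primary)

    if config.run_classify:
        with _stage("classify"):
            result = pc_logistic_loocv(
                averaged, samples, config.k_components, config.pca_policy
            )
            write_table(result.per_sample, out / "classifier_probabilities.tsv")
            manifest["loocv_error_count"] = result.error_count
            manifest["loocv_n_samples"] = len(result.per_sample)

        if config.run_permutation:
            with _stage("permutation"):
                perm = permutation_test(
                    averaged,
                    samples,
                    config.k_components,
                    result,
                    n_permutations=config.n_permutations,
                    seed=config.seed,
                )
                write_table(
                    pd.DataFrame({"null_error": perm.null_errors}),
                    out / "permutation_null.tsv",
                )
                manifest["permutation_method"] = perm.method
                manifest["permutation_n"] = perm.n_permutations
                manifest["permutation_p_value"] = round(perm.p_value, 6)

    if config.run_subset:
        with _stage("subset"):
            if config.annotations_path:
                annotations = read_table(config.annotations_path)
                flag = config.subset_flag or [
                    c for c in annotations.columns if c != "protein_id"
                ][0]
            elif truth is not None:
                flag = config.subset_flag or "planted"
                annotations = planted_annotation(truth, flag)
            else:
                raise ConfigurationError(
                    "run_subset requires annotations_path (or a simulated cohort)"
                )
            sres = run_subset_test(
                averaged,
                samples,
                annotations,
                flag,
                k_components=config.k_components,
                n_draws=config.subset_n_draws,
                seed=config.seed,
                pca_policy=config.pca_policy,
            )
            write_table(
                pd.DataFrame(
                    {
                        "random_error": sres.random_errors,
                        "random_log_loss": sres.random_log_losses,
                    }
                ),
                out / "subset_null.tsv",
            )
            manifest["subset_flag"] = sres.flag_name
            manifest["subset_size"] = sres.subset_size
            manifest["subset_error"] = sres.subset_error
            manifest["subset_empirical_p"] = round(sres.empirical_p, 6)

    write_key_value(manifest, out / "manifest.txt")
    return manifest
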