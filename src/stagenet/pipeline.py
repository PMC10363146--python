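"""End-to-end orchestration: config, run log, reports and summary.json.

The pipeline runs read/simulate -> per-group coexpression profiles ->
phase transitions + cross-cohort similarity -> stage-consistent and
cross-cohort common genes -> diagnostic/prognostic screen -> acquired-gene
DE summaries -> hub methylation comparisons, writing TSV reports per stage
plus a machine-readable ``summary.json`` and a ``run.log`` that records
every silent analysis decision (missing-value policy, quartile basis,
constant-gene exclusions).  Identical config + seed reproduces
``summary.json`` byte for byte.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field

import yaml

from . import coexpression, consistency_prognosis, methylation_analysis
from . import network_dynamics, synthetic_cohort
from .errors import ConfigError, StagenetError
from .io_firehose import (GeneId, annotate_samples, read_clinical,
                          read_expression, read_methylation)

logger = logging.getLogger("stagenet")


@dataclass
class RunConfig:
    """One reproducible run: either Firehose-style input paths per cohort or
    a synthetic scenario, plus thresholds and the seed."""

    mode: str = "synth"  # 'synth' | 'paths'
    hub: str = "MYC"
    rs_min: float = coexpression.RS_MIN_DEFAULT
    p_max: float = coexpression.P_MAX_DEFAULT
    alpha: float = consistency_prognosis.ALPHA_DEFAULT
    seed: int = 0
    samples_per_group: int = 100
    coexpr_strength: float = 0.95
    # mode 'paths': cohort -> {'expression': ..., 'methylation': ..., 'clinical': ...}
    cohorts: dict = field(default_factory=dict)
    missing_policy: str = "drop_gene"

    def validate(self) -> None:
        if self.mode not in ("synth", "paths"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "paths" and not self.cohorts:
            raise ConfigError("mode 'paths' needs cohort file paths")
        if self.mode == "synth" and self.cohorts:
            raise ConfigError("give either synth mode or cohort paths, not both")
        if not 0.0 <= self.rs_min <= 1.0:
            raise ConfigError("rs_min must be in [0, 1]")
        for name, v in (("p_max", self.p_max), ("alpha", self.alpha)):
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class PipelineStageError(StagenetError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full analysis; returns the summary dict (also written to
    ``<outdir>/summary.json``)."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir) -> dict:
    logger.info("decisions: missing_policy=%s; quartile basis = tumour samples "
                "with usable survival; boundary ties excluded from both arms; "
                "multiple tumour samples per patient kept; stage sub-letters "
                "collapsed; duplicate gene rows keep larger total",
                config.missing_policy)
    data = _load_cohorts(config, outdir)

    profiles = {}
    for cohort, (expr, meth, ann) in data.items():
        profiles[cohort] = _profile_cohort(config, outdir, cohort, expr, ann)

    summary: dict = {
        "config": {
            "mode": config.mode, "hub": config.hub, "rs_min": config.rs_min,
            "p_max": config.p_max, "alpha": config.alpha, "seed": config.seed,
        },
        "counts": _counts(profiles),
        "transitions": {},
        "consistency": {},
        "de_acquired_stage1": {},
        "methylation_hub": {},
    }

    series = {}
    for cohort, profile in profiles.items():
        series[cohort] = _dynamics(outdir, cohort, profile)
        summary["transitions"][cohort] = [
            network_dynamics.summary_dict(s) for s in series[cohort]]

    if len(profiles) >= 2:
        matrix = _cross_cohort(outdir, profiles)
        summary["cross_cohort_jaccard_pct"] = {
            r: {c: int(matrix.loc[r, c]) for c in matrix.columns}
            for r in matrix.index}

    consistency = _consistency(outdir, profiles)
    summary["consistency"] = {
        cohort: {"n_consistent": len(res.consistent),
                 "genes": sorted(g.render() for g in res.consistent)}
        for cohort, res in consistency.items()}

    common: frozenset = frozenset()
    if len(consistency) >= 2:
        common = consistency_prognosis.cross_cohort_consistent(consistency)
        consistency_prognosis.write_gene_list(
            common, os.path.join(outdir, "common_consistent.genes.txt"))
        summary["common_consistent"] = sorted(g.render() for g in common)

    summary["screen"] = _screen(config, outdir, data, common)

    for cohort, (expr, meth, ann) in data.items():
        summary["de_acquired_stage1"][cohort] = _de_acquired(
            config, expr, ann, cohort, series.get(cohort, []), profiles[cohort])
        summary["methylation_hub"][cohort] = _methylation(
            config, outdir, cohort, meth, ann)

    path = os.path.join(outdir, "summary.json")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("summary written to %s", path)
    return summary


@_stage("load")
def _load_cohorts(config: RunConfig, outdir) -> dict:
    data = {}
    if config.mode == "synth":
        scenario = synthetic_cohort.default_scenario(
            seed=config.seed, samples_per_group=config.samples_per_group,
            coexpr_strength=config.coexpr_strength)
        for cohort, synth_cfg in scenario.items():
            sc = synthetic_cohort.generate(synth_cfg)
            data[cohort] = (sc.expression, sc.methylation, sc.annotations)
            logger.info("simulated cohort %s: %d genes x %d samples", cohort,
                        *sc.expression.shape)
    else:
        for cohort, paths in config.cohorts.items():
            expr = read_expression(paths["expression"], config.missing_policy)
            meth = (read_methylation(paths["methylation"], config.missing_policy)
                    if paths.get("methylation") else None)
            clinical = read_clinical(paths["clinical"], cohort=cohort)
            ann = annotate_samples(expr.samples, clinical, cohort)
            data[cohort] = (expr, meth, ann)
            logger.info("loaded cohort %s: %d genes x %d samples", cohort,
                        *expr.shape)
    return data


@_stage("coexpression")
def _profile_cohort(config, outdir, cohort, expr, ann):
    profile = coexpression.stage_profile(expr, ann, cohort, config.hub,
                                         rs_min=config.rs_min, p_max=config.p_max)
    cdir = os.path.join(outdir, cohort)
    os.makedirs(cdir, exist_ok=True)
    for group, table in profile.items():
        coexpression.write_table(table, os.path.join(cdir, f"{group}.coexpression.tsv"))
        with open(os.path.join(cdir, f"{group}.coexpressed.txt"), "w",
                  encoding="utf-8") as fh:
            for g in sorted(table.gene_set):
                fh.write(g.render() + "\n")
    return profile


def _counts(profiles) -> dict:
    frame = coexpression.counts_table(profiles)
    return {cohort: {g: int(frame.loc[cohort, g]) for g in frame.columns}
            for cohort in frame.index}


@_stage("dynamics")
def _dynamics(outdir, cohort, profile):
    series = network_dynamics.phase_series(profile)
    network_dynamics.write_transitions(
        series, os.path.join(outdir, cohort, "transitions.tsv"))
    return series


@_stage("cross_cohort")
def _cross_cohort(outdir, profiles):
    matrix = network_dynamics.cross_cohort_matrix(profiles, basis="group")
    matrix.to_csv(os.path.join(outdir, "cross_cohort_jaccard.tsv"), sep="\t")
    return matrix


@_stage("consistency")
def _consistency(outdir, profiles) -> dict:
    out = {}
    for cohort, profile in profiles.items():
        missing = [s for s in consistency_prognosis.TUMOUR_STAGES
                   if s not in profile]
        if missing:
            logger.warning("%s: consistency skipped, missing %s", cohort, missing)
            continue
        res = consistency_prognosis.consistent_genes(profile, cohort)
        consistency_prognosis.write_gene_list(
            res.consistent, os.path.join(outdir, cohort, "consistent.genes.txt"))
        out[cohort] = res
    return out


@_stage("screen")
def _screen(config, outdir, data, candidates) -> dict:
    report = {}
    for cohort, (expr, _meth, ann) in data.items():
        results = [consistency_prognosis.screen_gene(expr, ann, cohort, g,
                                                     alpha=config.alpha)
                   for g in sorted(candidates)]
        consistency_prognosis.write_screen_report(
            results, os.path.join(outdir, cohort, "screen.tsv"))
        report[cohort] = {
            "n_candidates": len(results),
            "n_passing": sum(r.passes for r in results),
            "passing": sorted(r.gene.render() for r in results if r.passes),
        }
    return report


@_stage("de_acquired")
def _de_acquired(config, expr, ann, cohort, series, profile) -> dict:
    for summ in series:
        if (summ.from_group, summ.to_group) == ("N", "S1"):
            # keys in the summary are gene_key tuples; map back to GeneIds
            acquired_genes = [g for g in profile["S1"].gene_set
                              if network_dynamics._keyed([g]) <= summ.acquired]
            return consistency_prognosis.de_summary(
                expr, ann, cohort, acquired_genes, alpha=config.alpha)
    return {"n_de": 0, "n_total": 0, "pct_de": 0.0}


@_stage("methylation")
def _methylation(config, outdir, cohort, meth, ann) -> dict:
    if meth is None:
        return {}
    comparisons = methylation_analysis.stagewise_comparisons(
        meth, ann, cohort, config.hub)
    methylation_analysis.write_comparisons(
        comparisons, os.path.join(outdir, cohort, "methylation_hub.tsv"))
    return {f"{c.pair[0]}/{c.pair[1]}": {
                "median_a": round(c.medians[0], 6),
                "median_b": round(c.medians[1], 6),
                "p": float(f"{c.test.p_value:.6g}"),
                "significant": c.significant}
            for c in comparisons}
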