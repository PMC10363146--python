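"""Synthetic stage-labelled cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes in a Firehose-style cohort: samples labelled normal / stage I-IV, a
designated hub gene, per-group planted modules whose members track a latent
hub signal, tumour-vs-normal expression shifts on chosen genes, beta-value
promoter methylation with group-specific means, and exponential overall
survival whose hazard depends on the top-quartile expression of a designated
prognostic gene, with independent right-censoring.

Construction of planted coexpression: within each group the hub follows a
standard-normal latent signal h; a planted gene is ``a*h + (1-a)*eps`` with
loading ``a = coexpr_strength``, then mapped through exp() to a non-negative
RSEM-like scale.  Spearman correlation is invariant to that monotone map, so
the planted rank correlation is controlled by ``a`` alone.  Non-planted
genes are independent noise.  One global seed expands into independent
substreams for expression, methylation and survival, so changing the gene
count never perturbs the survival draws.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit, logit

from .errors import ConfigError
from .io_firehose import (GROUPS, ExpressionMatrix, GeneId, MethylationMatrix,
                          SampleAnnotation, write_annotations, write_expression)
from .network_dynamics import TransitionSummary, transition

TUMOUR_GROUPS = ("S1", "S2", "S3", "S4")

#: Firehose-dialect stage strings written to clinical.tsv (S2 carries a
#: sub-letter on purpose, to exercise stage collapsing on re-read).
_STAGE_STRINGS = {"S1": "Stage I", "S2": "Stage IIA", "S3": "Stage III",
                  "S4": "Stage IV"}


@dataclass
class SynthConfig:
    """Ground-truth parameters of one synthetic cohort.

    Gene indices refer to positions in the generated gene list; index 0 is
    the hub and may not appear in any planted set.  ``coexpr_strength`` is
    the latent-factor loading ``a`` in ``a*h + (1-a)*eps``.
    ``tumour_log_shift`` is added on the log scale to ``de_genes`` in tumour
    groups.  ``hazard_ratio_high`` multiplies the exponential death hazard
    for samples in the top expression quartile of ``prognostic_gene``.
    """

    n_genes: int = 1200
    samples_per_group: dict = field(
        default_factory=lambda: {g: 100 for g in GROUPS})
    hub_name: str = "MYC"
    hub_entrez: int = 4609
    planted_sets: dict = field(default_factory=dict)  # group -> set of gene idx
    coexpr_strength: float = 0.95
    de_genes: frozenset = frozenset()
    tumour_log_shift: float = 1.0
    meth_means: dict = field(
        default_factory=lambda: {"N": 0.6, "S1": 0.3, "S2": 0.3,
                                 "S3": 0.3, "S4": 0.3})
    meth_logit_sd: float = 0.5
    prognostic_gene: int = 1
    hazard_ratio_high: float = 3.0
    baseline_hazard: float = 1.0 / 1500.0  # deaths per day
    censor_rate: float = 0.2
    cohort: str = "SYNTH"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ConfigError("need at least 2 genes (hub + 1)")
        for g, n in self.samples_per_group.items():
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}")
            if n and n < 4:
                raise ConfigError(f"group {g}: {n} samples < 4")
        for g, idxs in self.planted_sets.items():
            if g not in GROUPS:
                raise ConfigError(f"planted set for unknown group {g!r}")
            idxs = set(idxs)
            if 0 in idxs:
                raise ConfigError("hub (index 0) cannot be planted")
            if idxs and (min(idxs) < 0 or max(idxs) >= self.n_genes):
                raise ConfigError(f"planted indices for {g} out of range")
        if not 0.0 <= self.coexpr_strength < 1.0:
            raise ConfigError("coexpr_strength must be in [0, 1)")
        if self.hazard_ratio_high <= 0:
            raise ConfigError("hazard_ratio_high must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate must be in [0, 1)")
        for g, m in self.meth_means.items():
            if not 0.0 < m < 1.0:
                raise ConfigError(f"meth_means[{g}] must be in (0, 1)")
        if not 0 <= self.prognostic_gene < self.n_genes:
            raise ConfigError("prognostic_gene out of range")


@dataclass
class SynthCohort:
    """A generated cohort with its embedded ground truth."""

    expression: ExpressionMatrix
    methylation: MethylationMatrix
    annotations: list
    truth: SynthConfig


def _gene_list(config: SynthConfig) -> list[GeneId]:
    genes = [GeneId(symbol=config.hub_name, entrez=config.hub_entrez)]
    genes += [GeneId(symbol=f"G{i:04d}", entrez=100000 + i)
              for i in range(1, config.n_genes)]
    return genes


def gene_ids_for(config: SynthConfig, indices) -> frozenset:
    """GeneIds corresponding to planted gene indices."""
    genes = _gene_list(config)
    return frozenset(genes[i] for i in indices)


def generate(config: SynthConfig) -> SynthCohort:
    """Generate a cohort; bit-identical for identical config + seed."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_expr, ss_meth, ss_surv = root.spawn(3)
    rng_e = np.random.default_rng(ss_expr)
    rng_m = np.random.default_rng(ss_meth)
    rng_s = np.random.default_rng(ss_surv)

    genes = _gene_list(config)
    a = config.coexpr_strength
    tag = _cohort_tag(config.cohort)

    barcodes: list[str] = []
    groups_of: list[str] = []
    expr_cols: list[np.ndarray] = []
    meth_cols: list[np.ndarray] = []
    pid = 0
    for group in GROUPS:
        n = int(config.samples_per_group.get(group, 0))
        if n == 0:
            continue
        h = rng_e.standard_normal(n)
        x = rng_e.standard_normal((config.n_genes, n))
        x[0] = h
        for i in config.planted_sets.get(group, ()):
            x[i] = a * h + (1.0 - a) * x[i]
        if group in TUMOUR_GROUPS and config.de_genes:
            x[list(config.de_genes)] += config.tumour_log_shift
        expr_cols.append(np.exp(6.0 + x))  # RSEM-like positive scale

        mu = logit(config.meth_means.get(group, 0.5))
        z = rng_m.standard_normal((config.n_genes, n))
        meth_cols.append(expit(mu + config.meth_logit_sd * z))

        suffix = "11A" if group == "N" else "01A"
        gtag = "NN" if group == "N" else group
        for _ in range(n):
            barcodes.append(f"{tag}-{gtag}-{pid:04d}-{suffix}")
            groups_of.append(group)
            pid += 1

    values = np.concatenate(expr_cols, axis=1)
    meth_values = np.concatenate(meth_cols, axis=1)
    expression = ExpressionMatrix(genes=genes, samples=list(barcodes), values=values)
    methylation = MethylationMatrix(genes=genes, samples=list(barcodes),
                                    values=meth_values)

    annotations = _survival_annotations(config, expression, barcodes,
                                        groups_of, rng_s)
    return SynthCohort(expression=expression, methylation=methylation,
                       annotations=annotations, truth=config)


def _cohort_tag(cohort: str) -> str:
    tag = "".join(c for c in cohort.upper() if c.isalnum())[:4]
    return (tag or "SYNT").ljust(4, "X")


def _survival_annotations(config, expression, barcodes, groups_of, rng):
    tumour_idx = [j for j, g in enumerate(groups_of) if g != "N"]
    prog = expression.values[config.prognostic_gene, tumour_idx]
    q75 = np.percentile(prog, 75) if tumour_idx else np.inf
    annotations = []
    for j, (bc, group) in enumerate(zip(barcodes, groups_of)):
        if group == "N":
            annotations.append(SampleAnnotation(
                barcode=bc, cohort=config.cohort, tissue="normal", stage="N"))
            continue
        high = expression.values[config.prognostic_gene, j] > q75
        hazard = config.baseline_hazard * (config.hazard_ratio_high if high else 1.0)
        t_event = rng.exponential(1.0 / hazard)
        censored = rng.random() < config.censor_rate
        if censored:
            time, event = rng.uniform(0.0, t_event), False
        else:
            time, event = t_event, True
        time = float(max(1.0, round(time)))  # whole days, survives file round-trip
        annotations.append(SampleAnnotation(
            barcode=bc, cohort=config.cohort, tissue="tumour", stage=group,
            time_days=time, event=event))
    return annotations


def planted_truth(config: SynthConfig, pair: tuple) -> TransitionSummary:
    """Exact lost/conserved/acquired sets implied by the planted modules."""
    g1, g2 = pair
    for g in (g1, g2):
        if g not in GROUPS or not config.samples_per_group.get(g, 0):
            raise ConfigError(f"group {g!r} not configured")
    a = gene_ids_for(config, config.planted_sets.get(g1, ()))
    b = gene_ids_for(config, config.planted_sets.get(g2, ()))
    return transition(a, b, g1, g2)


# ---------------------------------------------------------------------------
# Bundled two-cohort scenario
# ---------------------------------------------------------------------------

_CORE = frozenset({1, 2, 3, 4})  # planted in every tumour stage of every cohort


def default_scenario(seed: int = 0, samples_per_group: int = 100,
                     coexpr_strength: float = 0.95) -> dict:
    """Two synthetic cohorts with a shared 4-gene persistent core.

    Each cohort plants sliding 100-gene modules per stage (core + 96 stage
    genes, consecutive stages overlapping by 46 + core), so the per-cohort
    all-stage intersection is exactly the core and consecutive-phase overlap
    structure is non-trivial.  The normal-group module is disjoint from all
    tumour modules.  Core gene 1 is both differentially expressed and the
    prognostic gene.
    """
    def windows(start):
        return {
            "N": set(range(start - 200, start - 20)),
            "S1": set(_CORE) | set(range(start, start + 96)),
            "S2": set(_CORE) | set(range(start + 50, start + 146)),
            "S3": set(_CORE) | set(range(start + 100, start + 196)),
            "S4": set(_CORE) | set(range(start + 150, start + 246)),
        }

    spg = {g: samples_per_group for g in GROUPS}
    common = dict(
        n_genes=1200, samples_per_group=spg, coexpr_strength=coexpr_strength,
        de_genes=frozenset(_CORE) | frozenset(range(600, 610)),
        tumour_log_shift=1.0, prognostic_gene=1, hazard_ratio_high=3.0,
        censor_rate=0.2,
    )
    return {
        "SYNTH-A": SynthConfig(cohort="SYNTH-A", planted_sets=windows(300),
                               seed=(seed * 1000003 + 1) % 2**31, **common),
        "SYNTH-B": SynthConfig(cohort="SYNTH-B", planted_sets=windows(700),
                               seed=(seed * 1000003 + 2) % 2**31, **common),
    }


def null_config(seed: int = 0, samples_per_group: int = 100,
                n_genes: int = 1200) -> SynthConfig:
    """A cohort with no planted structure: no modules, no DE shift, no
    hazard link (used to bound false-positive rates)."""
    return SynthConfig(
        n_genes=n_genes, samples_per_group={g: samples_per_group for g in GROUPS},
        planted_sets={}, coexpr_strength=0.0, de_genes=frozenset(),
        tumour_log_shift=0.0, hazard_ratio_high=1.0, censor_rate=0.2,
        cohort="SYNTH-NULL", seed=seed)


# ---------------------------------------------------------------------------
# File output in the Firehose dialect
# ---------------------------------------------------------------------------

def write_cohort(cohort: SynthCohort, outdir) -> None:
    """Write expression.tsv / methylation.tsv / clinical.tsv (+ truth.json,
    annotations.tsv) in the dialect the readers accept."""
    os.makedirs(outdir, exist_ok=True)
    write_expression(cohort.expression, os.path.join(outdir, "expression.tsv"),
                     tag="normalized_count")
    write_expression(cohort.methylation, os.path.join(outdir, "methylation.tsv"),
                     tag="Beta_value")
    _write_clinical(cohort.annotations, os.path.join(outdir, "clinical.tsv"))
    write_annotations(cohort.annotations, os.path.join(outdir, "annotations.tsv"))
    truth = asdict(cohort.truth)
    truth["planted_sets"] = {g: sorted(s) for g, s in truth["planted_sets"].items()}
    truth["de_genes"] = sorted(truth["de_genes"])
    with open(os.path.join(outdir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _write_clinical(annotations, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("bcr_patient_barcode\tpathologic_stage\tvital_status\t"
                 "days_to_death\tdays_to_last_followup\n")
        for a in annotations:
            if a.tissue != "tumour":
                continue
            patient = "-".join(a.barcode.split("-")[:3])
            stage = _STAGE_STRINGS.get(a.stage, "[Not Available]")
            vital = "dead" if a.event else "alive"
            t = "NA" if math.isnan(a.time_days) else f"{a.time_days:g}"
            death = t if a.event else "NA"
            fup = "NA" if a.event else t
            fh.write(f"{patient}\t{stage}\t{vital}\t{death}\t{fup}\n")
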