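"""Stage-consistent gene extraction and the diagnostic/prognostic screen.

A gene is *consistent* in a cohort when it appears in the hub coexpression
set of every tumour stage S1-S4 (the normal group is excluded from the
intersection); genes consistent in every cohort form the *common* set.
Candidates are then screened on two axes: diagnostic -- Mann-Whitney of
pooled tumour vs normal expression requiring tumour-higher significance --
and prognostic -- a log-rank test between the top-quartile (>75th
percentile) and bottom-quartile (<25th percentile) expression arms requiring
significantly worse survival in the high arm.  A gene passes only when both
arms reject at the screening alpha in the stated directions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_firehose import (ExpressionMatrix, GeneId, SampleAnnotation,
                          gene_key)
from .network_dynamics import trunc2
from .stats_core import KMCurve, TestResult, km_fit, logrank, mann_whitney

logger = logging.getLogger("stagenet")

TUMOUR_STAGES = ("S1", "S2", "S3", "S4")

ALPHA_DEFAULT = 0.05


@dataclass
class ConsistencyResult:
    """Per-cohort stage-consistent genes (and, when filled, the cross-cohort
    common subset)."""

    cohort: str
    consistent: frozenset  # of GeneId
    common_consistent: frozenset = frozenset()


def consistent_genes(profile: dict, cohort: str = "") -> ConsistencyResult:
    """Intersection of the S1..S4 coexpression sets of one cohort.

    All four tumour stages must be present; a missing stage raises with its
    name.  The result is independent of intersection order.
    """
    missing = [s for s in TUMOUR_STAGES if s not in profile]
    if missing:
        raise ValueError(f"cannot compute consistency: missing stage(s) "
                         f"{', '.join(missing)}")
    sets = [frozenset(getattr(profile[s], "gene_set", profile[s]))
            for s in TUMOUR_STAGES]
    consistent = frozenset.intersection(*sets)
    return ConsistencyResult(cohort=cohort or getattr(profile["S1"], "cohort", ""),
                             consistent=consistent)


def cross_cohort_consistent(results: dict) -> frozenset:
    """Genes consistent in every cohort, matched by Entrez ID with symbol
    fallback.  Returns GeneIds drawn from the first cohort's set."""
    if len(results) < 2:
        raise ValueError("need >= 2 cohorts")
    keyed = [{gene_key(g): g for g in r.consistent} for r in results.values()]
    common_keys = set(keyed[0])
    for k in keyed[1:]:
        common_keys &= set(k)
    return frozenset(keyed[0][k] for k in common_keys)


# ---------------------------------------------------------------------------
# Quartile split
# ---------------------------------------------------------------------------

def quartile_split(barcodes: list[str], values) -> tuple[set, set]:
    """Split samples into high (> 75th percentile) and low (< 25th
    percentile) expression arms.

    Percentiles use linear interpolation; boundary ties are excluded from
    both arms (strict inequalities), so the arms never overlap.  The middle
    half is discarded.
    """
    values = np.asarray(values, dtype=float)
    if values.size != len(barcodes):
        raise ValueError("barcodes and values differ in length")
    if values.size < 8:
        raise ValueError(f"quartile split needs >= 8 samples, got {values.size}")
    q25, q75 = np.percentile(values, [25, 75])
    high = {b for b, v in zip(barcodes, values) if v > q75}
    low = {b for b, v in zip(barcodes, values) if v < q25}
    return high, low


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Diagnostic + prognostic screen outcome for one candidate gene.

    ``passes`` is True iff the gene is significantly tumour-overexpressed
    AND the high-expression arm has significantly worse survival."""

    gene: GeneId
    diag_p: float = math.nan
    diag_direction: str = "none"  # 'tumour_higher' | 'normal_higher' | 'none'
    km_high: KMCurve | None = None
    km_low: KMCurve | None = None
    logrank_p: float = math.nan
    worse_group: str = "none"  # 'high' | 'low' | 'none'
    passes: bool = False
    reason: str = ""


def screen_gene(expr: ExpressionMatrix, ann: list[SampleAnnotation],
                cohort: str, gene, alpha: float = ALPHA_DEFAULT,
                per_stage: bool = False) -> ScreenResult:
    """Run the two-arm screen for one gene in one cohort.

    The diagnostic arm pools all tumour stages against normals by default;
    ``per_stage=True`` instead tests every stage separately against normal
    and reports the least favourable (largest) p, so all four stages must
    individually show tumour-higher significance.  Prognostic quartiles are
    computed over tumour samples with usable survival only (the split
    exists to feed the survival comparison).  Unscreenable genes come back
    with ``passes=False`` and a reason code instead of raising.
    """
    idx = expr.find_gene(gene)
    gid = expr.genes[idx]
    coh = [a for a in ann if a.cohort == cohort]
    tumour = [a for a in coh if a.tissue == "tumour"]
    normal = [a for a in coh if a.tissue == "normal"]
    result = ScreenResult(gene=gid)
    if not tumour or not normal:
        result.reason = "missing_tissue_class"
        return result

    row = expr.values[idx]
    nvals = row[expr.sample_columns([a.barcode for a in normal])]
    try:
        if per_stage:
            diag = None
            for stage in TUMOUR_STAGES:
                sb = [a.barcode for a in tumour if a.stage == stage]
                if len(sb) < 4:
                    continue
                res = mann_whitney(row[expr.sample_columns(sb)], nvals)
                if diag is None or res.p_value > diag.p_value or \
                        res.direction != "group1_higher":
                    diag = res
                    if res.direction != "group1_higher":
                        break
            if diag is None:
                result.reason = "diagnostic_test_failed"
                return result
        else:
            tvals = row[expr.sample_columns([a.barcode for a in tumour])]
            diag = mann_whitney(tvals, nvals)
    except ValueError:
        result.reason = "diagnostic_test_failed"
        return result
    result.diag_p = diag.p_value
    result.diag_direction = {"group1_higher": "tumour_higher",
                             "group2_higher": "normal_higher",
                             "none": "none"}[diag.direction]

    surv = [a for a in tumour if a.survival_usable]
    if len(surv) < 8:
        result.reason = "insufficient_survival_data"
        return result
    svals = row[expr.sample_columns([a.barcode for a in surv])]
    try:
        high_bc, low_bc = quartile_split([a.barcode for a in surv], svals)
    except ValueError:
        result.reason = "quartile_split_failed"
        return result
    if len(high_bc) < 2 or len(low_bc) < 2:
        result.reason = "degenerate_quartiles"
        return result
    by_bc = {a.barcode: a for a in surv}
    th = [(by_bc[b].time_days, by_bc[b].event) for b in sorted(high_bc)]
    tl = [(by_bc[b].time_days, by_bc[b].event) for b in sorted(low_bc)]
    t_h, e_h = zip(*th)
    t_l, e_l = zip(*tl)
    lr = logrank(t_h, e_h, t_l, e_l)
    result.km_high = km_fit(t_h, e_h)
    result.km_low = km_fit(t_l, e_l)
    result.logrank_p = lr.p_value
    result.worse_group = {"group1_higher": "high", "group2_higher": "low",
                          "none": "none"}[lr.direction]
    result.passes = (result.diag_p < alpha
                     and result.diag_direction == "tumour_higher"
                     and result.logrank_p < alpha
                     and result.worse_group == "high")
    if not result.passes and not result.reason:
        result.reason = "below_threshold"
    return result


# ---------------------------------------------------------------------------
# Percent-DE reporting
# ---------------------------------------------------------------------------

def percent_de(de_count: int, total: int) -> float:
    """Percentage of differentially expressed genes, truncated at 2
    decimals (the convention matching published cohort reports)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= de_count <= total:
        raise ValueError("de_count must be in [0, total]")
    return trunc2(100.0 * de_count / total)


def de_summary(expr: ExpressionMatrix, ann: list[SampleAnnotation],
               cohort: str, genes, alpha: float = ALPHA_DEFAULT,
               stage: str | None = None) -> dict:
    """Fraction of *genes* significantly overexpressed in tumour vs normal
    samples (the acquired-gene DE report).

    The tumour side pools all stages by default; pass ``stage`` (e.g.
    ``"S1"``) to restrict the comparison to one stage vs normal.
    """
    coh = [a for a in ann if a.cohort == cohort]
    t_bc = [a.barcode for a in coh if a.tissue == "tumour"
            and (stage is None or a.stage == stage)]
    n_bc = [a.barcode for a in coh if a.tissue == "normal"]
    t_cols = expr.sample_columns(t_bc)
    n_cols = expr.sample_columns(n_bc)
    de = 0
    total = 0
    for gene in genes:
        try:
            idx = expr.find_gene(gene)
        except KeyError:
            continue
        total += 1
        res = mann_whitney(expr.values[idx, t_cols], expr.values[idx, n_cols])
        if res.p_value < alpha and res.direction == "group1_higher":
            de += 1
    return {"n_de": de, "n_total": total,
            "pct_de": percent_de(de, total) if total else 0.0}


def write_screen_report(results: list[ScreenResult], path) -> None:
    """Screen report TSV in fixed column order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tdiag_p\tdiag_direction\tlogrank_p\tworse_group\t"
                 "passes\treason\n")
        for r in sorted(results, key=lambda r: (r.gene.symbol, r.gene.entrez)):
            fh.write(f"{r.gene.render()}\t{r.diag_p:.6g}\t{r.diag_direction}\t"
                     f"{r.logrank_p:.6g}\t{r.worse_group}\t{int(r.passes)}\t"
                     f"{r.reason}\n")


def write_gene_list(genes, path) -> None:
    """One-ID-per-line gene list (Entrez where known), suitable as input to
    external enrichment tools."""
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes, key=gene_key):
            fh.write((str(g.entrez) if g.entrez > 0 else g.symbol) + "\n")
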