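"""Per-group extraction of genes coexpressed with the hub gene.

Within each (cohort, group) sample block every non-hub, non-constant gene is
rank-correlated with the hub; the coexpressed set is the strict threshold
``rs in (rs_min, 1] and p < p_max`` with the published defaults rs_min = 0.3
and p_max = 0.05.  Only positive correlations qualify by default (the
threshold window is one-sided); ``use_abs=True`` switches to |rs|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .io_firehose import (GROUPS, ExpressionMatrix, GeneId, SampleAnnotation,
                          group_barcodes)
from .stats_core import CorrelationResult, spearman_against_rows

logger = logging.getLogger("stagenet")

RS_MIN_DEFAULT = 0.3
P_MAX_DEFAULT = 0.05


@dataclass
class CoexpressionTable:
    """Hub correlation results for one (cohort, group) block.

    ``entries`` holds rs/p for every testable gene; ``gene_set`` is the
    thresholded subset.  ``n_constant`` counts genes excluded as constant
    within the group (Spearman undefined), logged per run.
    """

    cohort: str
    group: str
    hub: GeneId
    entries: dict = field(default_factory=dict)  # GeneId -> CorrelationResult
    gene_set: frozenset = frozenset()
    n_constant: int = 0
    n_samples: int = 0


def coexpressed_set(expr: ExpressionMatrix, ann: list[SampleAnnotation],
                    cohort: str, group: str, hub,
                    rs_min: float = RS_MIN_DEFAULT,
                    p_max: float = P_MAX_DEFAULT,
                    use_abs: bool = False) -> CoexpressionTable:
    """Genes significantly coexpressed with *hub* in one sample group.

    Strict inequalities at both thresholds: rs must exceed *rs_min* (and
    stay <= 1) and p must be below *p_max*; with ``rs_min=1.0`` the set is
    therefore empty.  Raw p-values are used -- the screen applies no
    multiple-testing correction.
    """
    if not 0.0 <= rs_min < 1.0 and rs_min != 1.0:
        raise ValueError(f"rs_min must be in [0, 1], got {rs_min}")
    hub_idx = expr.find_gene(hub)  # KeyError if absent
    hub_gene = expr.genes[hub_idx]
    barcodes = group_barcodes(ann, cohort, group)
    if len(barcodes) < 4:
        raise ValueError(
            f"group {group} of cohort {cohort} has {len(barcodes)} samples; "
            "need >= 4 for rank correlation")
    cols = expr.sample_columns(barcodes)
    block = expr.values[:, cols]
    hub_vals = block[hub_idx]

    rs, p, constant = spearman_against_rows(hub_vals, block)
    entries: dict[GeneId, CorrelationResult] = {}
    selected = []
    n = len(barcodes)
    for i, gene in enumerate(expr.genes):
        if i == hub_idx or constant[i]:
            continue
        res = CorrelationResult(rs=float(rs[i]), p_value=float(p[i]), n=n)
        entries[gene] = res
        stat = abs(res.rs) if use_abs else res.rs
        if stat > rs_min and stat <= 1.0 and res.p_value < p_max:
            selected.append(gene)
    n_constant = int(constant.sum()) - (1 if constant[hub_idx] else 0)
    if n_constant:
        logger.info("%s/%s: excluded %d constant genes", cohort, group, n_constant)
    return CoexpressionTable(cohort=cohort, group=group, hub=hub_gene,
                             entries=entries, gene_set=frozenset(selected),
                             n_constant=n_constant, n_samples=n)


def stage_profile(expr: ExpressionMatrix, ann: list[SampleAnnotation],
                  cohort: str, hub, rs_min: float = RS_MIN_DEFAULT,
                  p_max: float = P_MAX_DEFAULT,
                  use_abs: bool = False) -> dict:
    """One CoexpressionTable per available group (N, S1-S4).

    Groups with fewer than 4 samples are absent from the result and logged;
    the output is deterministic for fixed input.
    """
    profile: dict[str, CoexpressionTable] = {}
    for group in GROUPS:
        if len(group_barcodes(ann, cohort, group)) < 4:
            logger.warning("%s: group %s missing or too small, skipped", cohort, group)
            continue
        profile[group] = coexpressed_set(expr, ann, cohort, group, hub,
                                         rs_min=rs_min, p_max=p_max, use_abs=use_abs)
    return profile


def counts_table(profiles: dict) -> pd.DataFrame:
    """Coexpressed-gene counts in the groups-by-cohort layout."""
    data = {cohort: {g: (len(profile[g].gene_set) if g in profile else 0)
                     for g in GROUPS}
            for cohort, profile in profiles.items()}
    return pd.DataFrame(data).reindex(list(GROUPS)).T


def write_table(table: CoexpressionTable, path) -> None:
    """Per-group TSV: gene, symbol, entrez, rs, p, in_set flag."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tsymbol\tentrez\trs\tp\tin_set\n")
        for gene in sorted(table.entries, key=lambda g: (g.symbol, g.entrez)):
            res = table.entries[gene]
            fh.write(f"{gene.render()}\t{gene.symbol}\t{gene.entrez}\t"
                     f"{res.rs:.6g}\t{res.p_value:.6g}\t"
                     f"{int(gene in table.gene_set)}\n")
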