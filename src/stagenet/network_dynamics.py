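"""Cross-phase comparison of hub coexpression sets.

A coexpression "network" here is the star of genes passing the hub
correlation threshold within one sample group.  Progression is summarised
over the four consecutive phases N/S1, S1/S2, S2/S3, S3/S4 by classifying
each gene as lost (in A only), conserved (in both) or acquired (in B only)
and by the Jaccard index J(A, B) = |A n B| / |A u B|.

Percentage conventions: loss is relative to the source set A, gain relative
to the destination set B, and conservation relative to the union; all three
are reported truncated at two decimals (the convention that reproduces the
published kidney-cohort figures).  The cross-cohort similarity matrix is
rendered at integer percent with round-half-to-even.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .io_firehose import GROUPS, GeneId, gene_key

logger = logging.getLogger("stagenet")

#: Consecutive phase pairs, in progression order.
PHASES = (("N", "S1"), ("S1", "S2"), ("S2", "S3"), ("S3", "S4"))


def trunc2(x: float) -> float:
    """Truncate a non-negative percentage toward zero at 2 decimals."""
    return math.floor(x * 100.0 + 1e-9) / 100.0


def jaccard_index(a: frozenset, b: frozenset) -> float:
    """|a n b| / |a u b|; 0 when both sets are empty."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


@dataclass(frozen=True)
class TransitionSummary:
    """Lost / conserved / acquired decomposition of one phase transition."""

    from_group: str
    to_group: str
    lost: frozenset
    conserved: frozenset
    acquired: frozenset
    jaccard: float
    pct_lost: float                 # 100 * |lost| / |A|
    pct_acquired: float             # 100 * |acquired| / |B|
    pct_conserved_of_union: float   # 100 * |conserved| / |A u B|

    @property
    def n_from(self) -> int:
        return len(self.lost) + len(self.conserved)

    @property
    def n_to(self) -> int:
        return len(self.conserved) + len(self.acquired)

    @property
    def jaccard_pct(self) -> int:
        """Integer-percent rendering (round-half-to-even)."""
        return round(self.jaccard * 100.0)


def transition(a: frozenset, b: frozenset, from_group: str = "A",
               to_group: str = "B") -> TransitionSummary:
    """Classify genes of consecutive phase sets A -> B.

    lost = A \\ B, conserved = A n B, acquired = B \\ A.  Percentages follow
    the module conventions; empty sides yield 0 for the affected ratios.
    """
    a, b = frozenset(a), frozenset(b)
    lost, conserved, acquired = a - b, a & b, b - a
    union = len(a | b)
    return TransitionSummary(
        from_group=from_group, to_group=to_group,
        lost=lost, conserved=conserved, acquired=acquired,
        jaccard=jaccard_index(a, b),
        pct_lost=trunc2(100.0 * len(lost) / len(a)) if a else 0.0,
        pct_acquired=trunc2(100.0 * len(acquired) / len(b)) if b else 0.0,
        pct_conserved_of_union=trunc2(100.0 * len(conserved) / union) if union else 0.0,
    )


def _keyed(genes) -> frozenset:
    """Gene sets compared by Entrez ID with symbol fallback."""
    return frozenset(gene_key(g) if isinstance(g, GeneId) else g for g in genes)


def phase_series(profile: dict) -> list[TransitionSummary]:
    """Transition summaries for the four consecutive phases.

    *profile* maps group -> CoexpressionTable (or group -> gene set).  Pairs
    with a missing side are skipped with a warning.
    """
    out = []
    for g1, g2 in PHASES:
        if g1 not in profile or g2 not in profile:
            logger.warning("phase %s/%s skipped: group missing", g1, g2)
            continue
        out.append(transition(_genes_of(profile[g1]), _genes_of(profile[g2]), g1, g2))
    return out


def _genes_of(table) -> frozenset:
    gene_set = getattr(table, "gene_set", table)
    return _keyed(gene_set)


def cross_cohort_matrix(profiles: dict, basis: str = "group") -> pd.DataFrame:
    """Pairwise Jaccard percentage matrix across cohorts.

    ``basis='group'`` compares the per-group coexpression sets; and
    ``basis='conserved'`` compares the conserved set of each consecutive
    phase (the cross-tissue network-similarity view).  Rows/columns are
    labelled ``cohort:key``; values are integer percents (round-half-even)
    and the matrix is symmetric by construction.
    """
    if len(profiles) < 2:
        raise ValueError("cross_cohort_matrix needs at least 2 cohorts")
    sets: dict[str, frozenset] = {}
    for cohort, profile in profiles.items():
        if basis == "group":
            for group in GROUPS:
                if group in profile:
                    sets[f"{cohort}:{group}"] = _genes_of(profile[group])
        elif basis == "conserved":
            for summ in phase_series(profile):
                sets[f"{cohort}:{summ.from_group}/{summ.to_group}"] = summ.conserved
        else:
            raise ValueError(f"unknown basis {basis!r}")
    labels = list(sets)
    data = [[round(100.0 * jaccard_index(sets[r], sets[c])) for c in labels]
            for r in labels]
    return pd.DataFrame(data, index=labels, columns=labels, dtype=int)


def write_transitions(summaries: list[TransitionSummary], path) -> None:
    """TSV transition report in the fixed column order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("phase\tn_from\tn_to\tn_lost\tn_conserved\tn_acquired\t"
                 "pct_lost\tpct_acquired\tjaccard_pct\n")
        for s in summaries:
            fh.write(f"{s.from_group}/{s.to_group}\t{s.n_from}\t{s.n_to}\t"
                     f"{len(s.lost)}\t{len(s.conserved)}\t{len(s.acquired)}\t"
                     f"{s.pct_lost:.2f}\t{s.pct_acquired:.2f}\t{s.jaccard_pct}\n")


def summary_dict(s: TransitionSummary) -> dict:
    """JSON-ready view of a transition (counts and percentages only)."""
    return {
        "phase": f"{s.from_group}/{s.to_group}",
        "n_from": s.n_from, "n_to": s.n_to,
        "n_lost": len(s.lost), "n_conserved": len(s.conserved),
        "n_acquired": len(s.acquired),
        "pct_lost": s.pct_lost, "pct_acquired": s.pct_acquired,
        "pct_conserved_of_union": s.pct_conserved_of_union,
        "jaccard": round(s.jaccard, 6), "jaccard_pct": s.jaccard_pct,
    }
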