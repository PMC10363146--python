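"""Stage-wise comparison of promoter methylation beta-values.

Mirrors the expression comparisons: for a gene and an ordered pair of
sample groups, a two-sided Mann-Whitney U test on the beta-values plus the
two group medians, significant at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_firehose import (GeneId, MethylationMatrix, SampleAnnotation,
                          group_barcodes)
from .stats_core import TestResult, mann_whitney

ALPHA_DEFAULT = 0.05


@dataclass
class MethylationComparison:
    gene: GeneId
    pair: tuple  # (group_a, group_b)
    test: TestResult
    medians: tuple  # (median_a, median_b), beta-values in [0, 1]

    @property
    def significant(self) -> bool:
        return self.test.p_value < ALPHA_DEFAULT


def compare_methylation(meth: MethylationMatrix, ann: list[SampleAnnotation],
                        cohort: str, gene, pair: tuple) -> MethylationComparison:
    """Mann-Whitney comparison of a gene's beta-values between two groups.

    Both groups need >= 4 samples in the cohort; beta-values outside [0, 1]
    raise :class:`ValidationError` (they indicate a malformed matrix).
    """
    idx = meth.find_gene(gene)
    gid = meth.genes[idx]
    row = meth.values[idx]
    vals = []
    for group in pair:
        bcs = group_barcodes(ann, cohort, group)
        if len(bcs) < 4:
            raise ValueError(f"group {group} of {cohort} has {len(bcs)} "
                             "samples; need >= 4")
        v = row[meth.sample_columns(bcs)]
        v = v[np.isfinite(v)]
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValidationError(f"beta-values outside [0, 1] for {gid.render()}")
        if v.size < 4:
            raise ValueError(f"group {group}: fewer than 4 finite beta-values")
        vals.append(v)
    test = mann_whitney(vals[0], vals[1])
    medians = (float(np.median(vals[0])), float(np.median(vals[1])))
    return MethylationComparison(gene=gid, pair=tuple(pair), test=test,
                                 medians=medians)


def stagewise_comparisons(meth, ann, cohort, gene,
                          pairs=(("N", "S1"), ("N", "S2"), ("N", "S3"),
                                 ("N", "S4"))) -> list[MethylationComparison]:
    """Run :func:`compare_methylation` over a list of group pairs, skipping
    pairs whose groups are absent or too small."""
    out = []
    for pair in pairs:
        try:
            out.append(compare_methylation(meth, ann, cohort, gene, pair))
        except ValueError:
            continue
    return out


def write_comparisons(comparisons: list[MethylationComparison], path) -> None:
    """Comparison report TSV: gene, pair, medians, p, significance."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tgroup_a\tgroup_b\tmedian_a\tmedian_b\tp\tsignificant\n")
        for c in comparisons:
            fh.write(f"{c.gene.render()}\t{c.pair[0]}\t{c.pair[1]}\t"
                     f"{c.medians[0]:.6g}\t{c.medians[1]:.6g}\t"
                     f"{c.test.p_value:.6g}\t{int(c.significant)}\n")
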