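"""Readers and writers for Firehose-style Level-3 TSV files.

Broad GDAC Firehose distributes TCGA Level-3 data as tab-separated matrices
whose first column carries ``SYMBOL|ENTREZ`` gene keys and whose second
header row (when present) repeats a per-column datatype tag such as
``normalized_count``.  Clinical "Pick Tier 1" exports carry the pathologic
stage and the overall-survival fields per patient.  This module parses those
dialects into the pipeline's in-memory data model, classifies TCGA barcodes
into tissue classes, and normalizes pathologic-stage strings.

Conventions adopted here (the files themselves do not state them):

* tumour/normal is decided by the barcode sample-type code (01-09 tumour,
  10-19 normal, 20-29 control and rejected) -- the only information in a
  Firehose file that distinguishes the two;
* stage sub-letters (IA, IB, ...) collapse to the parent stage;
* clinical rows are keyed by the 12-character patient prefix and a patient's
  stage annotates all of their tumour samples;
* duplicate gene rows keep the row with the larger total expression, ties
  broken by file order.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger("stagenet")

#: Sample groups, in progression order.
GROUPS = ("N", "S1", "S2", "S3", "S4")

#: TCGA renal cohort labels the pipeline knows about; synthetic cohorts use
#: free-form ``SYNTH*`` labels.
KNOWN_COHORTS = ("KIPAN", "KIRC", "KICH", "KIRP", "SYNTH")


# ---------------------------------------------------------------------------
# Gene identifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GeneId:
    """A gene identified by HGNC symbol and Entrez ID.

    ``entrez == 0`` means the Entrez ID is unknown; an empty symbol with a
    positive Entrez ID corresponds to Firehose's ``?|ENTREZ`` rows.  Equality
    and hashing use both fields; cross-set comparisons prefer the Entrez ID
    (see :func:`gene_key`).
    """

    symbol: str
    entrez: int = 0

    def __post_init__(self) -> None:
        if not self.symbol and self.entrez <= 0:
            raise ValidationError("GeneId needs a symbol or a positive Entrez ID")
        if self.entrez < 0:
            raise ValidationError(f"negative Entrez ID: {self.entrez}")

    @classmethod
    def parse(cls, key: str) -> "GeneId":
        """Parse a ``SYMBOL|ENTREZ`` row key; ``?`` symbols become empty."""
        key = key.strip()
        if "|" in key:
            sym, _, ent = key.partition("|")
            sym = "" if sym == "?" else sym
            try:
                entrez = int(ent)
            except ValueError as exc:
                raise FormatError(f"unparseable gene key {key!r}") from exc
            return cls(symbol=sym, entrez=entrez)
        return cls(symbol=key, entrez=0)

    def render(self) -> str:
        """Render back to the Firehose ``SYMBOL|ENTREZ`` form."""
        return f"{self.symbol or '?'}|{self.entrez}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def gene_key(gene: GeneId):
    """Comparison key used when intersecting gene sets across cohorts:
    Entrez ID when known, symbol otherwise."""
    return ("E", gene.entrez) if gene.entrez > 0 else ("S", gene.symbol)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Dense genes-by-samples matrix of RSEM-normalized expression values."""

    genes: list[GeneId]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample barcodes")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._symbol_index = {g.symbol: i for i, g in enumerate(self.genes) if g.symbol}
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def find_gene(self, gene: "GeneId | str") -> int:
        """Row index of *gene* (GeneId, symbol, or ``SYMBOL|ENTREZ`` key)."""
        if isinstance(gene, GeneId):
            if gene in self._gene_index:
                return self._gene_index[gene]
            if gene.symbol in self._symbol_index:
                return self._symbol_index[gene.symbol]
            raise KeyError(f"gene {gene.render()} not in matrix")
        if gene in self._symbol_index:
            return self._symbol_index[gene]
        return self.find_gene(GeneId.parse(gene))

    def row(self, gene: "GeneId | str") -> np.ndarray:
        return self.values[self.find_gene(gene)]

    def sample_columns(self, barcodes) -> np.ndarray:
        return np.array([self._sample_index[b] for b in barcodes], dtype=int)

    def subset_samples(self, barcodes: list[str]) -> "ExpressionMatrix":
        cols = self.sample_columns(barcodes)
        return replace(self, samples=list(barcodes), values=self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=[g.render() for g in self.genes], columns=self.samples
        )


@dataclass
class MethylationMatrix(ExpressionMatrix):
    """Genes-by-samples matrix of promoter methylation beta-values in [0, 1].

    The Firehose ``Meth.by_min_expr_corr`` preprocess already collapses each
    gene to the probe whose methylation is most anti-correlated with
    expression, so one row per gene is taken at face value.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValidationError("beta-values outside [0, 1]")


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------

@dataclass
class SampleAnnotation:
    """Per-sample cohort, tissue class, stage, and overall-survival fields.

    ``time_days`` is NaN and ``survival_usable`` False when both clinical
    time fields were missing; such samples still participate in expression
    grouping.
    """

    barcode: str
    cohort: str
    tissue: str  # 'normal' | 'tumour'
    stage: str  # one of GROUPS or 'unknown'
    time_days: float = math.nan
    event: bool = False

    def __post_init__(self) -> None:
        if self.tissue not in ("normal", "tumour"):
            raise ValidationError(f"bad tissue class {self.tissue!r}")
        if self.tissue == "normal" and self.stage != "N":
            raise ValidationError("normal tissue must have stage N")
        if self.tissue == "tumour" and self.stage not in ("S1", "S2", "S3", "S4", "unknown"):
            raise ValidationError(f"bad tumour stage {self.stage!r}")
        if not math.isnan(self.time_days) and self.time_days < 0:
            raise ValidationError("negative survival time")

    @property
    def survival_usable(self) -> bool:
        return not math.isnan(self.time_days)

    @property
    def group(self) -> str:
        """The analysis group this sample belongs to (N or its stage)."""
        return "N" if self.tissue == "normal" else self.stage


# ---------------------------------------------------------------------------
# Barcode handling
# ---------------------------------------------------------------------------

def classify_barcode(barcode: str) -> str:
    """Classify a TCGA-style barcode into ``'tumour'`` or ``'normal'``.

    The fourth dash-delimited field starts with the two-digit sample-type
    code: 01-09 tumour, 10-19 normal.  Control codes (20-29) and anything
    unparseable raise :class:`ValidationError`.  Synthetic barcodes follow
    the same positional convention.
    """
    fields = barcode.strip().split("-")
    if len(fields) < 4 or len(fields[3]) < 2 or not fields[3][:2].isdigit():
        raise ValidationError(f"unparseable barcode {barcode!r}")
    code = int(fields[3][:2])
    if 1 <= code <= 9:
        return "tumour"
    if 10 <= code <= 19:
        return "normal"
    if 20 <= code <= 29:
        raise ValidationError(f"control sample code {code:02d} in {barcode!r}")
    raise ValidationError(f"unknown sample-type code {code:02d} in {barcode!r}")


def patient_of(barcode: str) -> str:
    """The patient prefix (first three dash fields) of a sample barcode."""
    return "-".join(barcode.strip().split("-")[:3]).upper()


# ---------------------------------------------------------------------------
# Stage normalization
# ---------------------------------------------------------------------------

_STAGE_RE = re.compile(r"^\s*stage\s+(iv|iii|ii|i)\s*[abc]?\s*$", re.IGNORECASE)
_STAGE_MAP = {"i": "S1", "ii": "S2", "iii": "S3", "iv": "S4"}


def normalize_stage(value: str) -> str:
    """Map a pathologic-stage string to S1-S4; anything else -> 'unknown'.

    Sub-letters (``stage iia``) collapse to the parent stage; already
    normalized codes pass through, so the mapping is idempotent.
    """
    if value is None:
        return "unknown"
    value = str(value).strip()
    if value in ("S1", "S2", "S3", "S4", "N", "unknown"):
        return value
    m = _STAGE_RE.match(value)
    if m:
        return _STAGE_MAP[m.group(1).lower()]
    return "unknown"


# ---------------------------------------------------------------------------
# Expression / methylation readers and writers
# ---------------------------------------------------------------------------

def _read_matrix_frame(path, missing_policy: str) -> tuple[list[GeneId], list[str], np.ndarray]:
    if missing_policy not in ("drop_gene", "impute_zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 2 or any(c == "" for c in cols[1:]):
            raise FormatError(f"{path}: malformed header on line 1")
        barcodes = cols[1:]
        if len(set(barcodes)) != len(barcodes):
            raise ValidationError(f"{path}: duplicate sample barcodes in header")
        pos = fh.tell()
        second = fh.readline().rstrip("\n").split("\t")
        # Firehose dialect: an optional second header row repeating a
        # datatype tag (e.g. 'normalized_count') under every data column.
        tag_row = (
            len(second) == len(cols)
            and len(set(second[1:])) == 1
            and not _is_number(second[1])
        )
        if not tag_row:
            fh.seek(pos)
        frame = pd.read_csv(
            fh, sep="\t", header=None, index_col=0, na_values=["NA", "null", ""],
            names=["gene"] + barcodes, float_precision="round_trip",
        )
    if frame.shape[1] != len(barcodes):
        raise FormatError(f"{path}: ragged data rows")
    genes = [GeneId.parse(str(k)) for k in frame.index]
    values = frame.to_numpy(dtype=float)

    # de-duplicate gene rows: keep the row with the larger total expression,
    # ties broken by file order
    if len(set(genes)) != len(genes):
        best: dict[GeneId, int] = {}
        totals = np.nansum(values, axis=1)
        for i, g in enumerate(genes):
            if g not in best or totals[i] > totals[best[g]]:
                best[g] = i
        keep = sorted(best.values())
        logger.info("dropped %d duplicate gene rows (kept larger total)",
                    len(genes) - len(keep))
        genes = [genes[i] for i in keep]
        values = values[keep]

    if missing_policy == "impute_zero":
        values = np.nan_to_num(values, nan=0.0)
    else:  # drop_gene
        ok = ~np.isnan(values).any(axis=1)
        if not ok.all():
            logger.info("dropped %d genes with missing values", int((~ok).sum()))
        genes = [g for g, k in zip(genes, ok) if k]
        values = values[ok]
    return genes, barcodes, values


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_expression(path, missing_policy: str = "drop_gene") -> ExpressionMatrix:
    """Read a Firehose RSEM-normalized expression TSV.

    The optional datatype-tag row is stripped; ``NA`` cells are resolved per
    *missing_policy* (``drop_gene`` removes the gene, ``impute_zero`` fills
    zeros).
    """
    genes, samples, values = _read_matrix_frame(path, missing_policy)
    if np.nanmin(values) < 0 if values.size else False:
        raise ValidationError(f"{path}: negative expression values")
    return ExpressionMatrix(genes=genes, samples=samples, values=values)


def read_methylation(path, missing_policy: str = "drop_gene") -> MethylationMatrix:
    """Read a Firehose methylation-preprocess TSV of beta-values."""
    genes, samples, values = _read_matrix_frame(path, missing_policy)
    return MethylationMatrix(genes=genes, samples=samples, values=values)


def write_expression(matrix: ExpressionMatrix, path, tag: str | None = None) -> None:
    """Write a matrix back as TSV with ``SYMBOL|ENTREZ`` keys.

    When *tag* is given a Firehose-style datatype row is emitted after the
    header.  Values round-trip bit-exactly (``repr`` precision).
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Hybridization REF\t" + "\t".join(matrix.samples) + "\n")
        if tag is not None:
            fh.write("gene_id\t" + "\t".join([tag] * len(matrix.samples)) + "\n")
        for gene, row in zip(matrix.genes, matrix.values):
            cells = "\t".join("NA" if np.isnan(v) else repr(float(v)) for v in row)
            fh.write(f"{gene.render()}\t{cells}\n")


# ---------------------------------------------------------------------------
# Clinical reader / annotation join
# ---------------------------------------------------------------------------

_DEATH_WORDS = {"dead", "deceased", "1"}

_CLINICAL_ALIASES = {
    "pathologic_stage": ("pathologic_stage", "pathologic stage", "ajcc_pathologic_tumor_stage"),
    "vital_status": ("vital_status", "vital status"),
    "days_to_death": ("days_to_death", "days to death"),
    "days_to_last_followup": ("days_to_last_followup", "days_to_last_follow_up",
                              "days to last followup"),
    "barcode": ("bcr_patient_barcode", "patient_barcode", "barcode", "patient"),
}


def _pick(colmap: dict[str, str], logical: str) -> str | None:
    for alias in _CLINICAL_ALIASES[logical]:
        if alias in colmap:
            return colmap[alias]
    return None


def read_clinical(path, cohort: str = "SYNTH") -> list[SampleAnnotation]:
    """Read a Clinical Pick Tier 1 style TSV into patient annotations.

    Each row is one patient; ``time_days`` is days_to_death for observed
    deaths and days_to_last_followup otherwise, falling back to whichever
    field is present.  Patients with neither field keep NaN time and are
    flagged unusable for survival while remaining usable for grouping.
    The returned annotations carry patient barcodes with tissue 'tumour'
    (stage unknown where unparseable); join them onto sample barcodes with
    :func:`annotate_samples`.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", "null", ""])
    colmap = {c.strip().lower(): c for c in frame.columns}
    bar_col = _pick(colmap, "barcode") or frame.columns[0]
    stage_col = _pick(colmap, "pathologic_stage")
    vital_col = _pick(colmap, "vital_status")
    death_col = _pick(colmap, "days_to_death")
    fup_col = _pick(colmap, "days_to_last_followup")
    if stage_col is None:
        raise FormatError(f"{path}: no pathologic stage column")

    out: list[SampleAnnotation] = []
    for _, row in frame.iterrows():
        stage = normalize_stage(row.get(stage_col))
        vital = str(row.get(vital_col, "")).strip().lower() if vital_col else ""
        event = vital in _DEATH_WORDS
        death = _float_or_nan(row.get(death_col)) if death_col else math.nan
        fup = _float_or_nan(row.get(fup_col)) if fup_col else math.nan
        time = death if event else fup
        if math.isnan(time):
            time = fup if event else death  # fall back to the other field
        if not math.isnan(time) and time < 0:
            time = math.nan
        out.append(SampleAnnotation(
            barcode=str(row[bar_col]).strip().upper(), cohort=cohort,
            tissue="tumour", stage=stage, time_days=time, event=event,
        ))
    return out


def _float_or_nan(value) -> float:
    try:
        v = float(value)
        return v if math.isfinite(v) else math.nan
    except (TypeError, ValueError):
        return math.nan


def annotate_samples(barcodes: list[str], clinical: list[SampleAnnotation],
                     cohort: str) -> list[SampleAnnotation]:
    """Join patient-level clinical annotations onto sample barcodes.

    Tissue comes from the barcode sample-type code; a patient's stage and
    survival annotate all of their tumour samples.  Normal samples get stage
    N and no survival semantics.  Control barcodes are dropped with a
    warning.
    """
    by_patient = {patient_of(a.barcode): a for a in clinical}
    out: list[SampleAnnotation] = []
    for bc in barcodes:
        try:
            tissue = classify_barcode(bc)
        except ValidationError as exc:
            logger.warning("skipping sample %s: %s", bc, exc)
            continue
        clin = by_patient.get(patient_of(bc))
        if tissue == "normal":
            out.append(SampleAnnotation(barcode=bc, cohort=cohort,
                                        tissue="normal", stage="N"))
        else:
            stage = clin.stage if clin is not None else "unknown"
            time = clin.time_days if clin is not None else math.nan
            event = clin.event if clin is not None else False
            out.append(SampleAnnotation(barcode=bc, cohort=cohort, tissue="tumour",
                                        stage=stage, time_days=time, event=event))
    return out


def group_barcodes(annotations: list[SampleAnnotation], cohort: str,
                   group: str) -> list[str]:
    """Barcodes of *cohort* samples belonging to analysis *group*."""
    return [a.barcode for a in annotations if a.cohort == cohort and a.group == group]


def write_annotations(annotations: list[SampleAnnotation], path) -> None:
    """Write annotations as TSV with fixed column order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("barcode\tcohort\ttissue\tstage\ttime_days\tevent\n")
        for a in annotations:
            t = "NA" if math.isnan(a.time_days) else repr(float(a.time_days))
            fh.write(f"{a.barcode}\t{a.cohort}\t{a.tissue}\t{a.stage}\t{t}\t"
                     f"{int(a.event)}\n")
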