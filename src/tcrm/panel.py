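"""Gene panel definition, cohort data model and CSV interchange.

The common rejection module (CRM) is an 11-gene signature of acute allograft
rejection shared across transplanted organs.  This module defines the default
qPCR panel (the 11 target genes, the 18S ribosomal endogenous control and the
Universal-RNA calibrator sample), the long-format CT table and sample-sheet
interchange formats, and the cross-validation of the two into a ``Cohort``.

Interchange formats (both CSV, LF line endings, ``.`` decimal separator,
6 significant digits for floats):

``ct_table.csv``
    ``sample_id,gene,replicate,ct`` — one row per replicate well; ``ct`` is a
    float or ``NA``/``Undetermined`` for wells that never crossed threshold.
``samples.csv``
    ``sample_id,patient_id,phenotype,timepoint_months,split,banff_t,banff_i``
    — blank Banff fields allowed.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CRM_GENES",
    "PIFTA_GENES",
    "REFERENCE_GENE",
    "CALIBRATOR_SAMPLE_ID",
    "GenePanel",
    "Phenotype",
    "Split",
    "Cohort",
    "FormatError",
    "CohortValidationError",
    "default_panel",
    "load_ct_table",
    "write_ct_table",
    "load_sample_sheet",
    "write_sample_sheet",
    "validate_cohort",
]

#: The 11 common-rejection-module target genes, in canonical order.
CRM_GENES: tuple[str, ...] = (
    "BASP1", "CD6", "CXCL10", "CXCL9", "INPP5D", "ISG20",
    "LCK", "NKG7", "PSMB9", "RUNX3", "TAP1",
)

#: The 7-gene subset with the greatest influence on progressive IFTA.
PIFTA_GENES: tuple[str, ...] = (
    "CD6", "INPP5D", "ISG20", "NKG7", "PSMB9", "RUNX3", "TAP1",
)

#: Endogenous (within-sample) control transcript.
REFERENCE_GENE = "18S"

#: Identifier of the between-run calibrator sample (Universal RNA).
CALIBRATOR_SAMPLE_ID = "UNIVERSAL_RNA"

CT_COLUMNS = ("sample_id", "gene", "replicate", "ct")
SAMPLE_COLUMNS = (
    "sample_id", "patient_id", "phenotype", "timepoint_months",
    "split", "banff_t", "banff_i",
)

_MISSING_CT_TOKENS = {"", "NA", "NaN", "nan", "Undetermined", "undetermined"}


class FormatError(ValueError):
    """A file does not conform to the documented interchange format."""


class CohortValidationError(ValueError):
    """Parsed data violate a cohort-level invariant."""


class Phenotype(str, enum.Enum):
    """Biopsy phenotype labels.

    ``AR``
        biopsy-proven acute rejection (Banff grade IA or higher).
    ``NOAR``
        stable allograft, no rejection on histology.
    ``PIFTA_P`` / ``PIFTA_NP``
        paired-protocol-biopsy patients who did (P) / did not (NP) develop
        progressive interstitial fibrosis and tubular atrophy by 24 months.
    """

    AR = "AR"
    NOAR = "NOAR"
    PIFTA_P = "PIFTA_P"
    PIFTA_NP = "PIFTA_NP"


class Split(str, enum.Enum):
    """Cohort partition used for threshold derivation/validation."""

    DISCOVERY = "DISCOVERY"
    VALIDATION = "VALIDATION"
    LONGITUDINAL = "LONGITUDINAL"


@dataclass(frozen=True)
class GenePanel:
    """A qPCR gene panel: target genes, endogenous control, calibrator."""

    target_genes: tuple[str, ...] = CRM_GENES
    reference_gene: str = REFERENCE_GENE
    calibrator_sample_id: str = CALIBRATOR_SAMPLE_ID

    def __post_init__(self) -> None:
        genes = tuple(g.strip() for g in self.target_genes)
        object.__setattr__(self, "target_genes", genes)
        if len(set(genes)) != len(genes):
            raise CohortValidationError("duplicate target genes in panel")
        if self.reference_gene in genes:
            raise CohortValidationError(
                f"reference gene {self.reference_gene!r} cannot be a target"
            )

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.target_genes + (self.reference_gene,)


def default_panel() -> GenePanel:
    """The shipped 11-gene CRM panel with 18S control and Universal RNA."""
    return GenePanel()


@dataclass
class Cohort:
    """A validated join of CT measurements and sample metadata.

    ``incomplete_samples`` lists biopsies missing more than two panel genes
    (all replicate wells undetermined); downstream scoring flags these rather
    than silently computing on a truncated panel.
    """

    ct_table: pd.DataFrame
    samples: pd.DataFrame
    panel: GenePanel
    incomplete_samples: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# CT table I/O
# ---------------------------------------------------------------------------

def _parse_ct(token: str) -> float:
    token = token.strip()
    if token in _MISSING_CT_TOKENS:
        return np.nan
    return float(token)


def load_ct_table(path, panel: GenePanel | None = None) -> pd.DataFrame:
    """Read a long-format CT table, validating genes against ``panel``.

    Returns a DataFrame with columns ``sample_id, gene, replicate, ct``
    (``ct`` is float, NaN for undetermined wells).
    """
    panel = panel or default_panel()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"ct table missing columns: {missing}")
    df = df.loc[:, list(CT_COLUMNS)].copy()
    df["sample_id"] = df["sample_id"].str.strip()
    df["gene"] = df["gene"].str.strip()
    known = set(panel.all_genes)
    unknown = sorted(set(df["gene"]) - known)
    if unknown:
        raise CohortValidationError(
            f"unknown gene symbols (not in panel): {unknown}"
        )
    try:
        df["replicate"] = df["replicate"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer replicate index: {exc}") from exc
    if (df["replicate"] < 1).any():
        raise FormatError("replicate indices must be positive")
    df["ct"] = df["ct"].map(_parse_ct)
    bad = df["ct"].notna() & ~((df["ct"] > 0) & (df["ct"] <= 45))
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise CohortValidationError(
            f"CT values outside (0, 45] at rows {rows}"
        )
    dup = df.duplicated(subset=["sample_id", "gene", "replicate"])
    if dup.any():
        raise CohortValidationError(
            "duplicate (sample_id, gene, replicate) records"
        )
    return df.reset_index(drop=True)


def _format_float(x: float) -> str:
    if pd.isna(x):
        return "NA"
    return format(float(x), ".6g")


def write_ct_table(ct: pd.DataFrame, path) -> None:
    """Write a CT table in canonical form (sorted, fixed float format)."""
    out = ct.sort_values(["sample_id", "gene", "replicate"], kind="mergesort")
    buf = io.StringIO()
    buf.write(",".join(CT_COLUMNS) + "\n")
    for row in out.itertuples(index=False):
        buf.write(
            f"{row.sample_id},{row.gene},{int(row.replicate)},"
            f"{_format_float(row.ct)}\n"
        )
    with open(path, "w", newline="\n") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Sample sheet I/O
# ---------------------------------------------------------------------------

def _parse_banff(token: str, row: int, col: str) -> float:
    token = token.strip()
    if token in _MISSING_CT_TOKENS:
        return np.nan
    value = int(token)
    if not 0 <= value <= 3:
        raise CohortValidationError(
            f"{col} must be in 0..3, got {value} (row {row})"
        )
    return float(value)


def load_sample_sheet(path) -> pd.DataFrame:
    """Read and validate a sample sheet.

    Phenotype/split tokens are validated against their enums; Banff scores
    are parsed as nullable integers in 0..3; timepoints are float months.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    df = df.loc[:, list(SAMPLE_COLUMNS)].copy()
    for col in ("sample_id", "patient_id", "phenotype", "split"):
        df[col] = df[col].str.strip()
    for i, token in df["phenotype"].items():
        if token not in Phenotype.__members__:
            raise CohortValidationError(
                f"unknown phenotype {token!r} at row {i}"
            )
    for i, token in df["split"].items():
        if token not in Split.__members__:
            raise CohortValidationError(f"unknown split {token!r} at row {i}")
    df["timepoint_months"] = df["timepoint_months"].astype(float)
    for col in ("banff_t", "banff_i"):
        df[col] = [
            _parse_banff(tok, i, col) for i, tok in df[col].items()
        ]
        df[col] = df[col].astype("Float64")
    pifta = df["phenotype"].isin((Phenotype.PIFTA_P.value,
                                  Phenotype.PIFTA_NP.value))
    bad_tp = pifta & ~df["timepoint_months"].isin((6.0, 24.0))
    if bad_tp.any():
        ids = df.loc[bad_tp, "sample_id"].tolist()
        raise CohortValidationError(
            f"pIFTA samples must be at 6 or 24 months: {ids}"
        )
    if df["sample_id"].duplicated().any():
        raise CohortValidationError("duplicate sample_id in sample sheet")
    return df.reset_index(drop=True)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    """Write a sample sheet in canonical form."""
    out = samples.sort_values("sample_id", kind="mergesort")
    buf = io.StringIO()
    buf.write(",".join(SAMPLE_COLUMNS) + "\n")
    for row in out.itertuples(index=False):
        banff_t = "" if pd.isna(row.banff_t) else str(int(row.banff_t))
        banff_i = "" if pd.isna(row.banff_i) else str(int(row.banff_i))
        buf.write(
            f"{row.sample_id},{row.patient_id},{row.phenotype},"
            f"{_format_float(row.timepoint_months)},{row.split},"
            f"{banff_t},{banff_i}\n"
        )
    with open(path, "w", newline="\n") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Cohort validation
# ---------------------------------------------------------------------------

def validate_cohort(
    ct_table: pd.DataFrame,
    samples: pd.DataFrame,
    panel: GenePanel | None = None,
) -> Cohort:
    """Cross-check CT data against the sample sheet and panel.

    Hard errors: calibrator absent or incomplete, CT/sample-sheet sample-id
    mismatch.  Soft flags: samples missing more than two panel genes are
    listed in ``Cohort.incomplete_samples``.  Idempotent and side-effect free.
    """
    panel = panel or default_panel()
    cal = panel.calibrator_sample_id
    ct_ids = set(ct_table["sample_id"])
    meta_ids = set(samples["sample_id"])
    if cal not in ct_ids:
        raise CohortValidationError(
            f"calibrator sample {cal!r} absent from CT table"
        )
    cal_genes = set(
        ct_table.loc[
            (ct_table["sample_id"] == cal) & ct_table["ct"].notna(), "gene"
        ]
    )
    missing_cal = sorted(set(panel.all_genes) - cal_genes)
    if missing_cal:
        raise CohortValidationError(
            f"calibrator sample lacks genes: {missing_cal}"
        )
    only_ct = sorted(ct_ids - meta_ids - {cal})
    only_meta = sorted(meta_ids - ct_ids)
    if only_ct or only_meta:
        raise CohortValidationError(
            f"sample mismatch: in CT only {only_ct}, in sheet only {only_meta}"
        )

    # per-sample gene completeness: a gene counts as present if at least one
    # replicate has a numeric CT
    present = (
        ct_table[ct_table["ct"].notna()]
        .groupby("sample_id")["gene"]
        .agg(lambda g: len(set(g) & set(panel.target_genes)))
    )
    incomplete = []
    n_targets = len(panel.target_genes)
    for sid in sorted(meta_ids):
        n_present = int(present.get(sid, 0))
        if n_targets - n_present > 2:
            incomplete.append(sid)
    return Cohort(
        ct_table=ct_table.reset_index(drop=True),
        samples=samples.reset_index(drop=True),
        panel=panel,
        incomplete_samples=incomplete,
    )
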