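"""Comparative-CT (2^-ddCT) relative quantification.

Implements the classic Livak workflow for a panel of target genes measured by
TaqMan qPCR against an endogenous control transcript (18S) and a calibrator
sample (Universal RNA):

    dCT_{s,g}  = CT_{s,g} - CT_{s,ref}
    ddCT_{s,g} = dCT_{s,g} - dCT_{cal,g}
    FC_{s,g}   = 2^-ddCT_{s,g}

Replicate wells are collapsed by the arithmetic mean of CT (CT being the
log-domain measurement); wells that never crossed threshold ("undetermined")
are excluded from the mean and a gene with no determined well is missing,
never imputed to a ceiling cycle.  Amplification efficiency is assumed to be
100% (exact base-2 doubling per cycle); efficiency correction from standard
curves is out of scope.

An alternative ``mode="dct_only"`` skips the calibrator and reports
2^-dCT directly (18S-only normalization), for assays run without a
between-run calibrator sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .panel import Cohort, GenePanel, default_panel

__all__ = [
    "ReplicateSummary",
    "ExpressionMatrix",
    "collapse_replicates",
    "delta_ct",
    "delta_delta_ct",
    "fold_change",
    "build_expression_matrix",
    "write_expression_matrix",
    "load_expression_matrix",
]

#: Replicate CT standard deviation above which a well triplet is flagged.
REPLICATE_SD_FLAG = 0.5


class ReplicateSummary(NamedTuple):
    mean_ct: float  # NaN when all replicates undetermined
    sd: float
    n_used: int
    flagged: bool  # True when replicate SD exceeds REPLICATE_SD_FLAG


def collapse_replicates(cts: Iterable[float]) -> ReplicateSummary:
    """Collapse replicate CT wells for one sample x gene.

    Arithmetic mean of the numeric CTs; undetermined (NaN) wells are dropped.
    All-undetermined yields a missing mean.  Replicate SD (ddof=1) above
    0.5 cycles is flagged as a pipetting/amplification inconsistency.
    """
    values = np.asarray(list(cts), dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return ReplicateSummary(np.nan, np.nan, 0, False)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return ReplicateSummary(mean, sd, int(values.size), sd > REPLICATE_SD_FLAG)


def delta_ct(ct_gene: float, ct_reference: float) -> float:
    """dCT: target CT minus endogenous-control CT within one sample."""
    return ct_gene - ct_reference


def delta_delta_ct(dct_sample: float, dct_calibrator: float) -> float:
    """ddCT: sample dCT minus calibrator dCT for the same gene."""
    return dct_sample - dct_calibrator


def fold_change(ddct):
    """Fold change 2^-ddCT (log2 fold change is -ddCT)."""
    return 2.0 ** (-np.asarray(ddct, dtype=float))


@dataclass
class ExpressionMatrix:
    """Per-sample, per-gene relative expression after the comparative-CT step.

    ``fold_change`` and ``log2_fc`` are samples x genes DataFrames satisfying
    ``fold_change == 2**log2_fc`` wherever not missing; ``missing`` marks
    entries whose replicate wells were all undetermined.  ``flagged_samples``
    lists samples whose 18S control was itself missing (the whole row is
    missing for those).
    """

    fold_change: pd.DataFrame
    log2_fc: pd.DataFrame
    missing: pd.DataFrame
    replicate_flags: pd.DataFrame | None = None
    flagged_samples: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.fold_change.index)

    @property
    def genes(self) -> list[str]:
        return list(self.fold_change.columns)


def _collapsed_ct(ct: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean CT and replicate-flag pivot tables (samples x genes)."""
    grouped = ct.groupby(["sample_id", "gene"])["ct"]
    summary = grouped.apply(lambda s: collapse_replicates(s.values))
    frame = pd.DataFrame(
        summary.tolist(), index=summary.index,
        columns=["mean_ct", "sd", "n_used", "flagged"],
    )
    mean = frame["mean_ct"].unstack("gene")
    flags = frame["flagged"].unstack("gene").fillna(False).astype(bool)
    return mean, flags


def build_expression_matrix(
    cohort: Cohort, mode: str = "calibrated"
) -> ExpressionMatrix:
    """Run the full comparative-CT pipeline over a validated cohort.

    Returns the fold-change matrix over all non-calibrator samples and the
    panel's target genes.  Samples whose 18S reference is missing are fully
    masked and listed in ``flagged_samples``.
    """
    if mode not in ("calibrated", "dct_only"):
        raise ValueError(f"unknown mode {mode!r}")
    panel = cohort.panel
    genes = list(panel.target_genes)
    mean_ct, rep_flags = _collapsed_ct(cohort.ct_table)
    mean_ct = mean_ct.reindex(columns=list(panel.all_genes))

    cal_id = panel.calibrator_sample_id
    sample_ids = [s for s in cohort.samples["sample_id"]]
    body = mean_ct.reindex(index=sample_ids)

    ref = body[panel.reference_gene]
    dct = body[genes].sub(ref, axis=0)
    if mode == "calibrated":
        cal_row = mean_ct.loc[cal_id]
        cal_dct = cal_row[genes] - cal_row[panel.reference_gene]
        ddct = dct.sub(cal_dct, axis=1)
    else:
        ddct = dct
    log2_fc = -ddct
    fc = 2.0 ** log2_fc

    missing = log2_fc.isna()
    flagged_samples = sorted(ref.index[ref.isna()])
    rep_flags = rep_flags.reindex(
        index=sample_ids, columns=genes, fill_value=False
    )
    return ExpressionMatrix(
        fold_change=fc,
        log2_fc=log2_fc,
        missing=missing,
        replicate_flags=rep_flags,
        flagged_samples=flagged_samples,
    )


def write_expression_matrix(expr: ExpressionMatrix, path, log2: bool = False) -> None:
    """Write the wide fold-change (or log2) matrix as CSV."""
    table = expr.log2_fc if log2 else expr.fold_change
    out = table.sort_index()
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.6g", lineterminator="\n")


def load_expression_matrix(path, panel: GenePanel | None = None) -> ExpressionMatrix:
    """Read a wide fold-change matrix written by :func:`write_expression_matrix`."""
    panel = panel or default_panel()
    fc = pd.read_csv(path, index_col="sample_id")
    unknown = sorted(set(fc.columns) - set(panel.target_genes))
    if unknown:
        raise ValueError(f"unknown genes in expression matrix: {unknown}")
    with np.errstate(divide="ignore"):
        log2_fc = np.log2(fc)
    return ExpressionMatrix(
        fold_change=fc, log2_fc=log2_fc, missing=fc.isna()
    )
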