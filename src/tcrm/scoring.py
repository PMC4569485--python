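"""tCRM score: geometric mean of fold changes over a gene subset.

The tissue common rejection module score for a biopsy is the geometric mean
of its per-gene fold changes:

    tCRM = exp( mean_g ln FC_g ) = 2^( mean_g log2 FC_g )

computed over the 11-gene panel or a stated subset (e.g. the 7-gene
progressive-IFTA set).  The score is unweighted, strictly positive,
permutation-invariant over genes and scale-equivariant (multiplying every
fold change by k multiplies the score by k).

Missing-gene policy: when a sample is missing panel genes, the score is
computed over the available genes provided at least 80% of the subset is
present (>= 9/11, >= 6/7); otherwise the score is undefined and flagged —
partial geometric means over fewer genes are biased, so the gap is surfaced
rather than papered over.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .panel import CRM_GENES

__all__ = ["MIN_SUBSET_FRACTION", "tcrm_score", "score_cohort", "write_scores"]

#: Minimum fraction of the requested subset that must be measured.
MIN_SUBSET_FRACTION = 0.8


def tcrm_score(
    fold_changes: Mapping[str, float] | pd.Series,
    subset: Sequence[str] = CRM_GENES,
) -> tuple[float, int]:
    """Geometric-mean score of ``fold_changes`` over ``subset``.

    Returns ``(score, n_genes_used)``; the score is NaN when fewer than
    80% of the subset genes carry a (positive) fold change.
    """
    if len(subset) == 0:
        raise ValueError("empty gene subset")
    fc = pd.Series(fold_changes, dtype=float).reindex(list(subset))
    used = fc.dropna()
    if (used <= 0).any():
        bad = sorted(used.index[used <= 0])
        raise ValueError(f"non-positive fold changes for genes {bad}")
    n_used = int(used.size)
    if n_used < int(np.ceil(MIN_SUBSET_FRACTION * len(subset))):
        return float("nan"), n_used
    return float(np.exp(np.mean(np.log(used.values)))), n_used


def score_cohort(
    expr: ExpressionMatrix,
    subset: Sequence[str] = CRM_GENES,
    subset_name: str = "tcrm11",
) -> pd.DataFrame:
    """Score every sample of an expression matrix over ``subset``.

    Returns a table with columns ``sample_id, subset_name, tcrm,
    n_genes_used, defined``; samples failing the 80% gene-availability
    policy carry ``defined=False`` and a NaN score.
    """
    unknown = sorted(set(subset) - set(expr.genes))
    if unknown:
        raise ValueError(f"subset genes absent from matrix: {unknown}")
    rows = []
    for sid, fc_row in expr.fold_change.iterrows():
        score, n_used = tcrm_score(fc_row, subset)
        rows.append(
            {
                "sample_id": sid,
                "subset_name": subset_name,
                "tcrm": score,
                "n_genes_used": n_used,
                "defined": bool(np.isfinite(score)),
            }
        )
    return pd.DataFrame(rows)


def write_scores(scores: pd.DataFrame, path) -> None:
    """Write a score table (canonical ordering, 6 significant digits)."""
    out = scores.sort_values(["subset_name", "sample_id"], kind="mergesort")
    out.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
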