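"""Shared fixtures: one default synthetic cohort run end-to-end."""

import pandas as pd
import pytest

import tcrm
from tcrm.expression import build_expression_matrix
from tcrm.panel import default_panel, validate_cohort
from tcrm.scoring import score_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Validated default synthetic cohort (146 biopsies + calibrator)."""
    ct, samples = tcrm.generate(tcrm.default_config())
    return validate_cohort(ct, samples, default_panel())


@pytest.fixture(scope="session")
def default_expression(default_cohort):
    return build_expression_matrix(default_cohort)


@pytest.fixture(scope="session")
def default_scores(default_cohort, default_expression):
    """11-gene score table joined with sample metadata."""
    scores = score_cohort(default_expression)
    return scores.merge(default_cohort.samples, on="sample_id")


def run_scored_cohort(seed):
    """Generate, express and score one cohort; returns (samples, expr, merged)."""
    cfg = tcrm.default_config()
    cfg.seed = seed
    ct, samples = tcrm.generate(cfg)
    cohort = validate_cohort(ct, samples, default_panel())
    expr = build_expression_matrix(cohort)
    merged = score_cohort(expr).merge(samples, on="sample_id")
    sub = score_cohort(expr, tcrm.PIFTA_GENES, "pifta7").merge(
        samples, on="sample_id"
    )
    return samples, expr, merged, sub
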