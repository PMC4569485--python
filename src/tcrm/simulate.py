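"""Synthetic qPCR cohort generator.

Emulates the study design behind the tCRM assay: 146 kidney allograft
biopsies from 122 patients — 54 acute-rejection (AR) and 44 stable (no-AR)
cross-sectional biopsies randomly split into a discovery set (27 AR + 22
no-AR) and a validation set of the same shape, plus 24 patients with paired
6- and 24-month protocol biopsies of whom 12 progressed to interstitial
fibrosis / tubular atrophy (pIFTA progressors, P) and 12 did not (NP).

Generative model (per biopsy i, gene g, all on the log2 fold-change scale):

    log2FC_{i,g} = mu_g(cell) + beta_g * z_i + eps_{i,g}

with a standard-normal latent severity z_i inducing cross-gene correlation,
independent N(0, sigma_g^2) gene noise, and per-cell mean vectors mu_g
calibrated in closed form so that the *measured* geometric-mean score
(including qPCR replicate noise picked up through the ddCT chain) has
exactly the printed group mean:  log2 of the G-gene score is
N(mu_bar, v) with

    v = beta_bar^2 + sum_g sigma_g^2 / G^2
        + (ct_noise_sd^2 / n_replicates) * (2 + 2/G)

so E[score] = 2^(mu_bar + ln2 * v / 2) and mu_bar = log2(T) - ln2 * v / 2
for a target mean T.  Group dispersions are deliberately NOT calibrated to
the printed SEMs — matching means, SEMs and classification metrics jointly
would over-constrain this simple family.

Per-cell mean structure:

* cross-sectional: flat no-AR baseline; AR adds a nonnegative per-gene
  excess distributed by ``ar_effect_share`` (CXCL9/CXCL10 largest).
* longitudinal: a common baseline gene profile (NP cells) plus, for
  progressors, an excess distributed by ``pifta_effect_share`` (CD6 largest;
  the 7 pIFTA genes >> CXCL9, LCK; BASP1 and CXCL10 nil).  The baseline
  profile carries a zero-mean offset solved so the 7-gene sub-score of the
  6-month progressor cell also matches its printed mean.

CT synthesis: CT_ref,i ~ N(12, 0.3^2); CT_{i,g} = CT_ref,i + dCT_cal,g -
log2FC_{i,g}; every replicate well adds N(0, ct_noise_sd^2).  The
calibrator sample's per-gene dCT constants are arbitrary plausible values —
pipeline outputs are invariant to them.  Banff t/i grades for AR biopsies
are quartile-discretizations of ``a * z_i + noise`` (missing for protocol
biopsies).  All randomness flows from the explicit config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .panel import (
    CALIBRATOR_SAMPLE_ID,
    CRM_GENES,
    PIFTA_GENES,
    REFERENCE_GENE,
    Phenotype,
    Split,
    write_ct_table,
    write_sample_sheet,
)

__all__ = [
    "GROUP_SCORE_TARGETS",
    "SUBSCORE_TARGET_P6",
    "SyntheticCohortConfig",
    "default_config",
    "calibrate_group_mean",
    "generate",
    "simulate_to_dir",
    "load_config",
    "save_config",
]

#: Printed group means of the 11-gene score the generator is calibrated to.
GROUP_SCORE_TARGETS: dict[str, float] = {
    "AR": 6.897,       # AR discovery arm (n=27)
    "NOAR": 0.8144,    # no-AR discovery arm (n=22)
    "P6": 3.33,        # pIFTA progressors at 6 months
    "NP6": 1.22,       # non-progressors at 6 months
    "P24": 7.94,       # progressors at 24 months
    "NP24": 2.28,      # non-progressors at 24 months
}

#: Printed mean of the 7-gene sub-score in 6-month progressor biopsies.
SUBSCORE_TARGET_P6 = 3.29

#: Fixed, arbitrary calibrator dCT (gene CT minus 18S CT in Universal RNA).
#: Immune transcripts sit 10-14 cycles above the rRNA control.
_CALIBRATOR_DCT: dict[str, float] = {
    "BASP1": 11.2, "CD6": 13.4, "CXCL10": 12.1, "CXCL9": 12.8,
    "INPP5D": 12.3, "ISG20": 11.7, "LCK": 13.1, "NKG7": 12.6,
    "PSMB9": 10.9, "RUNX3": 12.9, "TAP1": 11.4,
}

_AR_EFFECT_SHARE: dict[str, float] = {
    "BASP1": 1.0, "CD6": 1.0, "CXCL10": 3.0, "CXCL9": 3.0,
    "INPP5D": 1.0, "ISG20": 1.0, "LCK": 1.0, "NKG7": 1.0,
    "PSMB9": 1.0, "RUNX3": 1.0, "TAP1": 1.0,
}

_PIFTA_EFFECT_SHARE: dict[str, float] = {
    "CD6": 3.0, "INPP5D": 2.0, "ISG20": 2.0, "NKG7": 2.0,
    "PSMB9": 2.0, "RUNX3": 2.0, "TAP1": 2.0,
    "CXCL9": 0.5, "LCK": 0.5, "BASP1": 0.0, "CXCL10": 0.0,
}

_LN2 = float(np.log(2.0))


@dataclass
class SyntheticCohortConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 20150914
    n_ar_discovery: int = 27
    n_noar_discovery: int = 22
    n_ar_validation: int = 27
    n_noar_validation: int = 22
    n_progressors: int = 12
    n_nonprogressors: int = 12
    target_scores: dict[str, float] = field(
        default_factory=lambda: dict(GROUP_SCORE_TARGETS))
    subscore_target_p6: float = SUBSCORE_TARGET_P6
    ar_effect_share: dict[str, float] = field(
        default_factory=lambda: dict(_AR_EFFECT_SHARE))
    pifta_effect_share: dict[str, float] = field(
        default_factory=lambda: dict(_PIFTA_EFFECT_SHARE))
    residual_sd: dict[str, float] = field(
        default_factory=lambda: {g: 0.6 for g in CRM_GENES})
    latent_loading: float = 0.35
    #: latent loading in the paired protocol arm (histologically normal
    #: biopsies carry a weaker shared patient-level severity factor than
    #: biopsies taken during an acute event)
    latent_loading_longitudinal: float = 0.3
    banff_coupling: float = 1.0
    banff_noise_sd_t: float = 0.35
    banff_noise_sd_i: float = 0.28
    ct_replicates: int = 3
    ct_noise_sd: float = 0.15
    reference_ct_mean: float = 12.0
    reference_ct_sd: float = 0.3
    calibrator_dct: dict[str, float] = field(
        default_factory=lambda: dict(_CALIBRATOR_DCT))
    ar_timepoint_mean: float = 34.0
    ar_timepoint_sd: float = 31.6
    noar_timepoint_mean: float = 14.0
    noar_timepoint_sd: float = 9.2

    def __post_init__(self) -> None:
        counts = (
            self.n_ar_discovery, self.n_noar_discovery,
            self.n_ar_validation, self.n_noar_validation,
            self.n_progressors, self.n_nonprogressors,
            self.ct_replicates,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all cohort counts must be positive")
        sds = [self.ct_noise_sd, self.reference_ct_sd,
               *self.residual_sd.values()]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be nonnegative")

    @property
    def n_samples(self) -> int:
        return (self.n_ar_discovery + self.n_noar_discovery
                + self.n_ar_validation + self.n_noar_validation
                + 2 * (self.n_progressors + self.n_nonprogressors))

    @property
    def n_patients(self) -> int:
        return (self.n_ar_discovery + self.n_noar_discovery
                + self.n_ar_validation + self.n_noar_validation
                + self.n_progressors + self.n_nonprogressors)


def default_config() -> SyntheticCohortConfig:
    """The calibrated study-condition defaults (146 biopsies, 122 patients)."""
    return SyntheticCohortConfig()


# ---------------------------------------------------------------------------
# Closed-form calibration
# ---------------------------------------------------------------------------

def _score_log2_variance(
    config: SyntheticCohortConfig, genes: tuple[str, ...], beta: float
) -> float:
    """Variance of log2(score) for a G-gene geometric mean, including the
    replicate-noise terms the measured ddCT chain picks up (sample and
    calibrator 18S wells are shared across genes, target wells are not)."""
    g = len(genes)
    sig2 = sum(config.residual_sd[x] ** 2 for x in genes)
    rep = config.ct_noise_sd ** 2 / config.ct_replicates
    return beta ** 2 + sig2 / g ** 2 + rep * (2.0 + 2.0 / g)


def _mu_bar(target: float, v: float) -> float:
    """Mean of log2(score) so that the lognormal score has mean ``target``."""
    return float(np.log2(target) - _LN2 * v / 2.0)


def _excess(total: float, shares: dict[str, float]) -> pd.Series:
    """Distribute a total mean log2FC excess across genes by shares."""
    s = pd.Series({g: shares.get(g, 0.0) for g in CRM_GENES}, dtype=float)
    if (s < 0).any():
        raise ValueError("effect shares must be nonnegative")
    if s.sum() == 0:
        raise ValueError("effect shares must not be all zero")
    return total * len(s) * s / s.sum()


def _cell_means(config: SyntheticCohortConfig) -> dict[str, pd.Series]:
    """Per-gene log2FC means for every phenotype x timepoint cell."""
    genes = CRM_GENES
    t = config.target_scores
    # cross-sectional arm
    v_cross = _score_log2_variance(config, genes, config.latent_loading)
    mu_noar = _mu_bar(t["NOAR"], v_cross)
    mu_ar = _mu_bar(t["AR"], v_cross)
    d_ar = _excess(mu_ar - mu_noar, config.ar_effect_share)
    base_noar = pd.Series(mu_noar, index=genes, dtype=float)

    # longitudinal arm
    beta_l = config.latent_loading_longitudinal
    v11 = _score_log2_variance(config, genes, beta_l)
    v7 = _score_log2_variance(config, PIFTA_GENES, beta_l)
    mu_np6 = _mu_bar(t["NP6"], v11)
    mu_p6 = _mu_bar(t["P6"], v11)
    mu_np24 = _mu_bar(t["NP24"], v11)
    mu_p24 = _mu_bar(t["P24"], v11)
    d6 = _excess(mu_p6 - mu_np6, config.pifta_effect_share)
    d24 = _excess(mu_p24 - mu_np24, config.pifta_effect_share)
    # zero-mean baseline gene-profile offset: pins the 7-gene sub-score of
    # the 6-month progressor cell to its printed mean while leaving every
    # 11-gene cell mean untouched
    seven = list(PIFTA_GENES)
    others = [g for g in genes if g not in PIFTA_GENES]
    mean7_target = _mu_bar(config.subscore_target_p6, v7)
    mean7_eta = mean7_target - mu_np6 - float(d6[seven].mean())
    eta = pd.Series(0.0, index=genes, dtype=float)
    eta[seven] = mean7_eta
    eta[others] = -mean7_eta * len(seven) / len(others)
    base_long = eta

    return {
        "NOAR": base_noar,
        "AR": base_noar + d_ar,
        "NP6": base_long + mu_np6,
        "P6": base_long + mu_np6 + d6,
        "NP24": base_long + mu_np24,
        "P24": base_long + mu_np24 + d24,
    }


def calibrate_group_mean(
    config: SyntheticCohortConfig,
    phenotype: Phenotype | str,
    timepoint: float | None = None,
) -> pd.Series:
    """Per-gene planted log2 fold-change means for one cohort cell.

    ``timepoint`` (6 or 24) is required for the pIFTA phenotypes and
    ignored for the cross-sectional ones.
    """
    phenotype = Phenotype(phenotype)
    cells = _cell_means(config)
    if phenotype is Phenotype.AR:
        return cells["AR"]
    if phenotype is Phenotype.NOAR:
        return cells["NOAR"]
    if timepoint not in (6, 24, 6.0, 24.0):
        raise ValueError("pIFTA cells require timepoint 6 or 24")
    key = ("P" if phenotype is Phenotype.PIFTA_P else "NP") + str(int(timepoint))
    return cells[key]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, size, lower=1.0):
    draws = rng.normal(mean, sd, size)
    return np.round(np.maximum(draws, lower), 1)


def generate(
    config: SyntheticCohortConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort: ``(ct_table, sample_sheet)``.

    Deterministic given ``config.seed``: two calls with the same config
    produce identical frames (and hence byte-identical canonical files).
    """
    config = config or default_config()
    rng = np.random.default_rng(config.seed)
    genes = list(CRM_GENES)
    cells = _cell_means(config)

    meta_rows: list[dict] = []
    plan: list[tuple[str, pd.Series, float, float]] = []
    # (sample_id, mu vector, beta, z)

    def add_cross(prefix, n, phenotype, split, cell, tp_mean, tp_sd):
        tps = _truncated_normal(rng, tp_mean, tp_sd, n)
        zs = rng.normal(0.0, 1.0, n)
        for k in range(n):
            sid = f"{prefix}{k + 1:02d}"
            meta_rows.append({
                "sample_id": sid,
                "patient_id": f"PT-{sid}",
                "phenotype": phenotype.value,
                "timepoint_months": float(tps[k]),
                "split": split.value,
                "banff_t": np.nan,
                "banff_i": np.nan,
                "_z": zs[k],
            })
            plan.append((sid, cells[cell], config.latent_loading, zs[k]))

    add_cross("AR-D-", config.n_ar_discovery, Phenotype.AR,
              Split.DISCOVERY, "AR",
              config.ar_timepoint_mean, config.ar_timepoint_sd)
    add_cross("NOAR-D-", config.n_noar_discovery, Phenotype.NOAR,
              Split.DISCOVERY, "NOAR",
              config.noar_timepoint_mean, config.noar_timepoint_sd)
    add_cross("AR-V-", config.n_ar_validation, Phenotype.AR,
              Split.VALIDATION, "AR",
              config.ar_timepoint_mean, config.ar_timepoint_sd)
    add_cross("NOAR-V-", config.n_noar_validation, Phenotype.NOAR,
              Split.VALIDATION, "NOAR",
              config.noar_timepoint_mean, config.noar_timepoint_sd)

    def add_longitudinal(prefix, n, phenotype, key6, key24):
        zs = rng.normal(0.0, 1.0, n)  # patient-level latent, shared by pair
        beta_l = config.latent_loading_longitudinal
        for k in range(n):
            patient = f"PT-{prefix}{k + 1:02d}"
            for tp, cell in ((6.0, key6), (24.0, key24)):
                sid = f"{prefix}{k + 1:02d}-{int(tp):02d}M"
                meta_rows.append({
                    "sample_id": sid,
                    "patient_id": patient,
                    "phenotype": phenotype.value,
                    "timepoint_months": tp,
                    "split": Split.LONGITUDINAL.value,
                    "banff_t": np.nan,
                    "banff_i": np.nan,
                    "_z": zs[k],
                })
                plan.append((sid, cells[cell], beta_l, zs[k]))

    add_longitudinal("LP-", config.n_progressors, Phenotype.PIFTA_P,
                     "P6", "P24")
    add_longitudinal("LNP-", config.n_nonprogressors, Phenotype.PIFTA_NP,
                     "NP6", "NP24")

    samples = pd.DataFrame(meta_rows)

    # Banff grades for AR biopsies: quartile-discretized a*z + noise
    ar_mask = samples["phenotype"] == Phenotype.AR.value
    a = config.banff_coupling
    for col, noise_sd in (("banff_t", config.banff_noise_sd_t),
                          ("banff_i", config.banff_noise_sd_i)):
        w = (a * samples.loc[ar_mask, "_z"].to_numpy()
             + rng.normal(0.0, noise_sd, int(ar_mask.sum())))
        scale = float(np.hypot(a, noise_sd))
        cuts = stats.norm.ppf([0.25, 0.5, 0.75]) * scale
        samples.loc[ar_mask, col] = np.digitize(w, cuts).astype(float)
    samples["banff_t"] = samples["banff_t"].astype("Float64")
    samples["banff_i"] = samples["banff_i"].astype("Float64")
    samples = samples.drop(columns="_z")

    # planted log2 fold changes -> CT wells
    sigma = np.array([config.residual_sd[g] for g in genes])
    dct_cal = np.array([config.calibrator_dct[g] for g in genes])
    ct_rows: list[tuple[str, str, int, float]] = []
    reps = config.ct_replicates

    def emit_wells(sid: str, gene: str, true_ct: float) -> None:
        noise = rng.normal(0.0, config.ct_noise_sd, reps)
        for r in range(reps):
            ct_rows.append((sid, gene, r + 1, true_ct + noise[r]))

    for sid, mu, beta, z in plan:
        log2fc = mu.to_numpy() + beta * z + rng.normal(0.0, sigma)
        ct_ref = rng.normal(config.reference_ct_mean, config.reference_ct_sd)
        emit_wells(sid, REFERENCE_GENE, ct_ref)
        for j, gene in enumerate(genes):
            emit_wells(sid, gene, ct_ref + dct_cal[j] - log2fc[j])

    cal_ref = rng.normal(config.reference_ct_mean, config.reference_ct_sd)
    emit_wells(CALIBRATOR_SAMPLE_ID, REFERENCE_GENE, cal_ref)
    for j, gene in enumerate(genes):
        emit_wells(CALIBRATOR_SAMPLE_ID, gene, cal_ref + dct_cal[j])

    ct_table = pd.DataFrame(
        ct_rows, columns=["sample_id", "gene", "replicate", "ct"]
    )
    ct_table["ct"] = ct_table["ct"].round(4)
    return ct_table, samples.reset_index(drop=True)


def simulate_to_dir(config: SyntheticCohortConfig, out_dir) -> dict[str, Path]:
    """Generate a cohort and write canonical CSVs plus the config used."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct, samples = generate(config)
    paths = {
        "ct_table": out / "ct_table.csv",
        "samples": out / "samples.csv",
        "config": out / "config_used.yaml",
    }
    write_ct_table(ct, paths["ct_table"])
    write_sample_sheet(samples, paths["samples"])
    save_config(config, paths["config"])
    return paths


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------

def save_config(config: SyntheticCohortConfig, path) -> None:
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def load_config(path) -> SyntheticCohortConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SyntheticCohortConfig(**data)
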