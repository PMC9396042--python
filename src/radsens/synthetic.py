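"""Synthetic RNA-seq cohorts with known radiosensitivity ground truth.

The generator emulates the statistical structure the pipeline assumes:
negative-binomial background gene counts over a shared log-normal abundance
profile, log-normal library sizes, tissue-specific composition bias (a
subset of background genes shifted in tumour samples, which TMM must
absorb), and the ten signature genes planted so that the post-normalization
log2 CPM panel vector hits a per-sample target RSI. Paired tumour/normal
designs mirror the two study layouts: a single patient with repeated
biopsies (9 tumour / 3 normal) and a cohort of 14 patients with one
tumour and one adjacent-normal sample each.

Every sample draws from its own counter-split random stream derived from a
single seed, so adding samples never perturbs earlier ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SyntheticDataError
from .panel import CountMatrix, RSI_COEFFICIENTS, SampleSheet
from .radiosensitivity import Regimen, alpha_from_rsi, compute_gard

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "panel_expression_for_rsi",
    "generate_cohort",
    "alpha_cohort_tcp_reference",
    "breast_design",
    "prostate_design",
]

logger = logging.getLogger(__name__)

_CABL_COEFF = RSI_COEFFICIENTS["cABL"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort design and noise model for the generator.

    Defaults describe a bulk RNA-seq experiment: 5000 background genes,
    NB dispersion 0.1 (variance mu + 0.1 mu^2), library sizes log-normal
    around 5e6 reads, panel baseline log2 CPM of 5, and a between-sample
    RSI spread of 0.04 comparable to the tumour-group spread seen in
    paired-biopsy data.
    """

    n_patients: int = 1
    tumor_per_patient: int = 9
    normal_per_patient: int = 3
    n_background_genes: int = 5000
    nb_dispersion: float = 0.1
    lib_size_log_mean: float = math.log(5e6)
    lib_size_log_sd: float = 0.3
    target_rsi_tumor: float = 0.43
    target_rsi_normal: float = 0.52
    rsi_sd: float = 0.04
    panel_baseline: float = 5.0  # log2 CPM for the nine non-adjusted panel genes
    composition_bias_frac: float = 0.05  # background genes shifted in tumour
    composition_bias_log_sd: float = 1.0
    prior_count: float = 1.0
    regimen: Regimen = field(default_factory=lambda: Regimen(n=25, d=2.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_background_genes < 1:
            raise SyntheticDataError("cohort sizes must be positive")
        if self.tumor_per_patient < 1:
            raise SyntheticDataError("need at least one tumour sample per patient")
        for t in (self.target_rsi_tumor, self.target_rsi_normal):
            if not 0 < t < 1:
                raise SyntheticDataError(f"target RSI {t} outside (0, 1)")
        if self.nb_dispersion < 0 or self.rsi_sd < 0:
            raise SyntheticDataError("dispersion and rsi_sd must be non-negative")


def breast_design(**overrides) -> SyntheticConfig:
    """Single patient, 9 tumour / 3 normal biopsies, targets 0.43 / 0.52."""
    cfg = SyntheticConfig(
        n_patients=1,
        tumor_per_patient=9,
        normal_per_patient=3,
        target_rsi_tumor=0.43,
        target_rsi_normal=0.52,
        regimen=Regimen(n=25, d=2.0),
    )
    return replace(cfg, **overrides) if overrides else cfg


def prostate_design(**overrides) -> SyntheticConfig:
    """14 patients, one tumour and one adjacent normal each, targets 0.43 / 0.46."""
    cfg = SyntheticConfig(
        n_patients=14,
        tumor_per_patient=1,
        normal_per_patient=1,
        target_rsi_tumor=0.43,
        target_rsi_normal=0.46,
        regimen=Regimen(n=36, d=2.0),
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class GroundTruth:
    """Intended per-sample RSI/alpha/GARD under the config's regimen."""

    regimen: Regimen
    rsi: dict[str, float]
    alpha: dict[str, float]
    gard: dict[str, float]


def panel_expression_for_rsi(
    target_rsi: float, baseline: dict[str, float] | None = None
) -> dict[str, float]:
    """Panel expression hitting an exact target RSI.

    Starts from ``baseline`` (default: all genes at 0) and adjusts only the
    cABL component — the largest-magnitude coefficient — so the linear
    signature equals ``target_rsi`` exactly. Always solvable since the cABL
    coefficient is nonzero.
    """
    expr = {name: 0.0 for name in RSI_COEFFICIENTS}
    if baseline:
        expr.update({k: float(v) for k, v in baseline.items()})
    partial = sum(
        RSI_COEFFICIENTS[name] * expr[name] for name in RSI_COEFFICIENTS if name != "cABL"
    )
    expr["cABL"] = (target_rsi - partial) / _CABL_COEFF
    return expr


def _sample_rng(seed: int, key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[CountMatrix, SampleSheet, GroundTruth]:
    """Generate a paired tumour/normal cohort with known ground truth.

    Panel-gene counts are obtained by inverting log2(CPM + prior) at the
    sample's realized library size and rounding to the nearest integer, so
    the realized RSI differs from the intended one only by rounding and
    TMM-normalization noise.
    """
    # cohort-level draws (spawn_key 0): gene abundance profile & biased genes
    rng0 = _sample_rng(cfg.seed, (0,))
    g = cfg.n_background_genes
    abundance = rng0.lognormal(mean=0.0, sigma=1.5, size=g)
    abundance /= abundance.sum()
    n_biased = int(round(cfg.composition_bias_frac * g))
    biased_idx = rng0.choice(g, size=n_biased, replace=False)
    tumor_fold = np.ones(g)
    tumor_fold[biased_idx] = np.exp(
        rng0.normal(0.0, cfg.composition_bias_log_sd, size=n_biased)
    )

    sample_plan: list[tuple[str, str, str]] = []  # (sample_id, patient_id, tissue)
    for p in range(cfg.n_patients):
        pid = f"P{p + 1}"
        for t in range(cfg.tumor_per_patient):
            sample_plan.append((f"{pid}_T{t + 1}", pid, "tumor"))
        for n in range(cfg.normal_per_patient):
            sample_plan.append((f"{pid}_N{n + 1}", pid, "normal"))

    panel_names = list(RSI_COEFFICIENTS)
    baseline = {name: cfg.panel_baseline for name in panel_names}
    columns: dict[str, np.ndarray] = {}
    truth_rsi: dict[str, float] = {}

    for i, (sid, _pid, tissue) in enumerate(sample_plan):
        rng = _sample_rng(cfg.seed, (1, i))
        lib_target = rng.lognormal(cfg.lib_size_log_mean, cfg.lib_size_log_sd)
        mu = abundance * lib_target
        if tissue == "tumor":
            mu = mu * tumor_fold
            mu *= lib_target / mu.sum()  # bias changes composition, not depth
        background = _nb_draw(rng, mu, cfg.nb_dispersion).astype(np.int64)

        target = (
            cfg.target_rsi_tumor if tissue == "tumor" else cfg.target_rsi_normal
        )
        intended = float(rng.normal(target, cfg.rsi_sd)) if cfg.rsi_sd > 0 else target
        expr = panel_expression_for_rsi(intended, baseline)

        # invert log2(count/L * 1e6 + prior) at the final library size; the
        # panel contributes to L, so refine the total once
        lib = float(background.sum())
        for _ in range(2):
            cpm = np.array([2.0 ** expr[n] - cfg.prior_count for n in panel_names])
            if (cpm < 0).any():
                bad = panel_names[int(np.argmin(cpm))]
                raise SyntheticDataError(
                    f"infeasible panel expression for {sid}: gene {bad} "
                    "would require a negative count"
                )
            panel_counts = np.rint(cpm / 1e6 * lib)
            lib = float(background.sum() + panel_counts.sum())
        columns[sid] = np.concatenate([panel_counts.astype(np.int64), background])
        truth_rsi[sid] = intended

    gene_ids = [_panel_gene_id(n) for n in panel_names] + [
        f"BG{j + 1}" for j in range(g)
    ]
    counts = pd.DataFrame(columns, index=gene_ids)
    cm = CountMatrix(counts)
    sheet = SampleSheet(
        pd.DataFrame(sample_plan, columns=["sample_id", "patient_id", "tissue"])
    )
    alpha = {s: alpha_from_rsi(r) for s, r in truth_rsi.items()}
    gard = {s: compute_gard(a, cfg.regimen) for s, a in alpha.items()}
    truth = GroundTruth(regimen=cfg.regimen, rsi=truth_rsi, alpha=alpha, gard=gard)
    return cm, sheet, truth


def _panel_gene_id(canonical: str) -> str:
    """Default gene identifier planted for a signature symbol."""
    from .panel import DEFAULT_ALIASES

    return DEFAULT_ALIASES[canonical][0]


def alpha_cohort_tcp_reference(
    n: int, mean: float = 0.35, sd: float = 0.08, seed: int = 0
) -> np.ndarray:
    """Gaussian alpha draws for the TCP-literature reference dose distribution.

    Non-positive draws are redrawn (count logged) since alpha <= 0 has no
    dose solution; with the default mean/sd this is a ~6e-6 tail event.
    """
    if n < 1:
        raise SyntheticDataError("n must be >= 1")
    rng = np.random.default_rng(seed)
    values = rng.normal(mean, sd, size=n)
    redrawn = 0
    while (values <= 0).any():
        bad = values <= 0
        redrawn += int(bad.sum())
        values[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    if redrawn:
        logger.info("redrew %d non-positive alpha value(s)", redrawn)
    return values
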