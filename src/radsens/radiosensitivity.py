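"""RSI scoring and linear-quadratic dosimetry (alpha, GARD, optimal dose).

The radiosensitivity index (RSI) is a signed linear combination of the
normalized expression of ten genes, calibrated to SF2 — the surviving
fraction of clonogenic cells after a single 2 Gy fraction. Under the
linear-quadratic survival model with a fixed beta of 0.05 Gy^-2 and the
2 Gy calibration fraction, the patient-specific alpha follows in closed
form:

    alpha = -0.5 * ln(RSI) - 0.1          [Gy^-1]

and the genomic-adjusted radiation dose of an n x d Gy regimen is

    GARD = n * d * (alpha + beta * d).

Lower RSI means a more radiosensitive tumour, hence larger alpha and a
larger biological effect (GARD) from the same physical dose.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

from .errors import DoseError, RadsensError
from .normalization import NormalizedMatrix
from .panel import RSI_COEFFICIENTS

__all__ = [
    "Regimen",
    "RadioProfile",
    "RSI_HYPOFRACTIONATION_THRESHOLD",
    "compute_rsi",
    "alpha_from_rsi",
    "compute_gard",
    "optimal_total_dose",
    "profile_sample",
]

#: Tumours with RSI strictly above this are flagged as hypofractionation
#: candidates (relatively radioresistant, hence low alpha/beta).
RSI_HYPOFRACTIONATION_THRESHOLD = 0.4

#: Fixed radiobiological beta used throughout the GARD model.
DEFAULT_BETA = 0.05


@dataclass(frozen=True)
class Regimen:
    """A fractionation schedule: n fractions of d Gy with fixed beta (Gy^-2)."""

    n: int
    d: float
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if self.n < 1 or int(self.n) != self.n:
            raise RadsensError(f"fraction count must be a positive integer, got {self.n}")
        if self.d <= 0:
            raise RadsensError(f"dose per fraction must be positive, got {self.d}")
        if self.beta <= 0:
            raise RadsensError(f"beta must be positive, got {self.beta}")

    @property
    def total_dose(self) -> float:
        return self.n * self.d

    def __str__(self) -> str:  # e.g. "50 Gy/25fx"
        return f"{self.total_dose:g} Gy/{self.n}fx"


@dataclass(frozen=True)
class RadioProfile:
    """Per-sample radiosensitivity profile under a named regimen."""

    sample_id: str
    rsi: float
    alpha: float
    gard: float
    regimen: Regimen
    hypofractionation_ok: bool
    optimal_total_dose: float | None = None
    optimal_fractions: int | None = None


def compute_rsi(panel_expr: Mapping[str, float]) -> float:
    """Evaluate the ten-gene linear signature on normalized expression.

    ``panel_expr`` maps each signature symbol to its (log2 TMM CPM)
    expression. The result is not clamped: out-of-range values are left to
    the caller so that normalization problems stay visible.
    """
    total = 0.0
    for name, coeff in RSI_COEFFICIENTS.items():
        if name not in panel_expr:
            raise RadsensError(f"panel expression missing gene {name}")
        x = float(panel_expr[name])
        if not math.isfinite(x):
            raise RadsensError(f"panel expression for {name} is not finite ({x})")
        total += coeff * x
    return total


def alpha_from_rsi(rsi: float) -> float:
    """Patient-specific LQ alpha (Gy^-1) from RSI via the 2 Gy calibration.

    Negative alpha (RSI > e^-0.2 ~ 0.8187) is physically questionable but
    mathematically defined; it produces a warning, not an error.
    """
    if rsi <= 0:
        raise DoseError(f"RSI must be positive, got {rsi}")
    if rsi > 1:
        warnings.warn(
            f"RSI {rsi:g} exceeds 1; outside the SF2 interpretation", stacklevel=2
        )
    alpha = -0.5 * math.log(rsi) - 0.1
    if alpha < 0:
        warnings.warn(
            f"alpha is negative ({alpha:.4g}) for RSI {rsi:g}; "
            "dose-finding is undefined at d = 2 Gy",
            stacklevel=2,
        )
    return alpha


def compute_gard(alpha: float, regimen: Regimen) -> float:
    """GARD = n*d*(alpha + beta*d) for the given regimen."""
    return regimen.n * regimen.d * (alpha + regimen.beta * regimen.d)


def optimal_total_dose(
    alpha: float,
    gard_target: float,
    d: float = 2.0,
    beta: float = DEFAULT_BETA,
) -> tuple[float, int]:
    """Minimum total dose (Gy) reaching a GARD target at d Gy per fraction.

    Returns the continuous dose ``gard_target / (alpha + beta*d)`` and the
    whole number of d-Gy fractions covering it (ceiling).
    """
    if gard_target < 0:
        raise DoseError(f"GARD target must be non-negative, got {gard_target}")
    denom = alpha + beta * d
    if denom <= 0:
        raise DoseError(
            f"dose unattainable: alpha + beta*d = {denom:.4g} <= 0 "
            "(radioresistant beyond model validity)"
        )
    dose = gard_target / denom
    return dose, math.ceil(dose / d)


def profile_sample(
    nm: NormalizedMatrix,
    panel_map: Mapping[str, int],
    sample_id: str,
    regimen: Regimen,
    rsi_threshold: float = RSI_HYPOFRACTIONATION_THRESHOLD,
    gard_target: float | None = None,
) -> RadioProfile:
    """Full per-sample profile: RSI, alpha, GARD, flags, optional optimal dose.

    ``panel_map`` is the output of :func:`radsens.panel.resolve_panel`:
    signature symbol -> gene row index in the normalized matrix.
    """
    col = nm.sample_values(sample_id)
    expr = {name: float(col.iloc[idx]) for name, idx in panel_map.items()}
    rsi = compute_rsi(expr)
    alpha = alpha_from_rsi(rsi)
    gard = compute_gard(alpha, regimen)
    opt_dose = opt_fx = None
    if gard_target is not None:
        opt_dose, opt_fx = optimal_total_dose(alpha, gard_target, regimen.d, regimen.beta)
    return RadioProfile(
        sample_id=sample_id,
        rsi=rsi,
        alpha=alpha,
        gard=gard,
        regimen=regimen,
        hypofractionation_ok=rsi > rsi_threshold,  # strict: "in excess of"
        optimal_total_dose=opt_dose,
        optimal_fractions=opt_fx,
    )
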