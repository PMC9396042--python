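"""Between-sample normalization: CPM with TMM scaling factors, log2 output.

TMM (trimmed mean of M-values) corrects counts-per-million for composition
bias: a handful of very highly expressed genes in one sample deflate the
apparent expression of everything else. For each sample a scaling factor is
computed against a reference sample as a weighted mean of per-gene log2
expression ratios (M-values), after trimming the extremes of both M and of
average abundance (A), with weights given by the delta-method (binomial)
variance of each M-value. Factors are rescaled to geometric mean 1 and enter
the pipeline through the effective library size:

    value[g, s] = log2( count[g, s] / (lib_size[s] * factor[s]) * 1e6 + prior )
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NormalizationError
from .panel import CountMatrix

__all__ = ["NormalizedMatrix", "compute_cpm", "tmm_factor", "tmm_normalize"]


@dataclass(frozen=True)
class NormalizedMatrix:
    """log2 TMM-adjusted CPM values with the scaling factors that produced them."""

    values: pd.DataFrame  # genes x samples, log2 scale
    tmm_factors: pd.Series  # per-sample, geometric mean 1
    effective_lib_sizes: pd.Series  # lib_size * tmm_factor
    prior_count: float
    reference_sample: str

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def sample_values(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]


def compute_cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million: count / library size * 1e6, per sample."""
    lib = cm.lib_sizes
    zero = lib[lib == 0]
    if len(zero):
        raise NormalizationError(f"zero library size for sample {zero.index[0]!r}")
    return cm.counts / lib * 1e6


def _trim_keep(values: np.ndarray, trim: float) -> np.ndarray:
    """Boolean keep-mask after removing ceil(trim*m) values from each tail.

    Ties in the order statistics are resolved by element index so the result
    is deterministic and independent of any prior ordering.
    """
    m = len(values)
    k = math.ceil(trim * m)
    keep = np.ones(m, dtype=bool)
    if k == 0:
        return keep
    order = np.lexsort((np.arange(m), values))
    keep[order[:k]] = False
    keep[order[m - k:]] = False
    return keep


def tmm_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """TMM scaling factor of an observed count column against a reference.

    Genes with a zero count in either column, or constituting an entire
    library, carry an undefined or degenerate log-ratio and are excluded.
    Returns 1.0 (with a warning) when no genes survive trimming.
    """
    obs = np.asarray(obs, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n_obs, n_ref = obs.sum(), ref.sum()
    if n_obs <= 0 or n_ref <= 0:
        raise NormalizationError("TMM requires positive library sizes")

    usable = (obs > 0) & (ref > 0) & (obs < n_obs) & (ref < n_ref)
    o, r = obs[usable], ref[usable]
    if o.size == 0:
        warnings.warn("no usable genes for TMM; factor set to 1", stacklevel=2)
        return 1.0

    po, pr = o / n_obs, r / n_ref
    m_vals = np.log2(po / pr)
    a_vals = 0.5 * np.log2(po * pr)
    # inverse asymptotic (delta-method binomial) variances
    weights = 1.0 / ((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))

    keep = _trim_keep(m_vals, trim_m) & _trim_keep(a_vals, trim_a)
    if not keep.any():
        warnings.warn("no genes survive TMM trimming; factor set to 1", stacklevel=2)
        return 1.0
    return float(2.0 ** (np.sum(weights[keep] * m_vals[keep]) / np.sum(weights[keep])))


def _reference_column(cm: CountMatrix) -> int:
    """Sample whose 75th-percentile CPM is closest to the cross-sample mean.

    Ties are broken by lowest sample index.
    """
    cpm = compute_cpm(cm).to_numpy()
    q75 = np.percentile(cpm, 75, axis=0)
    return int(np.argmin(np.abs(q75 - q75.mean())))


def tmm_normalize(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    prior_count: float = 1.0,
) -> NormalizedMatrix:
    """Full normalization: TMM factors, geometric-mean-1 rescale, log2 CPM.

    The prior count is added on the CPM scale before the log so zeros stay
    finite. Deterministic for fixed input.
    """
    if cm.n_samples < 2:
        raise NormalizationError("TMM is undefined for a single-sample matrix")
    if prior_count <= 0:
        raise NormalizationError("prior_count must be positive")
    counts = cm.counts.to_numpy(dtype=float)
    lib = cm.lib_sizes.to_numpy(dtype=float)
    ref_idx = _reference_column(cm)
    ref = counts[:, ref_idx]

    factors = np.array(
        [tmm_factor(counts[:, j], ref, trim_m, trim_a) for j in range(cm.n_samples)]
    )
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean -> 1

    eff_lib = lib * factors
    values = np.log2(counts / eff_lib * 1e6 + prior_count)
    samples = cm.sample_ids
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=cm.gene_ids, columns=samples),
        tmm_factors=pd.Series(factors, index=samples, name="tmm_factor"),
        effective_lib_sizes=pd.Series(eff_lib, index=samples, name="effective_lib_size"),
        prior_count=prior_count,
        reference_sample=samples[ref_idx],
    )


def write_normalized(nm: NormalizedMatrix, values_path, factors_path=None) -> None:
    """Export the normalized matrix (and optionally the factors) as TSV."""
    nm.values.to_csv(values_path, sep="\t", index_label="gene_id")
    if factors_path is not None:
        nm.tmm_factors.rename_axis("sample_id").to_csv(factors_path, sep="\t")
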