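"""Count filtering and between-sample normalization.

Two normalization routes are supported for a gene x sample matrix of read
counts:

* TMM (trimmed mean of M-values) scale factors, followed by equalization of
  effective library sizes into non-integer pseudocounts that are converted
  back to integer counts with a ``ceiling(x - 0.5)`` rule (round-half-up,
  chosen to approach the correct proportion of zero counts), and
* externally computed per-gene per-sample log2 offsets (for example from
  conditional-quantile normalization adjusting for gene length and GC
  content), applied on the log2 reads-per-million scale and rolled back to
  absolute integer counts with the same rule.

Lowly expressed genes are removed by a mean counts-per-million filter before
model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "NormalizationFactors",
    "cpm_filter",
    "tmm_factors",
    "equalize_lib_sizes",
    "normalize_counts",
    "apply_offsets",
]


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts."""

    counts: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D gene x sample array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValueError("gene_ids length does not match the count matrix")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValueError("sample_ids length does not match the count matrix")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")

    @property
    def lib_sizes(self) -> np.ndarray:
        """Per-sample total counts (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))


@dataclass
class NormalizationFactors:
    """Per-sample scale factors and the effective library sizes they imply."""

    factors: np.ndarray
    lib_sizes: np.ndarray
    method: str = "tmm"

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("normalization factors must be positive")

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.factors


def cpm_filter(m: CountMatrix, min_cpm: float = 0.1) -> CountMatrix:
    """Keep genes whose mean counts-per-million across samples exceeds ``min_cpm``.

    The comparison is strict, so an all-zero gene is removed at any
    non-negative threshold.
    """
    lib = m.lib_sizes.astype(float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive for CPM filtering")
    cpm = m.counts * 1e6 / lib[np.newaxis, :]
    keep = cpm.mean(axis=1) > min_cpm
    if not keep.any():
        warnings.warn("CPM filter removed every gene", stacklevel=2)
    return CountMatrix(m.counts[keep], [g for g, k in zip(m.gene_ids, keep) if k],
                       m.sample_ids)


def _tmm_pair(obs, ref, lib_obs, lib_ref, trim_m, trim_a):
    """Trimmed, precision-weighted mean of M-values of one sample vs the reference."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return None
    o = obs[pos] / lib_obs
    r = ref[pos] / lib_ref
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    # delta-method variance of M, used as precision weight
    v = (lib_obs - obs[pos]) / (lib_obs * obs[pos]) + (lib_ref - ref[pos]) / (lib_ref * ref[pos])
    n = M.size
    rM = stats.rankdata(M)
    rA = stats.rankdata(A)
    keep = (
        (rM >= n * trim_m + 1) & (rM <= n * (1.0 - trim_m))
        & (rA >= n * trim_a + 1) & (rA <= n * (1.0 - trim_a))
    )
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f) or abs(f) < 1e-10:
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(m: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05,
                ref_column: int | None = None) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scale factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the across-sample mean; per-sample factors are the
    precision-weighted mean of log2 count ratios after trimming the most
    extreme ``trim_m`` of M-values and ``trim_a`` of A-values on each side.
    Factors are rescaled so that their geometric mean is exactly 1.
    """
    if m.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    counts = m.counts.astype(float)
    lib = m.lib_sizes.astype(float)
    if ref_column is None:
        f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                        for j in range(m.n_samples)])
        ref_column = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.empty(m.n_samples)
    for j in range(m.n_samples):
        f = _tmm_pair(counts[:, j], counts[:, ref_column], lib[j], lib[ref_column],
                      trim_m, trim_a)
        if f is None:
            raise ValueError(
                f"sample '{m.sample_ids[j]}' shares no expressed genes with the reference"
            )
        factors[j] = f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(factors=factors, lib_sizes=lib, method="tmm")


def equalize_lib_sizes(m: CountMatrix, f: NormalizationFactors) -> np.ndarray:
    """Rescale counts to a common effective library size.

    The target is the geometric mean of the effective library sizes; the
    output is a real-valued pseudocount matrix in which zeros stay zero.
    """
    eff = f.effective_lib_sizes
    common = float(np.exp(np.mean(np.log(eff))))
    return m.counts.astype(float) * (common / eff)[np.newaxis, :]


def normalize_counts(m: CountMatrix, f: NormalizationFactors | None = None) -> CountMatrix:
    """Library-size-equalized integer counts.

    Pseudocounts are mapped back to integers by ``ceiling(x - 0.5)`` floored
    at zero: ordinary round-half-up, which preserves integer counts exactly
    when all effective library sizes coincide and keeps the zero fraction as
    close as possible to the raw data.
    """
    if f is None:
        f = tmm_factors(m)
    pseudo = equalize_lib_sizes(m, f)
    out = np.maximum(np.ceil(pseudo - 0.5), 0.0).astype(np.int64)
    return CountMatrix(out, m.gene_ids, m.sample_ids)


def apply_offsets(m: CountMatrix, log2_offsets: np.ndarray) -> CountMatrix:
    """Apply externally supplied per-gene per-sample log2 normalization offsets.

    Counts are taken to log2 reads-per-million, the offsets are added, and
    the result is rolled back to the absolute count scale through each
    sample's library size and converted to integers with the same
    ``ceiling(x - 0.5)`` rule.  Zero counts bypass the log round trip and
    stay zero, preserving the zero-inflation structure of the data.
    """
    off = np.asarray(log2_offsets, dtype=float)
    if off.shape != m.counts.shape:
        raise ValueError(
            f"offsets shape {off.shape} does not match counts {m.counts.shape}"
        )
    lib = m.lib_sizes.astype(float)
    counts = m.counts.astype(float)
    with np.errstate(divide="ignore"):
        log2_rpm = np.log2(counts * 1e6 / lib[np.newaxis, :])
    adj = np.power(2.0, log2_rpm + off) * lib[np.newaxis, :] / 1e6
    adj[counts == 0] = 0.0
    out = np.maximum(np.ceil(adj - 0.5), 0.0).astype(np.int64)
    return CountMatrix(out, m.gene_ids, m.sample_ids)
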