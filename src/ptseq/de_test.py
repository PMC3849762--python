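"""Two-sample Poisson-Tweedie test for differential expression.

For each gene, both sample groups are fitted by Poisson-Tweedie maximum
likelihood and the group means are compared with a Wald statistic that is
standard normal under the null of equal means.  The default works on the
logarithmic scale, H0: log(mu_A) = log(mu_B), with delta-method variances
Var(log mu) = Var(mu) / mu^2; the raw-scale statistic
(mu_A - mu_B) / sqrt(Var(mu_A) + Var(mu_B)) is available as an option.
Genome-wide p-values are corrected by Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import CountMatrix
from .pt_inference import PTFitError, fit_pt_mle

__all__ = [
    "SampleGroups",
    "DEStat",
    "pt_test_gene",
    "tweede",
    "adjust_bh",
]

RESULT_COLUMNS = [
    "gene", "overallMean", "meanA", "meanB", "log2fc",
    "stat", "pval", "pval.adjust", "flags",
]


@dataclass(frozen=True)
class SampleGroups:
    """Assignment of each sample to one of exactly two groups."""

    labels: np.ndarray
    group_a: str
    group_b: str

    @classmethod
    def from_labels(cls, labels) -> "SampleGroups":
        labels = np.asarray(labels).astype(str)
        uniq = sorted(set(labels.tolist()))
        if len(uniq) != 2:
            raise ValueError(f"need exactly two groups, got {uniq}")
        a, b = uniq
        for g in (a, b):
            if int((labels == g).sum()) < 2:
                raise ValueError(f"group '{g}' has fewer than 2 samples")
        return cls(labels=labels, group_a=a, group_b=b)

    @property
    def mask_a(self) -> np.ndarray:
        return self.labels == self.group_a

    @property
    def mask_b(self) -> np.ndarray:
        return ~self.mask_a


@dataclass
class DEStat:
    """Per-gene two-sample test result."""

    mu_a: float
    mu_b: float
    var_mu_a: float
    var_mu_b: float
    statistic: float
    pvalue: float
    log2fc: float
    flags: str = ""


def pt_test_gene(counts_a, counts_b, scale: str = "log") -> DEStat:
    """Two-sample PT test for one gene.

    ``scale='log'`` (default) tests H0: log(mu_A) = log(mu_B) with
    delta-method variances; ``scale='raw'`` uses the plain difference of
    means.  A failed fit in either group yields a flagged result with
    missing statistic and p-value (NaN), never a p-value of 1.
    """
    if scale not in ("log", "raw"):
        raise ValueError("scale must be 'log' or 'raw'")
    flags: list[str] = []
    try:
        fit_a = fit_pt_mle(counts_a)
        fit_b = fit_pt_mle(counts_b)
    except Exception as exc:  # degenerate profile etc.
        return DEStat(*(float("nan"),) * 7, flags=f"fit_error:{type(exc).__name__}")
    for side, fit in (("A", fit_a), ("B", fit_b)):
        if not fit.converged:
            flags.append(f"no_convergence_{side}")
        flags += [f"{fl}_{side}" for fl in fit.flags if fl != "poisson_boundary"]
    mu_a, mu_b = fit_a.params.mu, fit_b.params.mu
    va, vb = fit_a.var_mu, fit_b.var_mu
    log2fc = math.log2(mu_a / mu_b)
    ok = (
        fit_a.converged and fit_b.converged
        and np.isfinite(va) and np.isfinite(vb) and va >= 0 and vb >= 0
    )
    if not ok:
        return DEStat(mu_a, mu_b, va, vb, float("nan"), float("nan"), log2fc,
                      flags=";".join(flags) or "fit_failed")
    if scale == "log":
        se = math.sqrt(va / mu_a ** 2 + vb / mu_b ** 2)
        diff = math.log(mu_a) - math.log(mu_b)
    else:
        se = math.sqrt(va + vb)
        diff = mu_a - mu_b
    if se == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(float("inf"), diff)
    else:
        t = diff / se
    pvalue = float(2.0 * stats.norm.sf(abs(t)))
    return DEStat(mu_a, mu_b, va, vb, float(t), pvalue, log2fc,
                  flags=";".join(flags))


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries (NaN) are excluded from the number of tests and stay
    missing in the output.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = p[ok]
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def tweede(matrix: CountMatrix, groups: SampleGroups, scale: str = "log") -> pd.DataFrame:
    """Genome-wide two-sample PT test.

    Returns a table sorted by p-value with columns gene, overallMean,
    meanA, meanB, log2fc, stat, pval, pval.adjust and flags; adjusted
    p-values are BH over the genes whose fits succeeded.
    """
    if groups.labels.size != matrix.n_samples:
        raise ValueError("group labels do not match the number of samples")
    ma, mb = groups.mask_a, groups.mask_b
    if ma.sum() < 2 or mb.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    rows = []
    for i, gene in enumerate(matrix.gene_ids):
        row = matrix.counts[i]
        st = pt_test_gene(row[ma], row[mb], scale=scale)
        rows.append((gene, float(row.mean()), st.mu_a, st.mu_b, st.log2fc,
                     st.statistic, st.pvalue, st.flags))
    df = pd.DataFrame(rows, columns=["gene", "overallMean", "meanA", "meanB",
                                     "log2fc", "stat", "pval", "flags"])
    df["pval.adjust"] = adjust_bh(df["pval"].to_numpy())
    df = df[RESULT_COLUMNS]
    df = df.sort_values("pval", kind="mergesort", na_position="last").reset_index(drop=True)
    return df
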