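"""Synthetic RNA-seq studies and calibration metrics.

Two generators produce the benchmark data:

* ``simulate_pt_profiles`` draws each gene's two group blocks i.i.d. from
  explicitly specified Poisson-Tweedie laws, which is the construction used
  for type-I-error studies (identical laws in both groups make a null gene).
* ``simulate_gamma_poisson_study`` draws a full study matrix from a
  hierarchical gamma-Poisson model: per-gene dispersion indices from
  Gamma(k=2, theta=0.7) shifted above 1, per-gene baseline means, a chosen
  number of differentially expressed genes at a fixed fold-change (half up,
  half down), optional per-sample multiplicative library factors
  exp(N(0, sigma)), and a per-gene-per-sample gamma-mixed Poisson count whose
  marginal is exactly negative binomial with the intended mean and
  dispersion.

The evaluation half of the module provides the empirical type-I error rate,
Storey's pi0 estimate with the q-value transform, empirical-FDR calibration
curves with their mean squared error, precision/recall/F on a gold standard,
and per-gene Kolmogorov-Smirnov uniformity tests for replicated null
p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .de_test import SampleGroups
from .normalization import CountMatrix
from .pt_core import PTMeanParams, pt_sample, to_canonical, _extended_pmf

__all__ = [
    "GammaPoissonStudyConfig",
    "SimulatedStudy",
    "CalibrationCurve",
    "simulate_pt_profiles",
    "simulate_gamma_poisson_study",
    "null_resample_groups",
    "type1_error",
    "estimate_pi0",
    "qvalues",
    "efdr_curve",
    "precision_recall_f",
    "ks_uniformity",
]


@dataclass(frozen=True)
class GammaPoissonStudyConfig:
    """Configuration of one hierarchical gamma-Poisson study."""

    n_genes: int = 20_000
    n_samples: int = 70
    n_de: int = 100
    fold_change: float = 2.0
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.7
    library_factor_sd: float = 0.0
    mean_range: tuple[float, float] = (5.0, 500.0)
    dispersion_map: str = "shift"  # 'shift': phi = 1 + draw; 'truncate': redraw at 1+eps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.library_factor_sd < 0:
            raise ValueError("library_factor_sd must be >= 0")
        if self.dispersion_map not in ("shift", "truncate"):
            raise ValueError("dispersion_map must be 'shift' or 'truncate'")


@dataclass
class SimulatedStudy:
    """A simulated count matrix with its ground truth."""

    matrix: CountMatrix
    truth: pd.DataFrame  # gene, is_de, direction (+1 up in A, -1 down in A, 0 null)
    groups: SampleGroups
    config: GammaPoissonStudyConfig | None = None


@dataclass
class CalibrationCurve:
    """Empirical FDR against nominal q-value levels."""

    nominal: np.ndarray
    efdr: np.ndarray
    mse: float


def _sample_law(law: PTMeanParams, n: int, rng: np.random.Generator,
                cache: dict) -> np.ndarray:
    """Draw n counts from one PT law, caching the cdf table of general shapes."""
    if law.is_poisson or law.a == 0.0:
        return pt_sample(n, law, rng)
    key = (law.mu, law.phi, law.a)
    if key not in cache:
        cache[key] = np.cumsum(_extended_pmf(to_canonical(law)))
    u = rng.random(n)
    return np.searchsorted(cache[key], u, side="left").astype(np.int64)


def simulate_pt_profiles(gene_laws, n_per_group: int, seed) -> SimulatedStudy:
    """Simulate a two-group matrix with explicit per-gene PT laws.

    ``gene_laws`` is a sequence of ``(law_a, law_b)`` pairs of
    ``PTMeanParams`` (equal laws make the gene null) or single laws, which
    are used for both groups.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cache: dict = {}
    rows, truth_rows = [], []
    for g, entry in enumerate(gene_laws):
        if isinstance(entry, PTMeanParams):
            law_a = law_b = entry
        else:
            law_a, law_b = entry
        xa = _sample_law(law_a, n_per_group, rng, cache)
        xb = _sample_law(law_b, n_per_group, rng, cache)
        rows.append(np.concatenate([xa, xb]))
        is_de = law_a.mu != law_b.mu
        truth_rows.append((f"g{g:05d}", is_de,
                           0 if not is_de else (1 if law_a.mu > law_b.mu else -1)))
    counts = np.vstack(rows)
    gene_ids = [t[0] for t in truth_rows]
    sample_ids = [f"A{i:03d}" for i in range(n_per_group)] + \
                 [f"B{i:03d}" for i in range(n_per_group)]
    labels = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    matrix = CountMatrix(counts, gene_ids, sample_ids)
    truth = pd.DataFrame(truth_rows, columns=["gene", "is_de", "direction"])
    return SimulatedStudy(matrix=matrix, truth=truth,
                          groups=SampleGroups.from_labels(labels))


def simulate_gamma_poisson_study(cfg: GammaPoissonStudyConfig) -> SimulatedStudy:
    """Simulate a study matrix from the hierarchical gamma-Poisson model.

    Per gene g and sample i the count is Poisson with a gamma-distributed
    rate with shape ``f_i mu_g / (phi_g - 1)`` and scale ``phi_g - 1``, so
    the marginal is negative binomial with mean ``f_i mu_g`` and dispersion
    index ``phi_g``.  The first ``n_de`` genes are differentially expressed:
    the first half up-regulated in group A (mean multiplied by the
    fold-change), the second half down-regulated (divided); an odd count
    puts the extra gene in the up half.
    """
    rng = np.random.default_rng(cfg.seed)
    p, n = cfg.n_genes, cfg.n_samples
    n_a = n // 2

    draws = rng.gamma(cfg.dispersion_shape, cfg.dispersion_scale, size=p)
    if cfg.dispersion_map == "shift":
        phi = 1.0 + draws
    else:
        eps = 1e-3
        while np.any(draws <= eps):
            bad = draws <= eps
            draws[bad] = rng.gamma(cfg.dispersion_shape, cfg.dispersion_scale,
                                   size=int(bad.sum()))
        phi = 1.0 + draws  # truncated away from the Poisson boundary

    lo, hi = cfg.mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=p))

    n_up = (cfg.n_de + 1) // 2
    direction = np.zeros(p, dtype=int)
    direction[:n_up] = 1
    direction[n_up:cfg.n_de] = -1
    mu_a = np.where(direction == 1, mu * cfg.fold_change, mu)
    mu_b = np.where(direction == -1, mu * cfg.fold_change, mu)

    f = np.exp(rng.normal(0.0, cfg.library_factor_sd, size=n)) \
        if cfg.library_factor_sd > 0 else np.ones(n)

    group_mean = np.empty((p, n))
    group_mean[:, :n_a] = mu_a[:, None]
    group_mean[:, n_a:] = mu_b[:, None]
    mean_gi = group_mean * f[None, :]

    scale = (phi - 1.0)[:, None]
    lam = rng.gamma(mean_gi / scale, scale)
    counts = rng.poisson(lam).astype(np.int64)

    gene_ids = [f"g{i:05d}" for i in range(p)]
    sample_ids = [f"A{i:03d}" for i in range(n_a)] + \
                 [f"B{i:03d}" for i in range(n - n_a)]
    labels = np.array(["A"] * n_a + ["B"] * (n - n_a))
    truth = pd.DataFrame({
        "gene": gene_ids,
        "is_de": direction != 0,
        "direction": direction,
        "mu": mu,
        "phi": phi,
    })
    return SimulatedStudy(matrix=CountMatrix(counts, gene_ids, sample_ids),
                          truth=truth,
                          groups=SampleGroups.from_labels(labels),
                          config=cfg)


def null_resample_groups(m: CountMatrix, labels, within_group, n_per_group: int,
                         reps: int, seed) -> list[tuple[np.ndarray, np.ndarray]]:
    """Resample two pseudo-groups from samples sharing one label.

    Recreates the null hypothesis of no differential expression: both
    pseudo-groups come from the same biological condition, so any test run
    across the splits samples its null distribution.  When at least
    ``2 * n_per_group`` samples carry the label, each split is a random
    partition without replacement; otherwise samples are drawn with
    replacement.
    """
    labels = np.asarray(labels).astype(str)
    if labels.size != m.n_samples:
        raise ValueError("labels do not match the number of samples")
    pool = np.flatnonzero(labels == str(within_group))
    if pool.size == 0:
        raise ValueError(f"no samples carry the label '{within_group}'")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(reps):
        if pool.size >= 2 * n_per_group:
            pick = rng.choice(pool, size=2 * n_per_group, replace=False)
        else:
            pick = rng.choice(pool, size=2 * n_per_group, replace=True)
        out.append((pick[:n_per_group], pick[n_per_group:]))
    return out


def type1_error(pvalues, alpha: float = 0.05) -> tuple[float, float]:
    """Empirical rejection rate on null results, with its binomial SE."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no non-missing p-values")
    rate = float(np.mean(p < alpha))
    se = float(np.sqrt(rate * (1.0 - rate) / p.size)) if 0 < rate < 1 else \
        float(np.sqrt(alpha * (1.0 - alpha) / p.size))
    return rate, se


_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(pvalues, lambdas: np.ndarray = _LAMBDA_GRID,
                 method: str = "average") -> float:
    """Storey estimate of the null-gene fraction pi0.

    ``pi0(lambda) = #{p > lambda} / ((1 - lambda) m)`` is evaluated on the
    lambda grid.  The default pools the central grid points
    (0.20 <= lambda <= 0.80) by simple averaging, which is nearly unbiased
    when true positives concentrate at small p and has far lower variance
    than tail extrapolation at moderate numbers of genes.
    ``method='smoother'`` instead fits a cubic polynomial over the grid and
    evaluates it at the largest lambda, following the spline-smoother
    q-value recipe.  The result is clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no non-missing p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0_l = np.array([(p > l).sum() / ((1.0 - l) * m) for l in lambdas])
    if method == "average":
        mid = (lambdas >= 0.20 - 1e-9) & (lambdas <= 0.80 + 1e-9)
        pi0 = float(pi0_l[mid].mean()) if mid.any() else float(pi0_l.mean())
    elif method == "smoother":
        coef = np.polyfit(lambdas, pi0_l, deg=3)
        pi0 = float(np.polyval(coef, float(lambdas.max())))
    else:
        raise ValueError("method must be 'average' or 'smoother'")
    return float(np.clip(pi0, 0.0, 1.0))


def qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: BH step-up adjusted p-values scaled by pi0."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    m = q.size
    if m == 0:
        return out
    if pi0 is None:
        pi0 = estimate_pi0(q)
    order = np.argsort(q, kind="mergesort")
    ranked = pi0 * q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def efdr_curve(pvalues, truth, nominal: np.ndarray | None = None,
               pi0: float | None = None) -> CalibrationCurve:
    """Empirical FDR as a function of the nominal q-value level.

    ``truth`` is a boolean per-gene indicator of differential expression.
    At each nominal level genes with q-value <= level are called and the
    observed false-positive fraction among calls is recorded (0 when no
    gene is called); ``mse`` is the mean squared difference between the
    empirical and nominal series over the grid.
    """
    if nominal is None:
        nominal = np.linspace(0.0, 0.25, 101)
    truth = np.asarray(truth, dtype=bool)
    q = qvalues(pvalues, pi0=pi0)
    efdr = np.empty(nominal.size)
    for i, level in enumerate(nominal):
        called = q <= level
        ncalls = int(np.nansum(called))
        if ncalls == 0:
            efdr[i] = 0.0
        else:
            efdr[i] = float(np.sum(called & ~truth)) / ncalls
    mse = float(np.mean((efdr - nominal) ** 2))
    return CalibrationCurve(nominal=np.asarray(nominal), efdr=efdr, mse=mse)


def precision_recall_f(called, gold, universe) -> tuple[float, float, float]:
    """Precision, recall and F-measure of a call set against a gold standard.

    Precision is undefined (NaN) for an empty call set; the F-measure is 0
    by convention when precision + recall = 0.
    """
    called, gold, universe = set(called), set(gold), set(universe)
    if not called <= universe or not gold <= universe:
        raise ValueError("called and gold sets must lie within the universe")
    if not called:
        recall = 0.0 if gold else float("nan")
        return float("nan"), recall, float("nan")
    tp = len(called & gold)
    precision = tp / len(called)
    recall = tp / len(gold) if gold else float("nan")
    if precision + recall == 0:
        return precision, recall, 0.0
    f = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f


def ks_uniformity(pvalue_matrix) -> np.ndarray:
    """Per-gene Kolmogorov-Smirnov test of replicate p-values against U(0, 1).

    ``pvalue_matrix`` is genes x replicates; rows with fewer than 10
    non-missing replicates give NaN.
    """
    pm = np.atleast_2d(np.asarray(pvalue_matrix, dtype=float))
    out = np.empty(pm.shape[0])
    for i in range(pm.shape[0]):
        vals = pm[i][~np.isnan(pm[i])]
        if vals.size < 10:
            out[i] = np.nan
            continue
        out[i] = stats.kstest(vals, "uniform").pvalue
    return out
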