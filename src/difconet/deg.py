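"""Negative-binomial differential-expression screen.

Implements the classic count-based two-group screen: median-of-ratios size
factors, a per-gene method-of-moments negative-binomial dispersion, an exact
conditional NB test on the two condition sums, Benjamini-Hochberg FDR, and a
dual fold-change/FDR call.  The defaults reproduce the screening rule
|log2FC| >= 0.585 with FDR <= 0.05.

The exact test conditions on the total count of a gene across all samples:
under the null hypothesis of a common mean, the probability of the observed
split of that total between the two conditions is compared with every other
possible split, and the two-sided p-value is the total probability of all
splits at most as likely as the observed one.  Each condition sum is modelled
as a negative binomial whose mean and variance are assembled from the fitted
per-sample means (size factor x pooled mean) and the gene's dispersion.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix

logger = logging.getLogger(__name__)

#: splits are enumerated exactly up to this total; above it a normal
#: approximation to the conditional distribution is used (and logged).
MAX_ENUMERATION_TOTAL = 100_000

DISPERSION_FLOOR = 1e-8


def estimate_size_factors(cm: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For every gene with strictly positive counts in all samples, the ratio of
    each sample's count to the gene's geometric mean is formed; the size
    factor of a sample is the median of these ratios.  Raises if no gene is
    positive everywhere (the normaliser is undefined in that case).
    Accepts a CountMatrix or a bare gene x sample DataFrame.
    """
    frame = cm.counts if isinstance(cm, CountMatrix) else cm
    counts = frame.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "size factors undefined: no gene has strictly positive counts in every sample"
        )
    logs = np.log(counts[all_positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(s, index=frame.columns, name="size_factor")


def _pooled_moments(cm: CountMatrix, size_factors: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Grand mean and pooled within-condition variance of normalized counts."""
    norm = cm.counts.to_numpy(dtype=float) / size_factors.reindex(cm.sample_ids).to_numpy()
    m = norm.mean(axis=1)
    n_total = 0
    pooled_ss = np.zeros(norm.shape[0])
    for label in ("A", "B"):
        cols = cm.condition.to_numpy() == label
        sub = norm[:, cols]
        pooled_ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        n_total += cols.sum()
    v = pooled_ss / max(n_total - 2, 1)
    return m, v


def _raw_dispersion(m: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unclamped method-of-moments dispersion (v - m) / m^2; may be negative."""
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / np.square(m)
    return np.where(np.isfinite(alpha), alpha, 0.0)


def estimate_dispersion(cm: CountMatrix, size_factors: pd.Series,
                        floor: float = DISPERSION_FLOOR) -> pd.Series:
    """Per-gene method-of-moments NB dispersion on normalized counts.

    alpha_hat = max(floor, (v - m) / m^2) with m the grand mean of the
    normalized counts and v the pooled within-condition variance (so a true
    mean difference between conditions does not inflate the estimate).
    Zero-variance genes clamp to the floor.
    """
    m, v = _pooled_moments(cm, size_factors)
    alpha = np.maximum(_raw_dispersion(m, v), floor)
    return pd.Series(alpha, index=cm.gene_ids, name="dispersion")


def fit_dispersion_trend(mean: np.ndarray, raw_alpha: np.ndarray,
                         n_bins: int = 20, min_genes: int = 50):
    """Fit the mean-dispersion trend alpha(mu) = a1 + a0 / mu.

    With few replicates the per-gene moments estimate has only a handful of
    degrees of freedom; its sampling noise makes a screen that trusts it
    gene-by-gene anticonservative.  The trend is fitted by least squares on
    equal-occupancy bin means of the raw (unclamped) per-gene estimates,
    which are approximately unbiased, and the screen then tests each gene at
    the MAXIMUM of its own estimate and the trend value — the conservative
    choice.  Returns a callable mu -> trend alpha, or None when there are
    too few genes to fit (< ``min_genes``); coefficients are clamped >= 0.
    """
    mean = np.asarray(mean, dtype=float)
    raw_alpha = np.asarray(raw_alpha, dtype=float)
    ok = mean > 0
    if ok.sum() < min_genes:
        return None
    m, y = mean[ok], raw_alpha[ok]
    order = np.argsort(m)
    m, y = m[order], y[order]
    edges = np.linspace(0, len(m), min(n_bins, max(len(m) // 10, 1)) + 1).astype(int)
    xb, yb = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi > lo:
            xb.append(np.mean(1.0 / m[lo:hi]))
            yb.append(np.mean(y[lo:hi]))
    xb = np.asarray(xb)
    yb = np.asarray(yb)
    design = np.column_stack([xb, np.ones_like(xb)])
    (a0, a1), *_ = np.linalg.lstsq(design, yb, rcond=None)
    if a0 < 0:
        a0, a1 = 0.0, max(float(np.mean(yb)), 0.0)
    a0, a1 = max(float(a0), 0.0), max(float(a1), 0.0)
    return lambda mu: a1 + a0 / np.maximum(np.asarray(mu, dtype=float), 1e-12)


def _log_nb_pmf(k: np.ndarray, mu: float, var: float) -> np.ndarray:
    """log pmf of an NB with given mean/variance; Poisson when var <= mu."""
    if mu <= 0:
        # degenerate at zero
        return np.where(k == 0, 0.0, -np.inf)
    if var <= mu * (1 + 1e-12):
        return stats.poisson.logpmf(k, mu)
    r = mu * mu / (var - mu)
    p = r / (r + mu)
    return stats.nbinom.logpmf(k, r, p)


def nb_exact_test(k_a: int, k_b: int, mu_a: float, mu_b: float,
                  var_a: float, var_b: float,
                  max_total: int = MAX_ENUMERATION_TOTAL) -> float:
    """Two-sided exact conditional NB test on two condition sums.

    ``k_a``/``k_b`` are the observed raw count sums; ``mu``/``var`` the fitted
    null mean and variance of each sum.  The p-value is the probability, over
    all splits (a, b) of the total T = k_a + k_b, of splits no more likely
    than the observed one, normalised by the total probability of all splits.
    """
    for k in (k_a, k_b):
        if k != int(k) or k < 0:
            raise ValueError(f"condition sums must be non-negative integers, got {k}")
    k_a, k_b = int(k_a), int(k_b)
    total = k_a + k_b
    if total == 0:
        return 1.0
    if total > max_total:
        return _normal_approx_p(k_a, total, mu_a, mu_b, var_a, var_b)
    a = np.arange(total + 1)
    log_joint = _log_nb_pmf(a, mu_a, var_a) + _log_nb_pmf(total - a, mu_b, var_b)
    log_obs = log_joint[k_a]
    finite = log_joint > -np.inf
    if not np.isfinite(log_obs):
        return 1.0 if not finite.any() else 0.0
    # small relative tolerance so float ties with the observed split count
    keep = log_joint <= log_obs + 1e-7
    num = _logsumexp(log_joint[keep & finite])
    den = _logsumexp(log_joint[finite])
    return float(np.clip(np.exp(num - den), 0.0, 1.0))


def _logsumexp(x: np.ndarray) -> float:
    if x.size == 0:
        return -np.inf
    m = x.max()
    return float(m + np.log(np.exp(x - m).sum()))


def _normal_approx_p(k_a: int, total: int, mu_a: float, mu_b: float,
                     var_a: float, var_b: float) -> float:
    """Normal approximation to the conditional split distribution.

    For X + Y = T with X, Y approximately normal, X | T is normal with mean
    mu_a + (T - mu_a - mu_b) * var_a / (var_a + var_b) and variance
    var_a * var_b / (var_a + var_b).
    """
    logger.info("nb_exact_test: total %d exceeds enumeration cap, using normal approximation", total)
    w = var_a / (var_a + var_b)
    mean = mu_a + (total - mu_a - mu_b) * w
    sd = np.sqrt(var_a * var_b / (var_a + var_b))
    z = (abs(k_a - mean) - 0.5) / sd  # continuity correction
    return float(np.clip(2 * stats.norm.sf(max(z, 0.0)), 0.0, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_calls(log2fc: np.ndarray, fdr: np.ndarray,
                   lfc_min: float = 0.585, fdr_max: float = 0.05) -> np.ndarray:
    """Dual-threshold direction call: up/down/ns."""
    log2fc = np.asarray(log2fc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    call = np.full(log2fc.shape, "ns", dtype=object)
    sig = fdr <= fdr_max
    call[sig & (log2fc >= lfc_min)] = "up"
    call[sig & (log2fc <= -lfc_min)] = "down"
    return call


def call_degs(cm: CountMatrix, lfc_min: float = 0.585, fdr_max: float = 0.05,
              dispersion_floor: float = DISPERSION_FLOOR) -> pd.DataFrame:
    """Run the full differential-expression screen.

    Returns a per-gene DataFrame with columns base_mean_A, base_mean_B,
    log2fc (B over A, pseudocount 1 on both normalized means), p_value, fdr
    and call.  Genes with zero counts in every sample are dropped before
    testing; they are listed in ``result.attrs["dropped_all_zero"]`` together
    with the run metadata (thresholds, dispersion method, test sidedness).
    """
    nonzero = cm.counts.sum(axis=1) > 0
    dropped = list(cm.gene_ids[~nonzero])
    counts = cm.counts.loc[nonzero]
    filtered = CountMatrix(counts, cm.condition)

    s = estimate_size_factors(filtered)
    m, v = _pooled_moments(filtered, s)
    raw_alpha = _raw_dispersion(m, v)
    trend = fit_dispersion_trend(m, raw_alpha)
    # conservative rule: test each gene at max(own estimate, fitted trend)
    alpha_test = np.maximum(raw_alpha, trend(m) if trend is not None else 0.0)
    alpha_test = np.maximum(alpha_test, dispersion_floor)

    norm = counts.to_numpy(dtype=float) / s.to_numpy()
    cond = filtered.condition.to_numpy()
    cols_a = cond == "A"
    cols_b = cond == "B"
    q0 = norm.mean(axis=1)  # pooled per-gene mean of normalized counts
    s_arr = s.to_numpy()

    base_a = norm[:, cols_a].mean(axis=1)
    base_b = norm[:, cols_b].mean(axis=1)
    log2fc = np.log2((base_b + 1.0) / (base_a + 1.0))

    raw = counts.to_numpy()
    k_a = raw[:, cols_a].sum(axis=1)
    k_b = raw[:, cols_b].sum(axis=1)
    sum_s_a = s_arr[cols_a].sum()
    sum_s_b = s_arr[cols_b].sum()
    alpha_arr = alpha_test

    p = np.empty(counts.shape[0])
    for i in range(counts.shape[0]):
        mu_a = q0[i] * sum_s_a
        mu_b = q0[i] * sum_s_b
        var_a = float((s_arr[cols_a] * q0[i] + alpha_arr[i] * (s_arr[cols_a] * q0[i]) ** 2).sum())
        var_b = float((s_arr[cols_b] * q0[i] + alpha_arr[i] * (s_arr[cols_b] * q0[i]) ** 2).sum())
        p[i] = nb_exact_test(int(k_a[i]), int(k_b[i]), mu_a, mu_b, var_a, var_b)

    fdr = bh_adjust(p)
    call = classify_calls(log2fc, fdr, lfc_min=lfc_min, fdr_max=fdr_max)

    table = pd.DataFrame(
        {
            "base_mean_A": base_a,
            "base_mean_B": base_b,
            "log2fc": log2fc,
            "p_value": p,
            "fdr": fdr,
            "call": call,
        },
        index=counts.index.rename("gene"),
    )
    table.attrs.update(
        dropped_all_zero=dropped,
        lfc_min=lfc_min,
        fdr_max=fdr_max,
        dispersion_method="per-gene pooled method-of-moments, tested at max(per-gene, mean-dispersion trend)",
        test="exact conditional NB, two-sided",
        size_factors=s.to_dict(),
    )
    return table


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
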