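"""Differential expression between tissue groups.

Two engines:

* :func:`nb_test` — an exact-style conditional negative-binomial test on
  library-equalized group sums with a pluggable common dispersion, for
  well-separated samples;
* :func:`purity_adjusted_de` — a transparent linear-unmixing estimator for
  imperfectly enriched samples: per gene, library-normalized expression is
  regressed on the two-column design [pi, 1-pi] (pi = BS purity), giving
  direct estimates of the pure-tissue expressions, whose contrast is
  t-tested.  This undoes the attenuation that cross-contamination imposes
  on naive group-ratio fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DispersionEstimate:
    phi: float
    method: str
    n_samples: int


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _normalized(counts: pd.DataFrame, lib_sizes: pd.Series | None) -> tuple[pd.DataFrame, pd.Series]:
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = lib_sizes.reindex(counts.columns)
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    mean_lib = float(lib_sizes.mean())
    return counts.mul(mean_lib / lib_sizes, axis=1), lib_sizes


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: dict[str, list[str]],
    lib_sizes: pd.Series | None = None,
    min_mean: float = 1.0,
) -> DispersionEstimate:
    """Method-of-moments common dispersion from replicated groups.

    Counts are scaled to the mean library size; within each replicated
    group the per-gene sample variance is pooled, and
    phi = max(0, mean over genes of (s^2 - mu) / mu^2).  Genes with mean
    normalized count below ``min_mean`` are ignored (the ratio is unstable
    there).  Raises if no group has two or more samples, instructing the
    caller to supply a dispersion from elsewhere.
    """
    norm, _ = _normalized(counts, lib_sizes)
    replicated = {g: s for g, s in groups.items() if len(s) >= 2}
    if not replicated:
        raise ValueError(
            "no replicated group: supply a common dispersion estimated from other data"
        )
    n_used = 0
    ss = np.zeros(counts.shape[0])
    df_total = 0
    means = []
    for g, sample_ids in replicated.items():
        sub = norm[sample_ids].to_numpy()
        centered = sub - sub.mean(axis=1, keepdims=True)
        ss += (centered**2).sum(axis=1)
        df_total += sub.shape[1] - 1
        means.append(sub.mean(axis=1))
        n_used += sub.shape[1]
    mu = np.mean(means, axis=0)
    s2 = ss / df_total
    ok = mu >= min_mean
    if not ok.any():
        raise ValueError("no gene passes the minimum-mean filter")
    phi_g = (s2[ok] - mu[ok]) / mu[ok] ** 2
    phi = max(0.0, float(phi_g.mean()))
    return DispersionEstimate(phi=phi, method="moments_common", n_samples=n_used)


def _conditional_nb_p(ya: int, yb: int, n_a: int, n_b: int, mu: float, phi: float) -> float:
    """Two-sided p for the observed split (ya, yb) of s = ya + yb reads.

    Group sums are NB with mean n*mu and dispersion phi/n; conditioning on
    the total gives a discrete distribution over splits, and the p-value
    sums the probabilities of all splits at most as probable as the one
    observed (the standard two-sided exact-test rule).  phi = 0 reduces to
    the binomial split of a Poisson total.
    """
    s = ya + yb
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if phi == 0.0:
        logp = stats.binom.logpmf(k, s, n_a / (n_a + n_b))
    else:
        ra, rb = n_a / phi, n_b / phi
        pa = ra / (ra + n_a * mu)
        pb = rb / (rb + n_b * mu)
        logp = stats.nbinom.logpmf(k, ra, pa) + stats.nbinom.logpmf(s - k, rb, pb)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[ya]
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-9)].sum()))


def nb_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    phi: float,
    lib_sizes: pd.Series | None = None,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Exact-style NB test of group A vs B per gene, log2fc = A minus B.

    Counts are scaled to the mean library size and rounded, group sums are
    formed, and the split of the total is tested conditionally at the
    supplied common dispersion.  Fold changes come from the normalized
    group means with a ``pseudo_count`` offset (on the mean-library count
    scale), so they are finite at zeros.
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    norm, _ = _normalized(counts, lib_sizes)
    n_a, n_b = len(group_a), len(group_b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups need at least one sample")
    a = norm[group_a].to_numpy()
    b = norm[group_b].to_numpy()
    ya = np.rint(a.sum(axis=1)).astype(np.int64)
    yb = np.rint(b.sum(axis=1)).astype(np.int64)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_a + pseudo_count) / (mean_b + pseudo_count))
    pvals = np.ones(counts.shape[0])
    for i in range(counts.shape[0]):
        s = ya[i] + yb[i]
        if s == 0:
            log2fc[i] = 0.0
            continue
        mu = s / (n_a + n_b)
        pvals[i] = _conditional_nb_p(int(ya[i]), int(yb[i]), n_a, n_b, mu, phi)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": bh_fdr(pvals),
            "mean_norm": (mean_a * n_a + mean_b * n_b) / (n_a + n_b),
        }
    ).reset_index(drop=True)


def purity_adjusted_de(
    counts: pd.DataFrame,
    purities: pd.Series,
    lib_sizes: pd.Series | None = None,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Linear-unmixing DE for imperfectly enriched samples.

    ``purities`` maps sample id -> BS purity pi in [0, 1].  Per gene,
    library-normalized expression y_r is least-squares fitted to
    y_r = pi_r * B + (1 - pi_r) * M; the (nonnegativity-clipped) pure
    estimates give log2fc = log2((B+c)/(M+c)) and the unclipped contrast
    B - M is t-tested against 0 using the residual variance on n-2 df.
    """
    purities = purities.reindex(counts.columns)
    if purities.isna().any():
        raise ValueError("every sample needs a purity")
    pi = purities.to_numpy(dtype=float)
    if ((pi < 0) | (pi > 1)).any():
        raise ValueError("purities must lie in [0, 1]")
    if np.ptp(pi) == 0:
        raise ValueError("design singular: all purities identical")
    norm, _ = _normalized(counts, lib_sizes)
    y = norm.to_numpy(dtype=float)  # genes x samples
    X = np.column_stack([pi, 1.0 - pi])  # samples x 2
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for the residual t test")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = y @ X @ xtx_inv.T  # genes x 2: (B_hat, M_hat)
    resid = y - beta @ X.T
    dof = n - 2
    sigma2 = (resid**2).sum(axis=1) / dof
    c = np.array([1.0, -1.0])
    var_contrast = sigma2 * float(c @ xtx_inv @ c)
    diff = beta[:, 0] - beta[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var_contrast > 0, diff / np.sqrt(var_contrast), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df=dof)
    pvals = np.clip(pvals, 0.0, 1.0)
    b_hat = np.clip(beta[:, 0], 0.0, None)
    m_hat = np.clip(beta[:, 1], 0.0, None)
    log2fc = np.log2((b_hat + pseudo_count) / (m_hat + pseudo_count))
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": log2fc,
            "p_value": pvals,
            "fdr": bh_fdr(pvals),
            "mean_norm": y.mean(axis=1),
            "bs_pure": b_hat,
            "m_pure": m_hat,
        }
    ).reset_index(drop=True)


def naive_attenuated_log2fc(true_ratio: float, pi: float) -> float:
    """Closed-form attenuation of a true BS:M ratio F under a pi/(1-pi) design.

    A 'BS' sample at purity pi and an 'M' sample at purity 1-pi measure
    mixtures whose ratio is (pi*F + 1 - pi) / ((1-pi)*F + pi); naive group
    fold changes converge to this instead of F.
    """
    f = float(true_ratio)
    return float(np.log2((pi * f + 1 - pi) / ((1 - pi) * f + pi)))
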