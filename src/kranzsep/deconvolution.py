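"""Marker-anchored deconvolution of mixed-tissue abundance profiles.

The estimator: within one developmental slice, convert every analyte's
values to fraction-of-total across the enrichment fractions, use the
M-marker (PEPC activity) and BS-marker (NADP-ME activity) profiles as
proxies for tissue amounts, and regress ln(target/M) on ln(BS/M) by
ordinary least squares.  The slope estimates the fraction of the target
found in pure BS; its departure from the 50/50 null (slope = 0.5) is
tested with a t statistic on n-2 degrees of freedom.  Pure-tissue
abundances are reconstructed as slope * 2 * mean and (1-slope) * 2 * mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .quantify import fraction_of_total


@dataclass
class DeconvResult:
    analyte_id: str
    slice: int
    slope_b: float
    se: float
    t_stat: float
    p_value: float
    n_points: int
    bs_pure: float
    m_pure: float
    clamped: bool = False


def marker_profiles(
    activity: pd.DataFrame,
    m_marker_id: str,
    bs_marker_id: str,
    slice: int,
) -> tuple[pd.Series, pd.Series]:
    """Fraction-of-total profiles of the two marker enzymes in one slice.

    Both series are indexed by (fraction, replicate) and each sums to 1 per
    replicate.  A missing or zero marker measurement is an error because the
    downstream log-ratios would be undefined.
    """
    sl = activity[activity["slice"] == slice]
    out = []
    for marker in (m_marker_id, bs_marker_id):
        rows = sl[sl["analyte"] == marker]
        if len(rows) == 0:
            raise ValueError(f"marker {marker!r} absent from slice {slice}")
        if (rows["value"] <= 0).any():
            raise ValueError(f"marker {marker!r} has non-positive values in slice {slice}")
        frac = fraction_of_total(rows)
        prof = frac.set_index(["fraction", "replicate"])["value"].sort_index()
        out.append(prof)
    m_prof, b_prof = out
    if not m_prof.index.equals(b_prof.index):
        raise ValueError("marker profiles are not aligned on (fraction, replicate)")
    return m_prof, b_prof


def estimate_fraction_bs(
    target: pd.Series | np.ndarray,
    m_profile: pd.Series | np.ndarray,
    b_profile: pd.Series | np.ndarray,
) -> tuple[float, float, float, int]:
    """OLS slope of ln(target/M) on ln(BS/M): the target's fraction in pure BS.

    Returns (slope, se, intercept, n).  Natural log, intercept included.
    """
    t = np.asarray(target, dtype=float)
    m = np.asarray(m_profile, dtype=float)
    b = np.asarray(b_profile, dtype=float)
    if not (len(t) == len(m) == len(b)):
        raise ValueError("profiles must be aligned")
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 points for the regression")
    if (t <= 0).any() or (m <= 0).any() or (b <= 0).any():
        raise ValueError("profiles must be strictly positive (log ratios)")
    x = np.log(b / m)
    y = np.log(t / m)
    if np.ptp(x) == 0:
        raise ValueError("markers not separated (BS/M ratio constant across points)")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.stderr), float(fit.intercept), n


def slope_test(slope_b: float, se: float, n_points: int) -> tuple[float, float]:
    """Two-sided t test of the slope against the 50/50 null (slope = 0.5)."""
    if n_points < 3:
        raise ValueError("need n_points >= 3")
    if se < 0:
        raise ValueError("se must be non-negative")
    if se == 0:
        # degenerate exact fit: conventionally certain
        return (np.inf if slope_b != 0.5 else 0.0), (0.0 if slope_b != 0.5 else 1.0)
    t = (slope_b - 0.5) / se
    p = 2.0 * stats.t.sf(abs(t), df=n_points - 2)
    return float(t), float(min(p, 1.0))


def pure_abundances(slope_b: float, slice_mean: float) -> tuple[float, float, bool]:
    """Reconstruct pure-tissue abundances as (b * 2*mean, (1-b) * 2*mean).

    The slope is clamped to [0, 1] for this reconstruction only (never for
    the test statistic); the flag reports whether clamping occurred.
    """
    if slice_mean < 0:
        raise ValueError("slice mean must be non-negative")
    b = min(max(slope_b, 0.0), 1.0)
    return b * 2.0 * slice_mean, (1.0 - b) * 2.0 * slice_mean, b != slope_b


def deconvolve(
    activity: pd.DataFrame,
    m_marker_id: str,
    bs_marker_id: str,
    pooled: bool = True,
    fdr_min_tests: int = 0,
) -> pd.DataFrame:
    """Deconvolve every non-marker analyte in every slice of a table.

    ``pooled=True`` (default) pools all fraction x replicate points of a
    slice into one regression; ``pooled=False`` regresses on replicate means
    (3 points for a 3-fraction design).  A BH-FDR column is always included;
    the >20-tests reporting convention is the caller's concern.
    """
    results: list[DeconvResult] = []
    for sl in sorted(activity["slice"].unique()):
        m_prof, b_prof = marker_profiles(activity, m_marker_id, bs_marker_id, slice=sl)
        sl_table = activity[activity["slice"] == sl]
        for analyte in sorted(sl_table["analyte"].unique()):
            if analyte in (m_marker_id, bs_marker_id):
                continue
            rows = sl_table[sl_table["analyte"] == analyte]
            frac = fraction_of_total(rows)
            t_prof = frac.set_index(["fraction", "replicate"])["value"].sort_index()
            if not t_prof.index.equals(m_prof.index):
                raise ValueError(
                    f"analyte {analyte!r} not aligned with markers in slice {sl}"
                )
            if pooled:
                t, m, b = t_prof, m_prof, b_prof
            else:
                t = t_prof.groupby(level="fraction").mean()
                m = m_prof.groupby(level="fraction").mean()
                b = b_prof.groupby(level="fraction").mean()
            slope, se, _, n = estimate_fraction_bs(t, m, b)
            t_stat, p = slope_test(slope, se, n)
            abar = float(rows["value"].mean())
            bs_pure, m_pure, clamped = pure_abundances(slope, abar)
            results.append(
                DeconvResult(analyte, sl, slope, se, t_stat, p, n, bs_pure, m_pure, clamped)
            )
    df = pd.DataFrame([r.__dict__ for r in results])
    if len(df) > 0 and len(df) >= fdr_min_tests:
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df
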