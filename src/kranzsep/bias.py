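"""Per-gene and per-sample 3'-coverage-bias metrics.

RNA degradation with 3'-end retention inflates coverage near the 3' end of
transcripts.  The metric used throughout: mean coverage over the 3'-most
``window`` bases divided by mean coverage over the whole transcript.  A
uniform profile scores 1; degradation pushes the score above 1, bounded by
length/window.  Transcripts shorter than 2*window, or without coverage,
are excluded (and logged) because the ratio is then meaningless.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 100
DEFAULT_TOP_N = 1000


def gene_three_prime_bias(depth: np.ndarray, window: int = DEFAULT_WINDOW) -> float:
    """3' bias of one coverage profile (0-based, 5'->3').

    Returns NaN for transcripts shorter than 2*window or with zero mean
    coverage.
    """
    depth = np.asarray(depth, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if (depth < 0).any():
        raise ValueError("coverage must be non-negative")
    L = len(depth)
    if L < 2 * window:
        return float("nan")
    total_mean = depth.mean()
    if total_mean <= 0:
        return float("nan")
    return float(depth[L - window :].mean() / total_mean)


def bias_table(
    coverage: dict[str, dict[str, np.ndarray]] | pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Compute bias3 and mean coverage for every (gene, sample) profile.

    ``coverage`` is either a nested dict sample_id -> gene_id -> depth
    vector, or a long DataFrame with columns (gene_id, sample_id, pos,
    depth).  Returns a long table (gene_id, sample_id, bias3, mean_cov);
    bias3 is NaN where undefined.
    """
    rows = []
    if isinstance(coverage, pd.DataFrame):
        nested: dict[str, dict[str, np.ndarray]] = {}
        for (g, s), grp in coverage.groupby(["gene_id", "sample_id"], sort=True):
            nested.setdefault(s, {})[g] = grp.sort_values("pos")["depth"].to_numpy()
        coverage = nested
    for sample_id in sorted(coverage):
        for gene_id in sorted(coverage[sample_id]):
            depth = np.asarray(coverage[sample_id][gene_id], dtype=float)
            rows.append(
                {
                    "gene_id": gene_id,
                    "sample_id": sample_id,
                    "bias3": gene_three_prime_bias(depth, window=window),
                    "mean_cov": float(depth.mean()) if len(depth) else 0.0,
                }
            )
    return pd.DataFrame(rows)


def sample_bias_summary(
    bias: pd.DataFrame,
    expression: pd.DataFrame,
    top_n: int = DEFAULT_TOP_N,
) -> pd.Series:
    """Median bias3 over each sample's ``top_n`` most expressed genes.

    ``expression`` is a TPM matrix (genes x samples).  Samples with fewer
    than ``top_n`` genes with a defined bias use all of them (with a
    warning via the returned count being smaller, not an exception).
    """
    out = {}
    for sample_id, grp in bias.groupby("sample_id"):
        defined = grp.dropna(subset=["bias3"])
        if sample_id in expression.columns:
            expr = expression[sample_id].reindex(defined["gene_id"]).fillna(0.0)
            order = expr.sort_values(ascending=False, kind="stable")
            chosen = set(order.index[:top_n])
            vals = defined.loc[defined["gene_id"].isin(chosen), "bias3"]
        else:
            vals = defined["bias3"]
        out[sample_id] = float(vals.median()) if len(vals) else float("nan")
    return pd.Series(out, name="median_bias3").sort_index()


def set_bias_profile(
    bias: pd.DataFrame,
    gene_sets: dict[str, set | list],
    background_name: str = "background",
) -> pd.DataFrame:
    """Median and IQR of bias3 per gene set per sample.

    The full gene universe (all genes with a defined bias in the sample) is
    always included as the background row.  Empty sets produce NaN rows.
    """
    sets = {background_name: None, **{k: set(v) for k, v in gene_sets.items()}}
    rows = []
    for sample_id, grp in bias.groupby("sample_id"):
        defined = grp.dropna(subset=["bias3"])
        for name, members in sets.items():
            sub = defined if members is None else defined[defined["gene_id"].isin(members)]
            if len(sub) == 0:
                rows.append(
                    {
                        "set": name,
                        "sample_id": sample_id,
                        "n": 0,
                        "median_bias3": float("nan"),
                        "iqr_bias3": float("nan"),
                    }
                )
                continue
            q1, med, q3 = np.percentile(sub["bias3"], [25, 50, 75])
            rows.append(
                {
                    "set": name,
                    "sample_id": sample_id,
                    "n": int(len(sub)),
                    "median_bias3": float(med),
                    "iqr_bias3": float(q3 - q1),
                }
            )
    return pd.DataFrame(rows)
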