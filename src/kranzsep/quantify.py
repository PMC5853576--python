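"""Expression and analyte normalization: TPM, fraction-of-total, filters."""

from __future__ import annotations

import pandas as pd

from .containers import CountMatrix


def compute_tpm(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts per million from counts and gene lengths.

    tpm_gs = 1e6 * (c_gs / l_g) / sum_g(c_gs / l_g).  Every column sums to
    1e6; a gene with zero counts has TPM 0.  A sample with no counts at all
    is an error (its TPM is undefined).
    """
    rate = counts.counts.div(counts.lengths, axis=0)
    total = rate.sum(axis=0)
    zero = total[total <= 0]
    if len(zero) > 0:
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return 1e6 * rate.div(total, axis=1)


def fraction_of_total(
    df: pd.DataFrame,
    value_col: str = "value",
    group_cols: tuple = ("analyte", "slice", "replicate"),
) -> pd.DataFrame:
    """Convert values to fractions of their group total.

    Within each group (default: one analyte/slice/replicate across the
    enrichment fractions) the values are divided by the group sum so they
    sum to 1.  Groups with no positive value are an error.
    """
    out = df.copy()
    totals = out.groupby(list(group_cols))[value_col].transform("sum")
    if (totals <= 0).any():
        bad = out.loc[totals <= 0, list(group_cols)].drop_duplicates()
        raise ValueError(f"group(s) with non-positive total: {bad.to_dict('records')[:3]}")
    out[value_col] = out[value_col] / totals
    return out


def normalize_metabolite_peaks(
    df: pd.DataFrame,
    peak_col: str = "peak",
    ribitol_col: str = "ribitol",
    fw_col: str = "fresh_weight",
    replicate_cols: tuple = ("slice", "fraction", "replicate"),
    value_col: str = "value",
) -> pd.DataFrame:
    """Two-stage metabolite normalization.

    Each integrated peak is divided by the internal-standard (ribitol) peak
    area and the fresh weight of its extraction, then by the mean over all
    analytes measured in the same physical replicate.  By construction the
    per-replicate mean of the result is 1, so values express distribution
    relative to the other (dominantly high-abundance) metabolites.
    """
    if (df[ribitol_col] <= 0).any():
        raise ValueError("ribitol peak areas must be positive")
    if (df[fw_col] <= 0).any():
        raise ValueError("fresh weights must be positive")
    out = df.copy()
    v1 = out[peak_col] / (out[ribitol_col] * out[fw_col])
    rep_mean = v1.groupby([out[c] for c in replicate_cols]).transform("mean")
    out[value_col] = v1 / rep_mean
    return out


def percent_bs(
    table: pd.DataFrame,
    bs_fraction: str = "BS_e",
    m_fraction: str = "M_e",
) -> pd.DataFrame:
    """Per-replicate percentage abundance in BS: BS_e / (BS_e + M_e).

    The intermediate fraction is ignored for this statistic.  Returns one
    row per (analyte, slice, replicate).
    """
    wide = table.pivot_table(
        index=["analyte", "slice", "replicate"], columns="fraction", values="value"
    )
    for col in (bs_fraction, m_fraction):
        if col not in wide.columns:
            raise ValueError(f"fraction {col!r} missing from table")
    pct = wide[bs_fraction] / (wide[bs_fraction] + wide[m_fraction])
    return pct.rename("pct_bs").reset_index()


def filter_metabolites(
    table: pd.DataFrame,
    min_signal: float | None = None,
    min_signal_quantile: float = 0.05,
    k_sd: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-signal analytes, then outlying replicates.

    An analyte is low-signal when its maximum value falls below
    ``min_signal`` (default: the ``min_signal_quantile`` quantile of the
    per-analyte maxima).  A replicate of an analyte/slice is an outlier when
    its percentage abundance in BS deviates from the mean across replicates
    by more than ``k_sd`` standard deviations; with SD = 0 nothing is
    excluded.  Returns the filtered table and an exclusion log that, with
    the output, reconstructs the input row set.
    """
    log_rows = []
    maxima = table.groupby("analyte")["value"].max()
    if min_signal is None:
        min_signal = float(maxima.quantile(min_signal_quantile))
    low = set(maxima.index[maxima < min_signal])
    kept = table[~table["analyte"].isin(low)].copy()
    for a in sorted(low):
        log_rows.append(
            {"analyte": a, "slice": pd.NA, "replicate": pd.NA, "reason": "low_signal"}
        )

    if len(kept) > 0:
        pct = percent_bs(kept)
        grp = pct.groupby(["analyte", "slice"])["pct_bs"]
        mean = grp.transform("mean")
        sd = grp.transform("std").fillna(0.0)
        outlier = (sd > 0) & ((pct["pct_bs"] - mean).abs() > k_sd * sd)
        bad = pct.loc[outlier, ["analyte", "slice", "replicate"]]
        if len(bad) > 0:
            key_cols = ["analyte", "slice", "replicate"]
            bad_keys = set(map(tuple, bad[key_cols].to_numpy()))
            mask = kept[key_cols].apply(tuple, axis=1).isin(bad_keys)
            kept = kept[~mask]
            for a, sl, rep in sorted(bad_keys):
                log_rows.append(
                    {"analyte": a, "slice": sl, "replicate": rep, "reason": "pct_bs_outlier"}
                )
    log = pd.DataFrame(log_rows, columns=["analyte", "slice", "replicate", "reason"])
    return kept.reset_index(drop=True), log
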