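"""Cross-study harmonization and artifact diagnostics.

Fold changes from different studies are made comparable by quantile
normalization; tissue TPM pairs are back-calculated from the normalized
log2 fold change and the stage mean TPM; conflict sets collect genes
called tissue-specific in opposite directions by two studies; agreement
fractions, Fisher overlap tests, sample/gene clustering, and the
developmental-switch support analysis complete the meta-analysis toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from .diffexpr import estimate_common_dispersion, nb_test


def fisher_two_sided_p(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# fold-change harmonization


def quantile_normalize_lfc(lfc: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize the columns of a gene x study fold-change matrix.

    After normalization each column's sorted values equal the across-column
    mean of sorted values; tied entries receive the mean of the reference
    values their ranks span.  Within-column ranks are preserved exactly.
    """
    if lfc.shape[1] < 2:
        raise ValueError("need at least 2 studies to quantile normalize")
    arr = lfc.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("fold-change matrix must be complete (inner-join genes first)")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 genes")
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    return pd.DataFrame(out, index=lfc.index, columns=lfc.columns)


def back_calculate_tpm(lfc_norm, mean_tpm):
    """Tissue TPM pair from normalized log2FC and mean TPM.

    tpm_bs = 2m * 2^l / (1 + 2^l), tpm_m = 2m / (1 + 2^l), so that the
    arithmetic mean is m and the log2 ratio is l, exactly.  m = 0 yields
    (0, 0).
    """
    l = np.asarray(lfc_norm, dtype=float)
    m = np.asarray(mean_tpm, dtype=float)
    if (m < 0).any():
        raise ValueError("mean TPM must be non-negative")
    r = np.exp2(l)
    tpm_bs = 2.0 * m * r / (1.0 + r)
    tpm_m = 2.0 * m / (1.0 + r)
    return tpm_bs, tpm_m


# ---------------------------------------------------------------------------
# conflict sets


@dataclass
class ConflictSets:
    set1: list  # BS-significant in study A, M-significant in study B
    set2: list  # the mirror image
    pairing: list
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_conflict_sets(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    pairing: list[tuple[str, str]],
    alpha: float = 0.05,
    sig_col: str = "fdr",
) -> ConflictSets:
    """Genes significantly tissue-enriched in opposite directions.

    set1: significant BS (log2fc > 0) in study A and significant M
    (log2fc < 0) in study B for any designated stage pair; set2 is the
    mirror image.  ``sig_col`` selects the significance column ("fdr"
    default; "p_value" for per-test thresholding).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    stages_a = set(res_a["stage_id"].unique())
    stages_b = set(res_b["stage_id"].unique())
    set1: set = set()
    set2: set = set()
    prov_rows = []
    for sa, sb in pairing:
        if sa not in stages_a:
            raise ValueError(f"stage {sa!r} not present in study A")
        if sb not in stages_b:
            raise ValueError(f"stage {sb!r} not present in study B")
        a = res_a[res_a["stage_id"] == sa].set_index("gene_id")
        b = res_b[res_b["stage_id"] == sb].set_index("gene_id")
        shared = a.index.intersection(b.index)
        a, b = a.loc[shared], b.loc[shared]
        sig_a = a[sig_col] < alpha
        sig_b = b[sig_col] < alpha
        s1 = shared[(sig_a & (a["log2fc"] > 0) & sig_b & (b["log2fc"] < 0))]
        s2 = shared[(sig_a & (a["log2fc"] < 0) & sig_b & (b["log2fc"] > 0))]
        set1.update(s1)
        set2.update(s2)
        for g in s1:
            prov_rows.append({"gene_id": g, "set": "set1", "stage_a": sa, "stage_b": sb})
        for g in s2:
            prov_rows.append({"gene_id": g, "set": "set2", "stage_a": sa, "stage_b": sb})
    return ConflictSets(
        set1=sorted(set1),
        set2=sorted(set2),
        pairing=list(pairing),
        provenance=pd.DataFrame(prov_rows, columns=["gene_id", "set", "stage_a", "stage_b"]),
    )


# ---------------------------------------------------------------------------
# degradation-sensitive genes


def degradation_sensitive_genes(
    counts: pd.DataFrame,
    separated: list[str],
    unseparated: list[str],
    phi: float | None = None,
    alpha: float = 0.05,
) -> tuple[list, list, pd.DataFrame]:
    """Genes significantly lower/higher in separated vs unseparated samples.

    Mirrors the detection of degradation-affected genes by contrasting a
    harsh separation protocol against matched unseparated tissue.  Returns
    (down, up, full DE table); ``down`` is the degradation-sensitive list.
    """
    if phi is None:
        groups = {"sep": separated, "unsep": unseparated}
        phi = estimate_common_dispersion(counts, groups).phi
    de = nb_test(counts, separated, unseparated, phi=phi)
    sig = de["fdr"] < alpha
    down = sorted(de.loc[sig & (de["log2fc"] < 0), "gene_id"])
    up = sorted(de.loc[sig & (de["log2fc"] > 0), "gene_id"])
    return down, up, de


# ---------------------------------------------------------------------------
# ortholog agreement and overlap tests


def agreement_fraction(
    gene_directions: pd.Series,
    ortholog_map: dict | pd.Series,
    other: pd.DataFrame,
) -> tuple[int, int, float]:
    """Fraction of genes whose orthologs go the same way in another study.

    ``gene_directions`` maps gene id -> direction ("BS" or "M").  Direction
    in the other study is the sign of the ortholog's log2fc regardless of
    significance.  Genes without an ortholog, or whose ortholog has no
    finite fold change, leave the denominator.  Returns
    (n_mapped, n_same_direction, fraction); fraction is NaN when nothing
    maps.
    """
    bad = set(gene_directions.unique()) - {"BS", "M"}
    if bad:
        raise ValueError(f"directions must be 'BS' or 'M', got {sorted(bad)}")
    if isinstance(ortholog_map, pd.Series):
        ortholog_map = ortholog_map.to_dict()
    other_lfc = other.set_index("gene_id")["log2fc"]
    n_mapped = 0
    n_same = 0
    for gene, direction in gene_directions.items():
        target = ortholog_map.get(gene)
        if target is None or target not in other_lfc.index:
            continue
        lfc = other_lfc.loc[target]
        if not np.isfinite(lfc) or lfc == 0:
            continue
        n_mapped += 1
        other_dir = "BS" if lfc > 0 else "M"
        if other_dir == direction:
            n_same += 1
    frac = n_same / n_mapped if n_mapped else float("nan")
    return n_mapped, n_same, frac


def overlap_test(set_a, set_b, universe) -> tuple[float, float, np.ndarray]:
    """Two-sided Fisher exact test of the overlap of two gene sets.

    Table: [[|A∩B|, |A\\B|], [|B\\A|, |U\\(A∪B)|]].  Returns the conditional
    maximum-likelihood odds ratio, the p-value, and the 2x2 table.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    k = len(a & b)
    table = np.array(
        [[k, len(a) - k], [len(b) - k, len(universe) - len(a) - len(b) + k]],
        dtype=np.int64,
    )
    p = fisher_two_sided_p(table)
    odds = float(stats.contingency.odds_ratio(table, kind="conditional").statistic)
    return odds, p, table


# ---------------------------------------------------------------------------
# clustering


def _tree_from_linkage(link: np.ndarray, labels: list[str]) -> TreeNode:
    ids = list(labels)
    tree = TreeNode.from_linkage_matrix(link, ids)
    return tree


def cluster_samples(
    tpm: pd.DataFrame,
    min_tpm: float = 0.0,
    max_tpm: float = 50.0,
    linkage_method: str = "average",
) -> tuple[str, str, pd.DataFrame]:
    """Hierarchical clustering of log2 TPM with correlation distances.

    Genes are kept when every sample has TPM > ``min_tpm`` and at least one
    sample exceeds ``max_tpm``; the filtered matrix is log2-transformed.
    Distances are 1 - r with Pearson correlation for genes and Spearman for
    samples; linkage is average by default.  Returns Newick strings for the
    gene and sample trees plus the filtered (log2) matrix.
    """
    keep = (tpm > min_tpm).all(axis=1) & (tpm.max(axis=1) > max_tpm)
    filtered = tpm.loc[keep]
    if filtered.shape[0] == 0:
        raise ValueError("no genes survive the expression filter")
    if filtered.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    log_mat = np.log2(filtered)

    gene_corr = np.corrcoef(log_mat.to_numpy())
    gene_dist = np.clip(1.0 - gene_corr, 0.0, None)
    np.fill_diagonal(gene_dist, 0.0)
    gene_link = hierarchy.linkage(squareform(gene_dist, checks=False), method=linkage_method)

    rho = stats.spearmanr(log_mat.to_numpy(), axis=0)[0]
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two samples
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    samp_dist = np.clip(1.0 - rho, 0.0, None)
    np.fill_diagonal(samp_dist, 0.0)
    samp_link = hierarchy.linkage(squareform(samp_dist, checks=False), method=linkage_method)

    gene_tree = _tree_from_linkage(gene_link, list(log_mat.index))
    sample_tree = _tree_from_linkage(samp_link, list(log_mat.columns))
    return str(gene_tree).strip(), str(sample_tree).strip(), log_mat


# ---------------------------------------------------------------------------
# developmental switches


def developmental_switch_classification(
    young_a: pd.DataFrame,
    old_a: pd.DataFrame,
    young_b: pd.DataFrame,
    old_b: pd.DataFrame,
    alpha: float = 0.05,
    require_significance_in_b: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Cross-study support for developmental switches in tissue specificity.

    Genes significant (FDR < alpha) at both stages of study A are classified
    as ``consistent`` (same log2fc sign young and old) or ``switching``
    (opposite signs).  A gene is *supported* when study B shows the same
    signed pattern at the matching stages (sign only by default; set
    ``require_significance_in_b`` to also demand FDR < alpha in B).
    Returns (per-gene table, 2x2 class-by-support table, Fisher p).
    """
    ya = young_a.set_index("gene_id")
    oa = old_a.set_index("gene_id")
    yb = young_b.set_index("gene_id")
    ob = old_b.set_index("gene_id")
    shared = ya.index.intersection(oa.index).intersection(yb.index).intersection(ob.index)
    rows = []
    for g in shared:
        if not (ya.loc[g, "fdr"] < alpha and oa.loc[g, "fdr"] < alpha):
            continue
        sy, so = np.sign(ya.loc[g, "log2fc"]), np.sign(oa.loc[g, "log2fc"])
        if sy == 0 or so == 0:
            continue
        cls = "consistent" if sy == so else "switching"
        supported = (
            np.sign(yb.loc[g, "log2fc"]) == sy and np.sign(ob.loc[g, "log2fc"]) == so
        )
        if require_significance_in_b:
            supported = supported and yb.loc[g, "fdr"] < alpha and ob.loc[g, "fdr"] < alpha
        rows.append({"gene_id": g, "class": cls, "supported": bool(supported)})
    per_gene = pd.DataFrame(rows, columns=["gene_id", "class", "supported"])
    table = np.zeros((2, 2), dtype=np.int64)
    for i, cls in enumerate(["consistent", "switching"]):
        sub = per_gene[per_gene["class"] == cls]
        table[i, 0] = int(sub["supported"].sum())
        table[i, 1] = int((~sub["supported"]).sum())
    support_table = pd.DataFrame(
        table, index=["consistent", "switching"], columns=["supported", "unsupported"]
    )
    p = fisher_two_sided_p(table)
    return per_gene, support_table, p


def keyword_set_expression(
    tpm_pairs: pd.DataFrame,
    gene_set,
) -> pd.DataFrame:
    """Cumulative BS and M expression of a gene set per study/stage.

    ``tpm_pairs`` has columns (study_id, stage_id, gene_id, tpm_bs, tpm_m)
    from back-calculation.  Returns summed tpm_bs/tpm_m per study/stage.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    sub = tpm_pairs[tpm_pairs["gene_id"].isin(gene_set)]
    out = (
        sub.groupby(["study_id", "stage_id"], as_index=False)[["tpm_bs", "tpm_m"]]
        .sum()
        .sort_values(["study_id", "stage_id"])
        .reset_index(drop=True)
    )
    return out
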