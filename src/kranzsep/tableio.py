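"""Plain-text readers and writers for every table the pipeline exchanges.

Conventions: TSV/CSV with a header row, ``.`` as the NA token, decimal
points, 0-based half-open coordinates in bedGraph.  Readers validate the
schema and report offending ids / line numbers; writers are deterministic
(fixed float formatting, sorted where order is not meaningful).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, SAMPLE_LABELS

NA_TOKEN = "."
FLOAT_FORMAT = "%.10g"


def _read_table(path, sep, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, na_values=[NA_TOKEN], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# counts and lengths


def write_counts(cm: CountMatrix, counts_path, lengths_path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    lengths = cm.lengths.rename("length").to_frame()
    lengths.index.name = "gene_id"
    lengths.to_csv(lengths_path, sep="\t")


def read_counts(counts_path, lengths_path) -> CountMatrix:
    df = _read_table(counts_path, "\t", ("gene_id",))
    dup = df["gene_id"].duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        raise ValueError(
            f"{counts_path}: duplicate gene id {df['gene_id'][i]!r} at line {i + 2}"
        )
    counts = df.set_index("gene_id")
    bad_cols = [c for c in counts.columns if not np.issubdtype(counts[c].dtype, np.number)]
    if bad_cols:
        raise ValueError(f"{counts_path}: non-numeric column(s) {bad_cols}")
    lengths_df = _read_table(lengths_path, "\t", ("gene_id", "length"))
    lengths = lengths_df.set_index("gene_id")["length"]
    return CountMatrix(counts=counts.astype(np.int64), lengths=lengths.astype(np.int64))


# ---------------------------------------------------------------------------
# sample sheet / activity


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_sample_sheet(path) -> pd.DataFrame:
    df = _read_table(path, ",", ("sample_id", "study_id", "slice", "label", "lib_size"))
    unknown = set(df["label"]) - set(SAMPLE_LABELS)
    if unknown:
        raise ValueError(f"{path}: unknown sample label(s) {sorted(unknown)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def write_activity(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_activity(path) -> pd.DataFrame:
    df = _read_table(path, ",", ("analyte", "slice", "fraction", "replicate", "value"))
    if not np.issubdtype(df["value"].dtype, np.number):
        bad = df.index[pd.to_numeric(df["value"], errors="coerce").isna()]
        raise ValueError(f"{path}: non-numeric value at line {int(bad[0]) + 2}")
    dup = df.duplicated(["analyte", "slice", "fraction", "replicate"])
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        raise ValueError(f"{path}: duplicate measurement key at line {i + 2}")
    return df


# ---------------------------------------------------------------------------
# coverage: long TSV and bedGraph


def write_coverage_tsv(coverage: dict[str, dict[str, np.ndarray]], path) -> None:
    """Long-form coverage: sample_id, gene_id, pos, depth (0-based 5'->3')."""
    with open(path, "w") as fh:
        fh.write("sample_id\tgene_id\tpos\tdepth\n")
        for sample_id in sorted(coverage):
            for gene_id in sorted(coverage[sample_id]):
                depth = coverage[sample_id][gene_id]
                for pos, d in enumerate(depth):
                    fh.write(f"{sample_id}\t{gene_id}\t{pos}\t{FLOAT_FORMAT % d}\n")


def read_coverage_tsv(path) -> dict[str, dict[str, np.ndarray]]:
    df = _read_table(path, "\t", ("sample_id", "gene_id", "pos", "depth"))
    out: dict[str, dict[str, np.ndarray]] = {}
    for (s, g), grp in df.groupby(["sample_id", "gene_id"], sort=True):
        out.setdefault(s, {})[g] = grp.sort_values("pos")["depth"].to_numpy(dtype=float)
    return out


def write_bedgraph(profiles: dict[str, np.ndarray], path) -> None:
    """One synthetic 'chromosome' per gene, 0-based half-open, runs merged.

    Profiles must already be in 5'->3' orientation; pair the file with a
    strand map so minus-strand genes can be flipped back on ingestion.
    """
    with open(path, "w") as fh:
        for gene_id in sorted(profiles):
            depth = np.asarray(profiles[gene_id], dtype=float)
            start = 0
            for i in range(1, len(depth) + 1):
                if i == len(depth) or depth[i] != depth[start]:
                    fh.write(f"{gene_id}\t{start}\t{i}\t{FLOAT_FORMAT % depth[start]}\n")
                    start = i


def read_bedgraph(path, lengths: dict[str, int], strands: dict[str, str] | None = None) -> dict[str, np.ndarray]:
    """Read per-gene coverage; minus-strand genes are flipped to 5'->3'.

    ``lengths`` gives each gene's transcript length; ``strands`` maps gene
    id to '+'/'-' (default all '+').
    """
    out = {g: np.zeros(L, dtype=float) for g, L in lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}")
            gene_id, start, end, value = fields
            if gene_id not in out:
                raise ValueError(f"{path}: unknown gene {gene_id!r} at line {lineno}")
            out[gene_id][int(start) : int(end)] = float(value)
    if strands:
        for g, strand in strands.items():
            if strand == "-" and g in out:
                out[g] = out[g][::-1].copy()
            elif strand not in ("+", "-"):
                raise ValueError(f"invalid strand {strand!r} for gene {g!r}")
    return out


# ---------------------------------------------------------------------------
# maps and study results


def read_category_map(path) -> pd.DataFrame:
    """gene_id <TAB> dot-path category; multiple rows per gene allowed."""
    return _read_table(path, "\t", ("gene_id", "category"))


def write_category_map(df: pd.DataFrame, path) -> None:
    df[["gene_id", "category"]].to_csv(path, sep="\t", index=False)


def read_ortholog_map(path) -> pd.Series:
    df = _read_table(path, "\t", ("source", "target"))
    dup = df["source"].duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        raise ValueError(f"{path}: duplicate source gene at line {i + 2}")
    return df.set_index("source")["target"]


def write_ortholog_map(mapping: pd.Series | dict, path) -> None:
    if isinstance(mapping, dict):
        mapping = pd.Series(mapping)
    out = mapping.rename("target").to_frame()
    out.index.name = "source"
    out.sort_index().to_csv(path, sep="\t")


def write_study_result(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep=NA_TOKEN)


def read_study_result(path) -> pd.DataFrame:
    return _read_table(path, "\t", ("gene_id", "log2fc", "p_value", "fdr", "mean_tpm"))


def write_matrix(df: pd.DataFrame, path, index_name: str = "gene_id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep=NA_TOKEN)


# ---------------------------------------------------------------------------
# manifest


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, parameters: dict, outputs: list[str]) -> Path:
    """Record parameters and output hashes; the manifest hash itself changes
    iff any parameter or output content changes (no timestamps)."""
    outdir = Path(outdir)
    manifest = {
        "parameters": parameters,
        "outputs": {name: file_sha256(outdir / name) for name in sorted(outputs)},
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
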