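"""File formats: TSV/CSV matrices, Matrix Market single-cell counts, run
metadata.

Conventions: matrix files store genes as rows with the gene identifier in the
first column and sample (or cell-type) names in the header.  A combined
signature file uses ``<type>__mean`` / ``<type>__sd`` column pairs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csc_matrix

from .types import BulkMatrix

__all__ = [
    "read_bulk",
    "write_bulk",
    "read_signature",
    "read_combined_signature",
    "write_signature",
    "read_sc_counts",
    "write_sc_counts",
    "write_fractions",
    "write_purified",
    "write_metadata",
    "file_checksum",
]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_bulk(path: str | Path, log_input: bool = False) -> BulkMatrix:
    """Read a genes x samples bulk matrix from TSV/CSV.

    ``log_input=True`` declares the file log1p-normalized; values are
    exponentiated (expm1) to the linear scale on load.
    """
    df = _read_table(path)
    scale = "log" if log_input else "linear"
    bulk = BulkMatrix(df.to_numpy(float), df.index.astype(str).tolist(),
                      df.columns.astype(str).tolist(), scale)
    return bulk.to_linear() if log_input else bulk


def write_bulk(bulk: BulkMatrix, path: str | Path) -> None:
    df = pd.DataFrame(bulk.values, index=bulk.gene_ids, columns=bulk.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene")


def read_signature(
    mean_path: str | Path, sd_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the two-file signature (mean TSV + SD TSV, genes x types)."""
    mean = _read_table(mean_path)
    sd = _read_table(sd_path)
    if not mean.index.equals(sd.index) or list(mean.columns) != list(sd.columns):
        raise KeyError("signature mean and sd files disagree on genes or cell types")
    return mean, sd


def read_combined_signature(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a wide signature TSV with ``<type>__mean`` / ``<type>__sd`` columns."""
    df = _read_table(path)
    means = {c[: -len("__mean")]: c for c in df.columns if c.endswith("__mean")}
    sds = {c[: -len("__sd")]: c for c in df.columns if c.endswith("__sd")}
    if set(means) != set(sds) or not means:
        raise KeyError("combined signature needs matching <type>__mean/<type>__sd columns")
    types = list(means)
    mean = df[[means[t] for t in types]].set_axis(types, axis=1)
    sd = df[[sds[t] for t in types]].set_axis(types, axis=1)
    return mean, sd


def write_signature(
    mean: pd.DataFrame, sd: pd.DataFrame, mean_path: str | Path, sd_path: str | Path
) -> None:
    mean.to_csv(mean_path, sep="\t", index_label="gene")
    sd.to_csv(sd_path, sep="\t", index_label="gene")


def read_sc_counts(
    mtx_path: str | Path, labels_path: str | Path, genes_path: str | Path | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read genes x cells counts (Matrix Market) plus per-cell labels.

    The labels file is a headerless single-column TSV (or two columns:
    cell id, label — the last column is used).  Returns
    ``(counts, labels, gene_ids)``.
    """
    counts = np.asarray(mmread(mtx_path).todense())
    labels_df = pd.read_csv(labels_path, sep="\t", header=None)
    labels = labels_df.iloc[:, -1].astype(str).to_numpy()
    if labels.size != counts.shape[1]:
        raise ValueError(
            f"{labels.size} labels for {counts.shape[1]} cells"
        )
    if genes_path is not None:
        gene_ids = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
        if len(gene_ids) != counts.shape[0]:
            raise ValueError(f"{len(gene_ids)} gene ids for {counts.shape[0]} genes")
    else:
        gene_ids = [f"gene{j}" for j in range(counts.shape[0])]
    return counts.astype(np.int64), labels, gene_ids


def write_sc_counts(
    counts: np.ndarray, labels: np.ndarray, outdir: str | Path, gene_ids=None
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(outdir / "counts.mtx", csc_matrix(counts))
    pd.Series(labels).to_csv(outdir / "labels.tsv", sep="\t", header=False, index=False)
    if gene_ids is not None:
        pd.Series(gene_ids).to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)


def write_fractions(fractions: np.ndarray, sample_ids, cell_types, path: str | Path) -> None:
    pd.DataFrame(fractions, index=sample_ids, columns=cell_types).to_csv(
        path, sep="\t", index_label="sample"
    )


def write_purified(
    tensor: np.ndarray,
    group: np.ndarray,
    gene_ids,
    sample_ids,
    cell_types,
    outdir: str | Path,
) -> None:
    """One genes x samples TSV per cell type plus the group-mode matrix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t, name in enumerate(cell_types):
        safe = str(name).replace("/", "_").replace(" ", "_")
        pd.DataFrame(tensor[:, :, t].T, index=gene_ids, columns=sample_ids).to_csv(
            outdir / f"purified_{safe}.tsv", sep="\t", index_label="gene"
        )
    pd.DataFrame(group, index=gene_ids, columns=cell_types).to_csv(
        outdir / "purified_group.tsv", sep="\t", index_label="gene"
    )


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_metadata(outdir: str | Path, seed: int, config: dict, inputs: dict | None = None) -> None:
    """Run metadata JSON: version, seed, config hash, input checksums."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = {k: v for k, v in config.items() if isinstance(v, (int, float, str, bool, list))}
    payload = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {
            name: file_checksum(p) for name, p in (inputs or {}).items() if Path(p).is_file()
        },
    }
    (outdir / "metadata.json").write_text(json.dumps(payload, indent=2) + "\n")
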