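"""Readers and writers: MTX/CSV count matrices, classification TSV,
thresholds JSON, run metadata.

On disk, MTX follows the cell-ranger-style orientation (features ×
barcodes, with ``barcodes.tsv`` and ``features.tsv`` sidecars); in memory
the contract is barcodes × tags, so the reader transposes. All text
outputs are UTF-8 with LF endings and '.' decimal separators.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import TagCountMatrix
from .demux import BackgroundModel

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "write_classification",
    "read_thresholds",
    "write_run_metadata",
    "read_truth",
    "write_truth",
]

log = logging.getLogger("hashdemux")

MTX_FILE = "matrix.mtx"
BARCODES_FILE = "barcodes.tsv"
FEATURES_FILE = "features.tsv"


def _read_sidecar(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _validate_mtx(path: Path) -> None:
    """Check the declared nnz against the number of data lines."""
    declared = None
    n_data = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            if declared is None:
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"{path}: malformed MTX size line {line!r}")
                declared = int(parts[2])
            else:
                n_data += 1
    if declared is None:
        raise ValueError(f"{path}: no MTX size header found")
    if n_data != declared:
        raise ValueError(
            f"{path}: header declares {declared} entries but file has {n_data}"
        )


def read_count_matrix(path) -> TagCountMatrix:
    """Read a barcode × tag UMI matrix from an MTX directory or dense CSV.

    MTX directories hold ``matrix.mtx`` (features × barcodes; transposed on
    read), ``barcodes.tsv`` and ``features.tsv``. CSV files are dense with
    barcode rows (first column) and tag columns (header). Integer counts
    are enforced; duplicates and sidecar/dimension mismatches are rejected
    with the offending location.
    """
    path = Path(path)
    if path.is_dir():
        mtx = path / MTX_FILE
        if not mtx.exists():
            raise FileNotFoundError(f"{mtx} not found")
        _validate_mtx(mtx)
        X = spio.mmread(mtx)
        barcodes = _read_sidecar(path / BARCODES_FILE)
        features = _read_sidecar(path / FEATURES_FILE)
        if X.shape != (len(features), len(barcodes)):
            raise ValueError(
                f"{mtx}: matrix is {X.shape[0]}x{X.shape[1]} but sidecars "
                f"give {len(features)} features x {len(barcodes)} barcodes"
            )
        log.info("read %s as features x barcodes; transposing to barcodes x tags", mtx)
        return TagCountMatrix(X.T.tocsr(), barcodes, features)

    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ValueError(f"{path}: duplicated barcode rows: {dups}")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        bad = np.argwhere(vals != np.floor(vals))
        if len(bad):
            r, c = bad[0]
            raise ValueError(
                f"{path}: non-integer entry {vals[r, c]} at barcode "
                f"{df.index[r]!r}, tag {df.columns[c]!r}"
            )
        vals = vals.astype(np.int64)
    return TagCountMatrix(vals, df.index.to_numpy(), df.columns.to_numpy())


def write_count_matrix(matrix: TagCountMatrix, outdir) -> None:
    """Write MTX triplet (features × barcodes) + barcode/feature sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sparse.coo_matrix(matrix.X.T)
    spio.mmwrite(outdir / MTX_FILE, X, field="integer")
    with open(outdir / BARCODES_FILE, "w", newline="\n") as fh:
        fh.writelines(f"{b}\n" for b in matrix.barcodes)
    with open(outdir / FEATURES_FILE, "w", newline="\n") as fh:
        fh.writelines(f"{t}\n" for t in matrix.tags)


def write_classification(
    classification: pd.DataFrame,
    model: BackgroundModel,
    outdir,
    counts: TagCountMatrix | None = None,
) -> None:
    """Write classification.tsv and thresholds.json.

    The TSV has stable columns (barcode, global_class, hash_id,
    n_positive_tags) plus per-tag raw counts and CLR values when the count
    matrix is supplied. Thresholds JSON round-trips the BackgroundModel
    and embeds the package version.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = classification.copy()
    out.index.name = "barcode"
    if counts is not None and len(classification):
        sub = counts.to_dataframe().loc[classification.index]
        norm = model.normalize(sub)
        for t in model.tags:
            out[f"count_{t}"] = sub[t]
        for t in model.tags:
            out[f"clr_{t}"] = norm[t].map(lambda v: f"{v:.6f}")
    out.to_csv(outdir / "classification.tsv", sep="\t", lineterminator="\n")

    payload = model.to_dict()
    payload["version"] = __version__
    with open(outdir / "thresholds.json", "w", newline="\n") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_thresholds(path) -> BackgroundModel:
    with open(path) as fh:
        return BackgroundModel.from_dict(json.load(fh))


def write_run_metadata(outdir, params: dict, seed=None) -> None:
    """Write run_metadata.json (parameters + seed + package version)."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"version": __version__, "seed": seed, "params": params}
    with open(outdir / "run_metadata.json", "w", newline="\n") as fh:
        json.dump(meta, fh, indent=2, default=str)
        fh.write("\n")


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write a simulator ground-truth table as TSV with header."""
    truth.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"member_samples": str}, keep_default_na=False,
        na_values=[],
    )
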