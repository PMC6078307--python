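"""File formats for the pipeline stages.

All tables are UTF-8 CSV/TSV with a header row, "." decimal separator
and "NA" for missing values.  Matrices are CSV with the region labels
as the header row.  Every stage writes a ``manifest.yaml`` sidecar
recording the config hash, seed, stage name, row counts and package
version.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

NA = "NA"


def write_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, na_rep=NA)


def read_table(path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, na_values=[NA], keep_default_na=False)


def write_matrix(M: np.ndarray, labels, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(M, columns=list(labels)).to_csv(path, index=False,
                                                 na_rep=NA)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, na_values=[NA], keep_default_na=False)
    return df.to_numpy(dtype=float), list(df.columns)


def write_edge_list(cm, path) -> None:
    """Weighted edge list TSV (node_a, node_b, weight) for one matrix."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    W, labels = cm.weights, cm.labels
    with open(path, "w", newline="") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        ii, jj = np.nonzero(np.triu(W, k=1))
        for i, j in zip(ii, jj):
            fh.write(f"{labels[i]}\t{labels[j]}\t{W[i, j]!r}\n")


def write_manifest(outdir, stage: str, config, counts: dict) -> None:
    from . import __version__
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "package_version": __version__,
        "counts": {k: int(v) for k, v in counts.items()},
    }
    path = outdir / "manifest.yaml"
    existing = {}
    if path.exists():
        with open(path) as fh:
            existing = yaml.safe_load(fh) or {}
    existing[stage] = manifest
    with open(path, "w") as fh:
        yaml.safe_dump(existing, fh, sort_keys=True)


def subject_matrix_paths(outdir, subdir: str, subject_ids) -> list[Path]:
    base = Path(outdir) / subdir
    return [base / f"{sid}.csv" for sid in subject_ids]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


def file_sha256(path) -> str:
    import hashlib
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def listdir_csv(path) -> list[str]:
    return sorted(f for f in os.listdir(path) if f.endswith(".csv"))
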