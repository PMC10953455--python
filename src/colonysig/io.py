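"""Standard-format I/O: count matrices (TSV / MatrixMarket), sample
metadata CSV, and the run manifest."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "file_digest",
    "read_counts_mtx",
    "read_counts_tsv",
    "read_metadata",
    "write_counts_mtx",
    "write_counts_tsv",
    "write_manifest",
    "write_metadata",
]


def read_counts_tsv(path) -> pd.DataFrame:
    """Genes-in-rows TSV with a header of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_mtx(prefix) -> pd.DataFrame:
    """MatrixMarket triple: <prefix>.mtx, <prefix>.genes.txt,
    <prefix>.samples.txt."""
    prefix = Path(prefix)
    mat = spio.mmread(prefix.with_suffix(".mtx"))
    genes = prefix.with_suffix(".genes.txt").read_text().split()
    samples = prefix.with_suffix(".samples.txt").read_text().split()
    return pd.DataFrame(mat.toarray() if sparse.issparse(mat) else mat,
                        index=genes, columns=samples).astype(int)


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    prefix.with_suffix(".samples.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="individual_id")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index_label="individual_id")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, stage_seeds: dict, outputs: dict) -> dict:
    """Run manifest: config snapshot, per-stage seeds, output digests.

    ``outputs`` maps stage name to a list of file paths; each file's
    sha256 is recorded so reruns can be checked byte-for-byte.
    """
    manifest = {
        "config": config,
        "stage_seeds": {k: int(v) for k, v in stage_seeds.items()},
        "outputs": {
            stage: {str(p): file_digest(p) for p in paths}
            for stage, paths in outputs.items()
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "package": "colonysig 0.1.0",
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
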