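"""Plain-text I/O for the pipeline's artifacts.

Expression and peak matrices travel as TSV (rows = genes/sites, columns =
cells/samples) or as an MTX triplet with row/column name sidecars; PPMs as
simple 4-row matrix text blocks (rows A, C, G, U); peaks as BED6.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_matrix_mtx",
    "read_matrix_mtx",
    "write_ppms",
    "read_ppms",
    "write_annotation",
    "read_annotation",
]

BASES = ("A", "C", "G", "U")


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path,
                     index_label: str = "id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_mtx(matrix: pd.DataFrame, prefix: str | Path) -> None:
    """Write an MTX triplet: <prefix>.mtx, <prefix>.rows.txt, <prefix>.cols.txt."""
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")),
                 sparse.csr_matrix(matrix.to_numpy()))
    prefix.with_suffix(".rows.txt").write_text(
        "\n".join(map(str, matrix.index)) + "\n")
    prefix.with_suffix(".cols.txt").write_text(
        "\n".join(map(str, matrix.columns)) + "\n")


def read_matrix_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    m = spio.mmread(str(prefix.with_suffix(".mtx")))
    rows = prefix.with_suffix(".rows.txt").read_text().splitlines()
    cols = prefix.with_suffix(".cols.txt").read_text().splitlines()
    return pd.DataFrame(np.asarray(m.todense() if sparse.issparse(m) else m),
                        index=rows, columns=cols)


def write_ppms(ppms: list[pd.DataFrame], path: str | Path) -> None:
    """Stacked PPM blocks: '>motif_id' header, then one line per base A,C,G,U."""
    with open(path, "w") as fh:
        for i, ppm in enumerate(ppms):
            mid = ppm.attrs.get("motif_id", f"motif_{i:03d}")
            fh.write(f">{mid}\n")
            for b in BASES:
                vals = "\t".join(f"{v:.6f}" for v in np.asarray(ppm.loc[b]))
                fh.write(f"{b}\t{vals}\n")


def read_ppms(path: str | Path) -> list[pd.DataFrame]:
    ppms = []
    block: dict[str, list[float]] = {}
    mid = None

    def flush():
        if mid is None:
            return
        if sorted(block) != sorted(BASES):
            raise ValueError(f"PPM block {mid} lacks rows for all of {BASES}")
        df = pd.DataFrame([block[b] for b in BASES], index=list(BASES))
        df.columns = [f"pos{i}" for i in range(df.shape[1])]
        df.attrs["motif_id"] = mid
        ppms.append(df)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                mid = line[1:]
                block = {}
            else:
                parts = line.split("\t")
                block[parts[0]] = [float(v) for v in parts[1:]]
    flush()
    if not ppms:
        raise ValueError(f"no PPM blocks in {path}")
    return ppms


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "gene_id", "utr5_len", "cds_len", "utr3_len"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return ann
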