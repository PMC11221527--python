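"""Reading and writing the pipeline's on-disk formats.

Count matrices use the MTX triplet layout (matrix.mtx + features.tsv +
barcodes.tsv, features x barcodes orientation); spot geometry uses the
tissue-positions CSV dialect (barcode, in_tissue, array_row, array_col,
pxl_row_in_fullres, pxl_col_in_fullres, 0-based array indices).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .lattice import POSITIONS_COLUMNS, SpotGrid


def write_mtx_dir(counts, gene_ids, barcodes, outdir) -> Path:
    """Write an MTX triplet directory (matrix.mtx, features.tsv, barcodes.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(np.asarray(counts))
    spio.mmwrite(outdir / "matrix.mtx", mat)
    pd.Series(list(gene_ids)).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(list(barcodes)).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    return outdir


def read_mtx_dir(indir):
    """Read an MTX triplet directory -> (counts ndarray, gene_ids, barcodes)."""
    indir = Path(indir)
    counts = np.asarray(spio.mmread(indir / "matrix.mtx").todense())
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    if counts.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix shape {counts.shape} does not match "
            f"{len(genes)} features x {len(barcodes)} barcodes"
        )
    return counts, genes, barcodes


def write_tissue_positions(grid: SpotGrid, path) -> None:
    grid.positions[POSITIONS_COLUMNS].to_csv(path, index=False)


def read_tissue_positions(path) -> SpotGrid:
    return SpotGrid(pd.read_csv(path))


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, index=True, index_label="sample_id")


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("sample_id")


def to_anndata(counts, gene_ids, grid: SpotGrid):
    """Package counts + geometry as an AnnData (spots x genes) for interop."""
    import anndata as ad

    adata = ad.AnnData(
        X=sparse.csr_matrix(np.asarray(counts).T),
        obs=grid.positions.set_index("barcode"),
        var=pd.DataFrame(index=list(gene_ids)),
    )
    adata.obsm["spatial"] = grid.positions[
        ["pxl_col_in_fullres", "pxl_row_in_fullres"]
    ].to_numpy()
    return adata
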