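"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as Matrix Market (MTX) alongside barcode/feature TSVs in the
10x-style directory layout; peak coordinates as BED (0-based, half-open);
gene annotation as a TSV with columns gene_id, chrom, strand, tss, start, end.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

ANNOTATION_COLUMNS = ["gene_id", "chrom", "strand", "tss", "start", "end"]


def write_counts_dir(matrix, barcodes, features, directory, features_name="features.tsv"):
    """Write a cells x features count matrix as MTX + barcodes/features TSV.

    The MTX is stored features x cells (10x convention).
    """
    os.makedirs(directory, exist_ok=True)
    mat = sparse.csr_matrix(np.asarray(matrix))
    spio.mmwrite(os.path.join(directory, "matrix.mtx"), mat.T.astype(int))
    pd.Series(list(barcodes)).to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(list(features)).to_csv(
        os.path.join(directory, features_name), sep="\t", index=False, header=False
    )


def read_counts_dir(directory, features_name="features.tsv"):
    """Read a 10x-style MTX directory; returns (cells x features array, barcodes, features)."""
    mat = spio.mmread(os.path.join(directory, "matrix.mtx"))
    mat = sparse.csr_matrix(mat).T.toarray()
    barcodes = pd.read_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str).tolist()
    features = pd.read_csv(
        os.path.join(directory, features_name), sep="\t", header=None
    )[0].astype(str).tolist()
    if mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match "
            f"{len(barcodes)} barcodes x {len(features)} features"
        )
    return mat, barcodes, features


def write_bed(intervals: pd.DataFrame, path):
    """Write BED3+name: chrom, start, end, name (0-based, half-open)."""
    intervals[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None)
    bed.columns = ["chrom", "start", "end", "name"][: bed.shape[1]]
    if "name" not in bed.columns:
        bed["name"] = [f"peak{i}" for i in range(len(bed))]
    return bed


def write_annotation(genes: pd.DataFrame, path):
    genes[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return ann
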