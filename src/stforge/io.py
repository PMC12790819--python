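"""Dataset readers and writers.

Canonical on-disk layout is a 10x-style Matrix Market triplet —
``matrix.mtx`` (genes x cells, integer counts), ``genes.tsv`` (one gene id
per line) and ``cells.tsv`` (cell table with ``cell_id``, coordinates and
``cell_type`` where available) — so outputs interoperate with standard
single-cell tooling.  Dense delimited matrices are accepted on read with
an orientation flag.  Every writer's output is re-readable by the matching
reader (exact integer counts, full-precision coordinates).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .aggregate import SpotST
from .errors import SchemaError
from .expression import ExpressionReference, SingleCellST
from .plate import CellPlate


def _read_ids(path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.split("\t")[0] for ln in lines if ln.strip()]


def write_reference(ref: ExpressionReference, outdir, prefix: str = "") -> dict:
    """Write a reference as matrix.mtx (genes x cells) + genes.tsv +
    labels.tsv; returns the file manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}matrix.mtx",
        "genes": outdir / f"{prefix}genes.tsv",
        "labels": outdir / f"{prefix}labels.tsv",
    }
    mmwrite(str(paths["matrix"]), sp.coo_matrix(ref.counts.T.astype(int)))
    paths["genes"].write_text("\n".join(ref.gene_ids) + "\n")
    pd.DataFrame(
        {"cell_id": np.arange(ref.n_cells), "cell_type": ref.cell_labels}
    ).to_csv(paths["labels"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def read_labeled_reference(
    matrix=None,
    genes=None,
    labels=None,
    dense=None,
    orientation: str = "cells_by_genes",
    sep: str = ",",
) -> ExpressionReference:
    """Read a labeled expression reference.

    Either ``matrix`` (Matrix Market, genes x cells) plus ``genes`` (gene
    id TSV) plus ``labels`` (TSV with cell_id and cell_type columns), or
    ``dense`` (delimited text matrix with a header row of ids and an
    index column) plus ``labels``, with ``orientation`` declaring whether
    rows are cells (``cells_by_genes``) or genes (``genes_by_cells``).
    """
    if labels is None:
        raise SchemaError("a cell label table is required")
    lab = pd.read_csv(labels, sep="\t")
    if "cell_type" not in lab.columns:
        if lab.shape[1] < 2:
            raise SchemaError(f"{labels}: expected cell_id and cell_type columns")
        lab.columns = ["cell_id", "cell_type"][: lab.shape[1]]

    if dense is not None:
        df = pd.read_csv(dense, sep=sep, index_col=0)
        if orientation == "genes_by_cells":
            df = df.T
        elif orientation != "cells_by_genes":
            raise SchemaError(f"unknown orientation {orientation!r}")
        counts = sp.csr_matrix(df.to_numpy())
        gene_ids = [str(g) for g in df.columns]
        cell_ids = [str(c) for c in df.index]
    else:
        if matrix is None or genes is None:
            raise SchemaError("need matrix+genes+labels or dense+labels")
        try:
            m = mmread(str(matrix))
        except Exception as exc:
            raise SchemaError(f"{matrix}: malformed Matrix Market file: {exc}") from exc
        counts = sp.csr_matrix(m).T.tocsr()  # stored genes x cells
        gene_ids = _read_ids(genes)
        cell_ids = [str(c) for c in lab["cell_id"]]
        if len(gene_ids) != counts.shape[1]:
            raise SchemaError(f"{genes}: {len(gene_ids)} ids for {counts.shape[1]} genes")

    if lab.shape[0] != counts.shape[0]:
        raise SchemaError(
            f"{labels}: {lab.shape[0]} labels for {counts.shape[0]} cells"
        )
    if "cell_id" in lab.columns and dense is not None:
        missing = set(map(str, lab["cell_id"])) - set(cell_ids)
        if missing:
            raise SchemaError(f"{labels}: cell ids absent from matrix: {sorted(missing)[:5]}")
    return ExpressionReference(
        counts=counts, cell_labels=lab["cell_type"].to_numpy(), gene_ids=gene_ids
    )


def write_dataset(sc: SingleCellST, outdir) -> dict:
    """Write a single-cell spatial dataset; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    axes = ["x", "y", "z"][: sc.plate.dim]
    cells = pd.DataFrame(sc.plate.coords, columns=axes)
    cells.insert(0, "cell_id", np.arange(sc.n_cells))
    cells["cell_type"] = sc.labels
    paths = {
        "cells": outdir / "cells.tsv",
        "matrix": outdir / "matrix.mtx",
        "genes": outdir / "genes.tsv",
        "bounds": outdir / "bounds.json",
    }
    cells.to_csv(paths["cells"], sep="\t", index=False, float_format="%.17g")
    mmwrite(str(paths["matrix"]), sp.coo_matrix(sc.counts.T.astype(int)))
    paths["genes"].write_text("\n".join(sc.gene_ids) + "\n")
    paths["bounds"].write_text(json.dumps(sc.plate.bounds.tolist()) + "\n")
    return {k: str(v) for k, v in paths.items()}


def read_dataset(indir) -> SingleCellST:
    """Read a dataset written by :func:`write_dataset`."""
    indir = Path(indir)
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", float_precision="round_trip")
    axes = [c for c in ("x", "y", "z") if c in cells.columns]
    bounds = np.asarray(json.loads((indir / "bounds.json").read_text()))
    plate = CellPlate(coords=cells[axes].to_numpy(dtype=float), bounds=bounds)
    try:
        counts = sp.csr_matrix(mmread(str(indir / "matrix.mtx"))).T.tocsr()
    except Exception as exc:
        raise SchemaError(f"{indir}/matrix.mtx: malformed Matrix Market: {exc}") from exc
    gene_ids = _read_ids(indir / "genes.tsv")
    if counts.shape[0] != plate.n_cells:
        raise SchemaError(
            f"{indir}: matrix has {counts.shape[0]} cells but cells.tsv has {plate.n_cells}"
        )
    if counts.shape[1] != len(gene_ids):
        raise SchemaError(f"{indir}: gene id count mismatch")
    return SingleCellST(
        plate=plate,
        labels=cells["cell_type"].to_numpy(),
        counts=counts,
        gene_ids=gene_ids,
    )


def write_spots(spots: SpotST, outdir) -> dict:
    """Write spot-level outputs: counts triplet, spots.tsv, composition.tsv
    (both counts and proportions per type)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spot_matrix": outdir / "spot_matrix.mtx",
        "spot_genes": outdir / "spot_genes.tsv",
        "spots": outdir / "spots.tsv",
        "composition": outdir / "composition.tsv",
        "proportions": outdir / "proportions.tsv",
    }
    mmwrite(str(paths["spot_matrix"]), sp.coo_matrix(spots.spot_counts.T.astype(int)))
    paths["spot_genes"].write_text("\n".join(spots.gene_ids) + "\n")
    tab = pd.DataFrame(spots.grid.centers, columns=["x", "y"])
    tab.insert(0, "spot_id", np.arange(spots.grid.n_spots))
    tab["n_cells"] = spots.n_cells
    tab.to_csv(paths["spots"], sep="\t", index=False, float_format="%.17g")
    comp = pd.DataFrame(spots.composition, columns=spots.type_names)
    comp.insert(0, "spot_id", np.arange(spots.grid.n_spots))
    comp.to_csv(paths["composition"], sep="\t", index=False)
    prop = pd.DataFrame(spots.proportions, columns=spots.type_names)
    prop.insert(0, "spot_id", np.arange(spots.grid.n_spots))
    prop.to_csv(paths["proportions"], sep="\t", index=False, float_format="%.17g")
    return {k: str(v) for k, v in paths.items()}
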