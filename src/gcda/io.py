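"""Delimited-text I/O for expression datasets and dataset/graph alignment.

Expression matrices are plain delimited text (tab by default) with a header
row of gene identifiers and an index column of sample identifiers; labels
are a two-column file (sample id, class label).  Real networks rarely cover
exactly the profiled gene set, so :func:`align_graph` restricts a dataset
and a labelled graph to their common genes, in dataset order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import Graph

__all__ = ["LabelledDataset", "load_dataset", "write_dataset", "align_graph"]

logger = logging.getLogger("gcda")


@dataclass
class LabelledDataset:
    """An n x p expression matrix with binary labels and identifiers."""

    X: np.ndarray
    y: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        n, p = self.X.shape
        if len(self.y) != n:
            raise ValueError(f"{len(self.y)} labels for {n} samples")
        if len(self.sample_ids) != n or len(self.gene_ids) != p:
            raise ValueError("identifier lists must match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene ids")
        if np.isnan(self.X).any():
            rows, cols = np.nonzero(np.isnan(self.X))
            where = ", ".join(
                f"({self.sample_ids[r]}, {self.gene_ids[c]})"
                for r, c in list(zip(rows, cols))[:5]
            )
            raise ValueError(f"missing values at {where}"
                             + (" ..." if rows.size > 5 else ""))
        classes = np.unique(self.y)
        if classes.size != 2:
            raise ValueError(
                f"expected 2 classes, got {classes.size}: {classes.tolist()}"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def load_dataset(
    matrix_path, labels_path, orientation: str = "samples-in-rows",
    sep: str = "\t",
) -> LabelledDataset:
    """Load a delimited expression matrix plus a sample-label file.

    ``orientation`` is ``"samples-in-rows"`` or ``"genes-in-rows"``; the
    result is always samples x genes.  Labels are joined on sample id;
    samples without a label (or labels without a sample) are dropped with a
    log message.
    """
    if orientation not in ("samples-in-rows", "genes-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(matrix_path, sep=sep, index_col=0)
    if orientation == "genes-in-rows":
        df = df.T
    bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    labels = pd.read_csv(labels_path, sep=sep, header=None, comment="#",
                         dtype=str, skip_blank_lines=True)
    if labels.shape[1] != 2:
        raise ValueError("labels file must have two columns: sample id, label")
    # Tolerate an optional header line whose first field matches no sample.
    if labels.iloc[0, 0] not in set(map(str, df.index)):
        labels = labels.iloc[1:]
    lab = dict(zip(labels.iloc[:, 0], labels.iloc[:, 1]))
    if len(lab) != len(labels):
        raise ValueError("duplicate sample ids in labels file")
    sample_ids = [str(s) for s in df.index]
    matched = [s for s in sample_ids if s in lab]
    dropped = sorted(set(sample_ids) - set(matched))
    unmatched = sorted(set(lab) - set(sample_ids))
    if dropped:
        logger.info("dropping %d unlabelled samples: %s", len(dropped), dropped[:5])
    if unmatched:
        logger.info("ignoring %d labels without samples: %s",
                    len(unmatched), unmatched[:5])
    df = df.loc[[s for s in df.index if str(s) in lab]]
    y = np.array([lab[str(s)] for s in df.index])
    return LabelledDataset(
        X=df.to_numpy(dtype=float),
        y=y,
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
    )


def write_dataset(ds: LabelledDataset, matrix_path, labels_path,
                  sep: str = "\t") -> None:
    pd.DataFrame(ds.X, index=ds.sample_ids, columns=ds.gene_ids).to_csv(
        matrix_path, sep=sep)
    pd.DataFrame({"sample": ds.sample_ids, "label": ds.y}).to_csv(
        labels_path, sep=sep, index=False, header=False)


def align_graph(ds: LabelledDataset, g: Graph) -> tuple[LabelledDataset, Graph]:
    """Restrict dataset and graph to their common genes, in dataset order.

    Needed because inferred or pathway-derived networks usually cover a
    different gene set than the expression matrix.
    """
    if g.vertex_labels is None:
        raise ValueError("graph must carry vertex labels to be aligned")
    common = [gene for gene in ds.gene_ids if gene in set(g.vertex_labels)]
    if not common:
        raise ValueError("dataset and graph share no genes")
    dropped_genes = ds.p - len(common)
    col_idx = [ds.gene_ids.index(gene) for gene in common]
    new_ds = LabelledDataset(
        X=ds.X[:, col_idx], y=ds.y, sample_ids=list(ds.sample_ids),
        gene_ids=common,
    )
    pos = {gene: i for i, gene in enumerate(common)}
    old = {i: lab for i, lab in enumerate(g.vertex_labels)}
    edges = set()
    for i, j in g.edges:
        gi, gj = old[i], old[j]
        if gi in pos and gj in pos:
            edges.add((pos[gi], pos[gj]))
    dropped_edges = g.n_edges - len(edges)
    if dropped_genes or dropped_edges:
        logger.info("align_graph: dropped %d genes and %d edges",
                    dropped_genes, dropped_edges)
    new_g = Graph(len(common), frozenset(edges), tuple(common))
    return new_ds, new_g
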