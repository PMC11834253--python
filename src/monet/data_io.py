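"""Readers, writers and assembly of attributed PPI datasets.

The on-disk formats are deliberately plain: tab-separated edge lists (optional
confidence score column), a tab-separated gene x feature table whose columns
encode ``<OMICS>_<CANCER>`` blocks, and one-gene-per-line label lists. The
assembly step aligns everything to a deterministic (lexicographic) node order
and produces the single object the model consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse as sp

logger = logging.getLogger(__name__)

#: The four omics blocks: somatic mutation frequency, DNA methylation,
#: gene expression, copy number alteration.
OMICS_TYPES: tuple[str, ...] = ("MF", "METH", "GE", "CNA")

#: The 16 TCGA cancer-type codes the feature grid spans.
CANCER_TYPES: tuple[str, ...] = (
    "BLCA", "BRCA", "CESC", "COAD", "ESCA", "HNSC", "KIRC", "KIRP",
    "LIHC", "LUAD", "LUSC", "PRAD", "READ", "STAD", "THCA", "UCEC",
)

#: Canonical column order of the full 4 x 16 feature grid.
FULL_FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{om}_{ca}" for om in OMICS_TYPES for ca in CANCER_TYPES
)

LABEL_POSITIVE = 1
LABEL_NEGATIVE = 0
LABEL_UNLABELED = -1


class DataFormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GeneNetwork:
    """An undirected PPI network over gene symbols.

    Nodes are sorted lexicographically; edges are stored as frozensets of
    unordered symbol pairs with no self-pairs (self-loops are introduced
    later by adjacency normalization, not stored here).
    """

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    name: str = "network"

    def __post_init__(self):
        node_set = set(self.nodes)
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"self-pair or malformed edge: {set(e)}")
            if not e <= node_set:
                raise ValueError(f"edge endpoint outside node set: {set(e)}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> sp.csr_matrix:
        """Binary symmetric adjacency (no self-loops) in node order."""
        idx = {g: i for i, g in enumerate(self.nodes)}
        rows, cols = [], []
        for e in self.edges:
            a, b = sorted(e)
            rows += [idx[a], idx[b]]
            cols += [idx[b], idx[a]]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)),
                             shape=(self.n_nodes, self.n_nodes))


@dataclass(frozen=True)
class OmicsFeatureTable:
    """Gene x feature matrix with ``<OMICS>_<CANCER>`` column labels."""

    genes: tuple[str, ...]
    columns: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.genes), len(self.columns)):
            raise ValueError("values shape does not match genes x columns")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene rows")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes),
                            columns=list(self.columns))


@dataclass(frozen=True)
class LabelCatalog:
    """Disjoint positive / negative gene symbol sets."""

    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self):
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"genes labeled both positive and negative: "
                             f"{sorted(overlap)[:5]}")


@dataclass
class AttributedGraphDataset:
    """One network with aligned features, labels and split masks.

    ``y`` holds 1/0/-1 for positive/negative/unlabeled; the three masks are
    boolean per-node vectors that are pairwise disjoint and cover exactly the
    labeled nodes once a split has been applied.
    """

    network: GeneNetwork
    features: np.ndarray
    y: np.ndarray
    train_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    val_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    test_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        n = self.network.n_nodes
        if self.features.shape[0] != n or self.y.shape[0] != n:
            raise ValueError("features/labels not aligned to node count")
        if self.train_mask is None:
            self.train_mask = np.zeros(n, dtype=bool)
        if self.val_mask is None:
            self.val_mask = np.zeros(n, dtype=bool)
        if self.test_mask is None:
            self.test_mask = np.zeros(n, dtype=bool)

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.y != LABEL_UNLABELED

    @property
    def n_nodes(self) -> int:
        return self.network.n_nodes


def read_edge_list(path: str | Path, score_threshold: float | None = None,
                   name: str | None = None) -> GeneNetwork:
    """Read a TSV edge list into an undirected, deduplicated network.

    Rows are ``gene_a<TAB>gene_b[<TAB>score]``; lines starting with ``#`` are
    ignored. When ``score_threshold`` is given, only rows with score strictly
    greater than the threshold are retained, and the node universe is the set
    of endpoints of surviving edges. Self-pairs are dropped.
    """
    path = Path(path)
    edges: set[frozenset[str]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise DataFormatError(
                    f"{path}:{lineno}: malformed edge row: {line!r}")
            a, b = parts[0].strip(), parts[1].strip()
            if score_threshold is not None:
                if len(parts) < 3:
                    raise DataFormatError(
                        f"{path}:{lineno}: score threshold given but row has "
                        f"no score column")
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise DataFormatError(
                        f"{path}:{lineno}: non-numeric score {parts[2]!r}"
                    ) from exc
                if not score > score_threshold:
                    continue
            if a == b:
                continue
            edges.add(frozenset((a, b)))
    nodes = tuple(sorted({g for e in edges for g in e}))
    return GeneNetwork(nodes=nodes, edges=frozenset(edges),
                       name=name or path.stem)


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# network: {network.name}\n")
        for e in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")


def read_feature_table(path: str | Path, strict: bool = False) -> OmicsFeatureTable:
    """Read the gene x feature TSV (header row, first column ``gene``).

    With ``strict=True`` the columns must be exactly the 4 x 16 grid of
    ``<OMICS>_<CANCER>`` names (any order is rejected too: the canonical
    block order is required so omics sub-setting is well defined).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique()
        raise DataFormatError(f"{path}: duplicate gene rows: {list(dup)[:5]}")
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            gene = bad.index[0]
            raise DataFormatError(
                f"{path}: non-numeric value {bad.iloc[0]!r} at "
                f"gene={gene!r}, column={col!r}") from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise DataFormatError(
            f"{path}: missing value at gene={df.index[i]!r}, "
            f"column={df.columns[j]!r}")
    columns = tuple(df.columns)
    if strict and columns != FULL_FEATURE_COLUMNS:
        raise DataFormatError(
            f"{path}: strict mode requires the canonical "
            f"{len(FULL_FEATURE_COLUMNS)}-column omics grid")
    return OmicsFeatureTable(genes=tuple(df.index), columns=columns,
                             values=values)


def write_feature_table(table: OmicsFeatureTable, path: str | Path) -> None:
    df = table.to_frame()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_label_list(path: str | Path) -> frozenset[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = set()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.add(sym)
    return frozenset(out)


def read_labels(positives_path: str | Path,
                negatives_path: str | Path) -> LabelCatalog:
    return LabelCatalog(positives=read_label_list(positives_path),
                        negatives=read_label_list(negatives_path))


def write_label_list(genes, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def subset_omics(table: OmicsFeatureTable, omics_types) -> OmicsFeatureTable:
    """Restrict the table to the selected omics blocks, preserving order."""
    omics_types = set(omics_types)
    if not omics_types:
        raise ValueError("omics_types must be non-empty")
    unknown = omics_types - set(OMICS_TYPES)
    if unknown:
        raise ValueError(f"unknown omics tags: {sorted(unknown)}; "
                         f"valid tags are {OMICS_TYPES}")
    keep = [j for j, c in enumerate(table.columns)
            if c.split("_", 1)[0] in omics_types]
    return OmicsFeatureTable(
        genes=table.genes,
        columns=tuple(table.columns[j] for j in keep),
        values=table.values[:, keep].copy(),
    )


def zscore_columns(table: OmicsFeatureTable) -> OmicsFeatureTable:
    """Optional per-column z-score; constant columns map to zero."""
    mu = table.values.mean(axis=0)
    sd = table.values.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return OmicsFeatureTable(table.genes, table.columns,
                             (table.values - mu) / sd)


def assemble_dataset(network: GeneNetwork, table: OmicsFeatureTable,
                     labels: LabelCatalog) -> AttributedGraphDataset:
    """Align features and labels to the network's node order.

    Genes in the network but missing from the feature table receive all-zero
    feature rows (zero is neutral for z-scored features); a warning reports
    the count. Labels are restricted to network nodes. Raises if no labeled
    gene is in the network, since such a dataset cannot be trained on.
    """
    node_index = {g: i for i, g in enumerate(network.nodes)}
    n, d = network.n_nodes, len(table.columns)
    features = np.zeros((n, d), dtype=np.float64)
    gene_row = {g: i for i, g in enumerate(table.genes)}
    missing = 0
    for g, i in node_index.items():
        j = gene_row.get(g)
        if j is None:
            missing += 1
        else:
            features[i] = table.values[j]
    if missing:
        msg = (f"{missing}/{n} network genes missing from the feature table; "
               f"zero-imputed")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    y = np.full(n, LABEL_UNLABELED, dtype=np.int64)
    for g in labels.positives:
        if g in node_index:
            y[node_index[g]] = LABEL_POSITIVE
    for g in labels.negatives:
        if g in node_index:
            y[node_index[g]] = LABEL_NEGATIVE
    if not (y != LABEL_UNLABELED).any():
        raise ValueError("no labeled gene is present in the network; "
                         "the dataset is untrainable")
    return AttributedGraphDataset(network=network, features=features, y=y)


def save_dataset(dataset: AttributedGraphDataset, path: str | Path) -> None:
    """Snapshot the aligned dataset to a single .npz archive."""
    adj = dataset.network.adjacency().tocoo()
    np.savez_compressed(
        Path(path),
        nodes=np.array(dataset.network.nodes, dtype=object),
        name=np.array(dataset.network.name),
        adj_row=adj.row, adj_col=adj.col,
        features=dataset.features, y=dataset.y,
        train_mask=dataset.train_mask, val_mask=dataset.val_mask,
        test_mask=dataset.test_mask,
    )


def load_dataset(path: str | Path) -> AttributedGraphDataset:
    with np.load(Path(path), allow_pickle=True) as z:
        nodes = tuple(str(g) for g in z["nodes"])
        edges = frozenset(
            frozenset((nodes[i], nodes[j]))
            for i, j in zip(z["adj_row"], z["adj_col"]) if i < j
        )
        network = GeneNetwork(nodes=nodes, edges=edges, name=str(z["name"]))
        return AttributedGraphDataset(
            network=network, features=z["features"], y=z["y"],
            train_mask=z["train_mask"], val_mask=z["val_mask"],
            test_mask=z["test_mask"],
        )
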