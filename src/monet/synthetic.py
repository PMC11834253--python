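"""Synthetic PPI ensembles with planted driver signal.

The generator emulates the statistical structure the model consumes through
its two branches: a topological channel (a planted community of driver genes
with elevated internal edge probability p_in against a background p_out) and
a feature channel (a 4-omics x 16-cancer-type feature grid where driver
genes' rows are mean-shifted in configurable omics blocks, in
standard-deviation units). An ensemble of correlated networks is produced by
independently resampling a fraction of the base graph's edges per network.
Labels mirror the real benchmark's imbalance: positives are drawn from the
planted drivers, negatives from the background, at a configurable neg:pos
ratio (default 3).

Everything is a deterministic function of the config: the driver set, every
network, the features and the labels are reproduced exactly from the same
seed, with per-component substreams spawned from one master seed sequence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import (CANCER_TYPES, FULL_FEATURE_COLUMNS, GeneNetwork,
                      LabelCatalog, OMICS_TYPES, OmicsFeatureTable,
                      write_edge_list, write_feature_table, write_label_list)

__all__ = [
    "SyntheticConfig", "driver_genes", "generate_network_ensemble",
    "generate_features", "generate_labels", "simulate",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-driver scenario.

    Defaults define the reference scenario used throughout the tests:
    600 genes with 60 drivers, within-community edge probability 0.05
    against background 0.005, a mean shift of 1.5 SD on the mutation (MF)
    and expression (GE) blocks, six networks at 20% edge resampling, half
    the drivers labeled positive and three negatives per positive.
    """

    n_genes: int = 600
    n_drivers: int = 60
    p_in: float = 0.05
    p_out: float = 0.005
    omics_effect: dict[str, float] = field(
        default_factory=lambda: {"MF": 1.5, "METH": 0.0, "GE": 1.5,
                                 "CNA": 0.0})
    n_networks: int = 6
    edge_rewire_fraction: float = 0.2
    label_fraction_pos: float = 0.5
    neg_pos_ratio: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not (0 < self.n_drivers < self.n_genes):
            raise ValueError("need 0 < n_drivers < n_genes")
        if not (0 <= self.edge_rewire_fraction <= 1):
            raise ValueError("edge_rewire_fraction must be in [0, 1]")
        unknown = set(self.omics_effect) - set(OMICS_TYPES)
        if unknown:
            raise ValueError(f"unknown omics tags in omics_effect: "
                             f"{sorted(unknown)}")

    @property
    def gene_symbols(self) -> tuple[str, ...]:
        width = len(str(self.n_genes))
        return tuple(f"G{i:0{width}d}" for i in range(self.n_genes))

    def _substream(self, component: str) -> np.random.Generator:
        # deterministic per-component substream from the master seed
        names = ("drivers", "networks", "features", "labels")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return np.random.default_rng(children[names.index(component)])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def driver_genes(config: SyntheticConfig) -> frozenset[str]:
    """The planted driver set: a seeded random subset of the gene universe."""
    rng = config._substream("drivers")
    genes = config.gene_symbols
    idx = rng.choice(config.n_genes, size=config.n_drivers, replace=False)
    return frozenset(genes[i] for i in idx)


def _sample_base_edges(config: SyntheticConfig,
                       rng: np.random.Generator) -> set[tuple[int, int]]:
    n = config.n_genes
    genes = config.gene_symbols
    drivers = driver_genes(config)
    is_driver = np.array([g in drivers for g in genes])
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(is_driver[iu] & is_driver[ju], config.p_in, config.p_out)
    keep = rng.random(p.shape) < p
    return {(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])}


def _rewire(edges: set[tuple[int, int]], fraction: float, n: int,
            rng: np.random.Generator) -> set[tuple[int, int]]:
    """Resample ``fraction`` of the edges to fresh uniform non-edges."""
    edge_list = sorted(edges)
    n_rewire = int(round(fraction * len(edge_list)))
    if n_rewire == 0:
        return set(edges)
    drop_idx = rng.choice(len(edge_list), size=n_rewire, replace=False)
    out = set(edges)
    for k in drop_idx:
        out.discard(edge_list[k])
    while len(out) < len(edges):
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        e = (int(min(i, j)), int(max(i, j)))
        if e not in out:
            out.add(e)
    return out


def generate_network_ensemble(config: SyntheticConfig) -> list[GeneNetwork]:
    """The base planted-community graph plus rewired variants.

    All networks share the full gene universe as their node set (isolated
    genes are kept so features and labels align across the ensemble).
    """
    rng = config._substream("networks")
    genes = config.gene_symbols
    base = _sample_base_edges(config, rng)
    networks = []
    for k in range(config.n_networks):
        edges = base if k == 0 else _rewire(base, config.edge_rewire_fraction,
                                            config.n_genes, rng)
        networks.append(GeneNetwork(
            nodes=genes,
            edges=frozenset(frozenset((genes[i], genes[j]))
                            for i, j in edges),
            name=f"synthetic_net_{k}"))
    return networks


def generate_features(config: SyntheticConfig,
                      networks: list[GeneNetwork] | None = None) -> OmicsFeatureTable:
    """Standard-normal 64-column feature grid with driver mean shifts.

    Rows of planted drivers get the configured per-omics-block shift added
    to all 16 cancer-type columns of that block; the background stays
    standard normal. ``networks`` is accepted for interface symmetry (the
    feature table spans the shared gene universe regardless).
    """
    rng = config._substream("features")
    genes = config.gene_symbols
    drivers = driver_genes(config)
    values = rng.standard_normal((config.n_genes, len(FULL_FEATURE_COLUMNS)))
    driver_rows = np.array([g in drivers for g in genes])
    for b, om in enumerate(OMICS_TYPES):
        effect = config.omics_effect.get(om, 0.0)
        if effect:
            cols = slice(b * len(CANCER_TYPES), (b + 1) * len(CANCER_TYPES))
            values[driver_rows, cols] += effect
    return OmicsFeatureTable(genes=genes, columns=FULL_FEATURE_COLUMNS,
                             values=values)


def generate_labels(config: SyntheticConfig) -> LabelCatalog:
    """Positives from the planted drivers, negatives from the background.

    n_pos = round(label_fraction_pos * n_drivers);
    n_neg = round(neg_pos_ratio * n_pos). The rest stays unlabeled.
    """
    rng = config._substream("labels")
    genes = config.gene_symbols
    drivers = sorted(driver_genes(config))
    background = sorted(set(genes) - set(drivers))
    n_pos = int(round(config.label_fraction_pos * len(drivers)))
    n_neg = int(round(config.neg_pos_ratio * n_pos))
    if n_pos < 1 or n_pos > len(drivers):
        raise ValueError(f"infeasible positive label count {n_pos}")
    if n_neg < 1 or n_neg > len(background):
        raise ValueError(f"infeasible negative label count {n_neg} "
                         f"(only {len(background)} background genes)")
    pos = rng.choice(len(drivers), size=n_pos, replace=False)
    neg = rng.choice(len(background), size=n_neg, replace=False)
    return LabelCatalog(
        positives=frozenset(drivers[i] for i in pos),
        negatives=frozenset(background[i] for i in neg))


def simulate(config: SyntheticConfig, out_dir: str | Path) -> dict:
    """Write the full scenario in the on-disk formats the readers consume.

    Produces one edge-list TSV per network, the feature TSV, positive and
    negative label lists, the planted driver list, and a JSON manifest with
    the full config. Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    networks = generate_network_ensemble(config)
    features = generate_features(config, networks)
    labels = generate_labels(config)
    files = []
    for net in networks:
        p = out / f"{net.name}.edges.tsv"
        write_edge_list(net, p)
        files.append(p.name)
    write_feature_table(features, out / "features.tsv")
    write_label_list(labels.positives, out / "positives.txt")
    write_label_list(labels.negatives, out / "negatives.txt")
    write_label_list(driver_genes(config), out / "planted_drivers.txt")
    manifest = {
        "config": config.to_dict(),
        "networks": files,
        "features": "features.tsv",
        "positives": "positives.txt",
        "negatives": "negatives.txt",
        "planted_drivers": "planted_drivers.txt",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
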