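"""Consensus candidate calling across multiple PPI networks.

Each network yields an ordered gene ranking by predicted driver probability.
The top K (default 300) genes of every ranking are candidate genes; genes
present in at least m (default 2) of those top-K sets are the consensus
candidate driver genes, partitioned into known (in the positive catalog) and
novel. Known positives are deliberately retained in the rankings before the
top-K cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import LabelCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRanking", "ConsensusResult", "rank_genes", "top_k",
    "consensus_candidates", "annotate_known",
    "read_probability_tsv", "write_candidates_tsv",
    "DEFAULT_TOP_K", "DEFAULT_MIN_SUPPORT",
]

DEFAULT_TOP_K = 300
DEFAULT_MIN_SUPPORT = 2


@dataclass(frozen=True)
class GeneRanking:
    """Per-network descending (gene, probability) list; genes unique."""

    network: str
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self):
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in ranking")
        probs = [p for _, p in self.entries]
        if any(a < b for a, b in zip(probs, probs[1:])):
            raise ValueError("probabilities must be non-increasing")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)


@dataclass(frozen=True)
class ConsensusResult:
    """Candidate drivers with per-gene support counts and known/novel split."""

    support: dict[str, int]  # gene -> number of top-K lists containing it
    mean_probability: dict[str, float]
    k: int
    min_support: int
    known: frozenset[str] = field(default_factory=frozenset)
    novel: frozenset[str] = field(default_factory=frozenset)

    @property
    def candidates(self) -> frozenset[str]:
        return frozenset(self.support)

    @property
    def known_fraction(self) -> float:
        return len(self.known) / len(self.support) if self.support else 0.0


def rank_genes(probabilities, nodes) -> GeneRanking:
    """Stable descending sort; ties broken lexicographically by symbol."""
    probabilities = np.asarray(probabilities, dtype=float)
    order = sorted(range(len(nodes)), key=lambda i: (-probabilities[i], nodes[i]))
    return GeneRanking(network="ranking",
                       entries=tuple((nodes[i], float(probabilities[i]))
                                     for i in order))


def top_k(ranking: GeneRanking, k: int = DEFAULT_TOP_K) -> tuple[str, ...]:
    """First min(k, len) genes; boundary ties follow the ranking order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if (k < len(ranking)
            and ranking.entries[k - 1][1] == ranking.entries[k][1]):
        logger.info("tie at the top-%d boundary of %s resolved by ranking "
                    "order", k, ranking.network)
    return ranking.genes[:k]


def consensus_candidates(rankings, k: int = DEFAULT_TOP_K,
                         min_support: int = DEFAULT_MIN_SUPPORT) -> ConsensusResult:
    """Genes in the top-K of at least ``min_support`` rankings."""
    rankings = list(rankings)
    if min_support > len(rankings):
        raise ValueError(f"min_support={min_support} exceeds the number of "
                         f"rankings ({len(rankings)})")
    support: dict[str, int] = {}
    prob_sums: dict[str, float] = {}
    for ranking in rankings:
        probs = dict(ranking.entries)
        for gene in top_k(ranking, k):
            support[gene] = support.get(gene, 0) + 1
            prob_sums[gene] = prob_sums.get(gene, 0.0) + probs[gene]
    kept = {g: c for g, c in support.items() if c >= min_support}
    return ConsensusResult(
        support=kept,
        mean_probability={g: prob_sums[g] / support[g] for g in kept},
        k=k, min_support=min_support)


def annotate_known(result: ConsensusResult,
                   positives: LabelCatalog | frozenset[str]) -> ConsensusResult:
    """Partition candidates into known (in the positive catalog) and novel."""
    pos = positives.positives if isinstance(positives, LabelCatalog) else frozenset(positives)
    candidates = result.candidates
    known = frozenset(candidates & pos)
    return ConsensusResult(support=result.support,
                           mean_probability=result.mean_probability,
                           k=result.k, min_support=result.min_support,
                           known=known, novel=frozenset(candidates - known))


def read_probability_tsv(path: str | Path, network: str | None = None) -> GeneRanking:
    """Read a probability TSV (from training) into a ranking."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "probability"} <= set(df.columns):
        raise ValueError(f"{path}: expected 'gene' and 'probability' columns")
    ranking = rank_genes(df["probability"].to_numpy(),
                         df["gene"].astype(str).tolist())
    return GeneRanking(network=network or Path(path).stem,
                       entries=ranking.entries)


def write_candidates_tsv(result: ConsensusResult, path: str | Path) -> None:
    """TSV: gene, support count, mean probability, known flag."""
    rows = sorted(result.support,
                  key=lambda g: (-result.support[g],
                                 -result.mean_probability[g], g))
    with Path(path).open("w") as fh:
        fh.write("gene\tsupport_count\tmean_probability\tknown_flag\n")
        for g in rows:
            flag = int(g in result.known)
            fh.write(f"{g}\t{result.support[g]}"
                     f"\t{result.mean_probability[g]:.10g}\t{flag}\n")
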