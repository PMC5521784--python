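"""Resampling consensus filter for the BRP interaction network.

The taxa are partitioned into biogas-related-pathway (BRP) families and the
rest (NBRP). A raw network is inferred from the BRP families alone; then
``n_sim`` mixed communities — the BRP families plus a random subset of NBRP
families — are re-fitted, and for every ordered BRP pair the consensus
probability

    P(i, j) = (# runs with a positive inferred effect of j on i) / n_sim

is accumulated. An edge is kept only when the resampled sign consensus and
the raw-network sign agree:

* confident activation: P >= p_threshold and raw strength > 0;
* confident repression: P <= 1 - p_threshold and raw strength < 0;

every other combination (including strength exactly 0 and intermediate P)
is non-confident and produces no edge.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .glv import InteractionMatrix, infer_interactions
from .table import AbundanceTable, Thresholds

__all__ = [
    "BrpAnnotation",
    "ConsensusProfile",
    "ConfidentNetwork",
    "InteractionClass",
    "ConsensusNetworkFilter",
    "partition_taxa",
    "raw_brp_network",
    "simulate_mixed_networks",
    "classify_interaction",
    "build_confident_network",
]

PATHWAY_TAGS = ("p1", "p2", "p3", "p4", "deS")  # hydrolysis, acidogenesis,
# acetogenesis, methanogenesis, desulfurization


class InteractionClass(enum.Enum):
    CONFIDENT_ACTIVATION = "activation"
    CONFIDENT_REPRESSION = "repression"
    NON_CONFIDENT = "non_confident"


@dataclass
class BrpAnnotation:
    """Taxon -> BRP/NBRP membership, with optional pathway tags for BRP taxa."""

    brp: set[str]
    nbrp: set[str]
    pathways: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.brp & self.nbrp
        if overlap:
            raise ValueError(f"taxa in both groups: {sorted(overlap)}")
        for taxon, tags in self.pathways.items():
            bad = set(tags) - set(PATHWAY_TAGS)
            if bad:
                raise ValueError(f"unknown pathway tag(s) {sorted(bad)} for {taxon}")

    @classmethod
    def read(cls, path) -> "BrpAnnotation":
        """Read a two/three-column TSV: taxon, BRP|NBRP[, comma-joined tags]."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        brp, nbrp, pathways = set(), set(), {}
        for row in df.itertuples(index=False):
            taxon, group = row[0], row[1].upper()
            if group == "BRP":
                brp.add(taxon)
                if len(row) > 2 and isinstance(row[2], str) and row[2]:
                    pathways[taxon] = tuple(row[2].split(","))
            elif group == "NBRP":
                nbrp.add(taxon)
            else:
                raise ValueError(f"unknown group {group!r} for taxon {taxon!r}")
        return cls(brp=brp, nbrp=nbrp, pathways=pathways)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for t in sorted(self.brp):
                tags = ",".join(self.pathways.get(t, ()))
                fh.write(f"{t}\tBRP\t{tags}\n")
            for t in sorted(self.nbrp):
                fh.write(f"{t}\tNBRP\t\n")


@dataclass
class ConsensusProfile:
    """Per ordered BRP pair: count and fraction of runs with positive effect."""

    taxa: list[str]  # BRP taxa, fixed order
    positive_counts: np.ndarray  # (n, n), diagonal unused
    n_sim: int
    seed: int | None = None

    @property
    def P(self) -> np.ndarray:
        return self.positive_counts / self.n_sim


@dataclass
class ConfidentNetwork:
    """Directed signed edges surviving the consensus filter.

    ``edges`` columns: source, target, strength, sign, P.
    """

    edges: pd.DataFrame
    taxa: list[str]
    condition: str = ""

    def __post_init__(self) -> None:
        required = {"source", "target", "strength", "sign", "P"}
        missing = required - set(self.edges.columns)
        if missing:
            raise ValueError(f"edge table missing columns {sorted(missing)}")
        if ((self.edges["source"] == self.edges["target"])).any():
            raise ValueError("self-edges are not allowed")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(condition=self.condition)
        g.add_nodes_from(self.taxa)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.source, row.target, strength=row.strength, sign=row.sign, P=row.P
            )
        return g


def partition_taxa(
    table: AbundanceTable, annotation: BrpAnnotation
) -> tuple[AbundanceTable, list[str]]:
    """Split a table into the BRP sub-table and the NBRP taxon list."""
    known = annotation.brp | annotation.nbrp
    missing = [t for t in table.taxa if t not in known]
    if missing:
        raise ValueError(f"unannotated taxa: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    brp_taxa = [t for t in table.taxa if t in annotation.brp]
    nbrp_taxa = [t for t in table.taxa if t in annotation.nbrp]
    return table.subset(brp_taxa), nbrp_taxa


def raw_brp_network(brp_table: AbundanceTable, n_components: int | str = "auto") -> InteractionMatrix:
    """Interaction matrix inferred from the BRP families alone."""
    if brp_table.n_taxa == 0:
        raise ValueError("BRP table is empty")
    return infer_interactions(brp_table, n_components=n_components)


def simulate_mixed_networks(
    table: AbundanceTable,
    annotation: BrpAnnotation,
    thresholds: Thresholds | None = None,
    seed: int | None = None,
    n_components: int | str = "auto",
) -> ConsensusProfile:
    """Accumulate per-pair positive-sign counts over resampled communities.

    Each run draws ``n_nbrp_sample`` NBRP taxa uniformly without
    replacement, re-infers interactions on the combined community (original
    row order preserved), and records the sign of every ordered BRP-pair
    effect.
    """
    thr = thresholds or Thresholds()
    brp_table, nbrp_taxa = partition_taxa(table, annotation)
    if thr.n_nbrp_sample > len(nbrp_taxa):
        raise ValueError(
            f"cannot sample {thr.n_nbrp_sample} of {len(nbrp_taxa)} NBRP taxa"
        )
    rng = np.random.default_rng(seed)
    brp_set = set(brp_table.taxa)
    n = brp_table.n_taxa
    counts = np.zeros((n, n), dtype=int)
    for _ in range(thr.n_sim):
        chosen = set(rng.choice(nbrp_taxa, size=thr.n_nbrp_sample, replace=False))
        mixed_taxa = [t for t in table.taxa if t in brp_set or t in chosen]
        mixed = infer_interactions(table.subset(mixed_taxa), n_components=n_components)
        sub = mixed.subset(brp_table.taxa)
        counts += (sub.effects > 0).astype(int)
    np.fill_diagonal(counts, 0)
    return ConsensusProfile(
        taxa=list(brp_table.taxa), positive_counts=counts, n_sim=thr.n_sim, seed=seed
    )


def classify_interaction(
    strength: float, P: float, p_threshold: float = 0.95
) -> InteractionClass:
    """Consensus classification of one ordered pair (the four conditions)."""
    if not 0 <= P <= 1:
        raise ValueError(f"P must be in [0, 1], got {P}")
    if P >= p_threshold and strength > 0:
        return InteractionClass.CONFIDENT_ACTIVATION
    if P <= 1 - p_threshold and strength < 0:
        return InteractionClass.CONFIDENT_REPRESSION
    return InteractionClass.NON_CONFIDENT


def build_confident_network(
    raw: InteractionMatrix,
    consensus: ConsensusProfile,
    thresholds: Thresholds | None = None,
) -> ConfidentNetwork:
    """Keep the ordered pairs classified confident; strengths from the raw fit."""
    thr = thresholds or Thresholds()
    if raw.taxa != consensus.taxa:
        raise ValueError("raw network and consensus profile cover different taxa")
    P = consensus.P
    rows = []
    for i, target in enumerate(raw.taxa):
        for j, source in enumerate(raw.taxa):
            if i == j:
                continue
            cls = classify_interaction(raw.effects[i, j], P[i, j], thr.p_threshold)
            if cls is not InteractionClass.NON_CONFIDENT:
                rows.append(
                    (source, target, raw.effects[i, j], cls.value, P[i, j])
                )
    edges = pd.DataFrame(rows, columns=["source", "target", "strength", "sign", "P"])
    return ConfidentNetwork(edges=edges, taxa=list(raw.taxa), condition=raw.condition)


class ConsensusNetworkFilter(BaseEstimator):
    """End-to-end confident-network construction as a fittable estimator.

    ``fit(table, annotation)`` runs the raw BRP fit, the ``n_sim``
    resampled mixed-community fits, and the consensus classification.

    Attributes
    ----------
    raw_ : InteractionMatrix
    consensus_ : ConsensusProfile
    network_ : ConfidentNetwork
    """

    def __init__(
        self,
        n_sim: int = 1000,
        n_nbrp_sample: int = 120,
        p_threshold: float = 0.95,
        n_components: int | str = "auto",
        seed: int | None = None,
    ):
        self.n_sim = n_sim
        self.n_nbrp_sample = n_nbrp_sample
        self.p_threshold = p_threshold
        self.n_components = n_components
        self.seed = seed

    def fit(self, table: AbundanceTable, annotation: BrpAnnotation) -> "ConsensusNetworkFilter":
        thr = Thresholds(
            n_sim=self.n_sim,
            n_nbrp_sample=self.n_nbrp_sample,
            p_threshold=self.p_threshold,
        )
        brp_table, _ = partition_taxa(table, annotation)
        self.raw_ = raw_brp_network(brp_table, n_components=self.n_components)
        self.consensus_ = simulate_mixed_networks(
            table, annotation, thr, seed=self.seed, n_components=self.n_components
        )
        self.network_ = build_confident_network(self.raw_, self.consensus_, thr)
        return self
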