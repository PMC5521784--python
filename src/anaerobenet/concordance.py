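"""Concordance of inferred interactions with metabolic trophic indices.

Pairs of organisms carry two indices derived from genome-scale metabolic
models, both in [0, 1]: the complementarity index (fraction of one
organism's required nutrients that the other can synthesize — trophic
dependence) and the competition index (fraction of required nutrients
shared — trophic overlap). Species-pair indices are averaged into ordered
family pairs, joined to the inferred network edges, and the interaction
strengths are regressed on the matching index: positive strengths on
complementarity, negative strengths on competition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .confidence import ConfidentNetwork

__all__ = [
    "TrophicIndexTable",
    "RegressionResult",
    "read_index_table",
    "aggregate_to_family",
    "match_edges",
    "strength_index_regression",
]


@dataclass
class TrophicIndexTable:
    """Ordered taxon pairs with complementarity and competition indices.

    ``pairs`` columns: taxon_a, taxon_b, complementarity, competition.
    ``level`` is "species" or "family". Indices are directional:
    (a, b) need not equal (b, a).
    """

    pairs: pd.DataFrame
    level: str = "species"

    def __post_init__(self) -> None:
        required = {"taxon_a", "taxon_b", "complementarity", "competition"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise ValueError(f"index table missing columns {sorted(missing)}")
        for col in ("complementarity", "competition"):
            v = self.pairs[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{col} values must lie in [0, 1]")
        if self.pairs.duplicated(subset=["taxon_a", "taxon_b"]).any():
            raise ValueError("duplicate ordered pairs in index table")


@dataclass
class RegressionResult:
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def read_index_table(path, level: str = "species") -> TrophicIndexTable:
    df = pd.read_csv(path, sep="\t")
    return TrophicIndexTable(pairs=df, level=level)


def aggregate_to_family(
    species_table: TrophicIndexTable, species_to_family: dict[str, str]
) -> TrophicIndexTable:
    """Average species-pair indices within each ordered family pair."""
    df = species_table.pairs.copy()
    for col in ("taxon_a", "taxon_b"):
        unmapped = sorted(set(df[col]) - set(species_to_family))
        if unmapped:
            raise ValueError(f"unmapped species: {unmapped[:5]}")
        df[col] = df[col].map(species_to_family)
    out = (
        df.groupby(["taxon_a", "taxon_b"], as_index=False)[
            ["complementarity", "competition"]
        ]
        .mean()
        .sort_values(["taxon_a", "taxon_b"])
        .reset_index(drop=True)
    )
    return TrophicIndexTable(pairs=out, level="family")


def match_edges(
    network: ConfidentNetwork, indices: TrophicIndexTable
) -> tuple[pd.DataFrame, int]:
    """Inner-join network edges with the index table on (source, target).

    Returns the matched records (strength, complementarity, competition)
    and the count of edges that had no trophic information.
    """
    merged = network.edges.merge(
        indices.pairs,
        left_on=["source", "target"],
        right_on=["taxon_a", "taxon_b"],
        how="inner",
    )[["source", "target", "strength", "complementarity", "competition"]]
    return merged, len(network.edges) - len(merged)


def strength_index_regression(records: pd.DataFrame, subset: str) -> RegressionResult:
    """OLS of interaction strength on the matching trophic index.

    ``subset="positive"`` regresses strengths > 0 on the complementarity
    index; ``subset="negative"`` regresses strengths < 0 on the competition
    index. The p-value is the F-test with (1, n-2) degrees of freedom,
    identical to the two-sided t-test on the slope.
    """
    if subset == "positive":
        sel = records[records["strength"] > 0]
        x = sel["complementarity"].to_numpy(dtype=float)
    elif subset == "negative":
        sel = records[records["strength"] < 0]
        x = sel["competition"].to_numpy(dtype=float)
    else:
        raise ValueError(f"subset must be 'positive' or 'negative', got {subset!r}")
    y = sel["strength"].to_numpy(dtype=float)
    n = len(sel)
    if n < 3:
        raise ValueError(f"need at least 3 records, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("index values are constant; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )
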