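"""Fold-change differential-abundance calling between two reactor conditions.

For each taxon and time point the treatment/reference abundance ratio is
computed (zeros on either side make the ratio "ignored", encoded 0), turned
into a binary differential status against a fold threshold (default 2), and
a taxon is called differentially abundant when enough time points are
differential in both the early stage (first ``t_cut`` samples, >= 4 by
default) and the late stage (>= 2). Requiring late-stage support avoids
calling taxa that differ only during reactor start-up. Running the
procedure in both reference directions yields an UP/DN/NONE direction per
taxon (UP = more abundant under the treatment condition, by convention the
thermophilic reactor).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .table import AbundanceTable, Thresholds

__all__ = [
    "Direction",
    "FoldChangeMatrix",
    "DifferentialCall",
    "DifferentialAbundanceCaller",
    "fold_change",
    "differential_status",
    "call_differential",
    "differential_table",
]


class Direction(enum.Enum):
    UP = "UP"
    DN = "DN"
    NONE = "NONE"
    CONFLICT = "CONFLICT"


@dataclass
class FoldChangeMatrix:
    """Taxa x days matrix of treatment/reference abundance ratios.

    A stored 0 encodes "ignored" (zero abundance on either side), not a
    true zero ratio.
    """

    taxa: list[str]
    days: list[int]
    folds: np.ndarray

    def __post_init__(self) -> None:
        self.folds = np.asarray(self.folds, dtype=float)
        if np.any(self.folds < 0):
            raise ValueError("fold changes must be nonnegative")
        if self.folds.shape != (len(self.taxa), len(self.days)):
            raise ValueError("folds shape does not match taxa/days")


@dataclass
class DifferentialCall:
    taxon: str
    index_vector: np.ndarray
    early_sum: int
    late_sum: int
    is_differential: bool
    direction: Direction = Direction.NONE


def _check_matched(a: AbundanceTable, b: AbundanceTable) -> None:
    if a.taxa != b.taxa:
        raise ValueError("tables have different taxa")
    if a.days != b.days:
        raise ValueError("tables have different day labels")


def fold_change(treatment: AbundanceTable, reference: AbundanceTable) -> FoldChangeMatrix:
    """Elementwise treatment/reference ratio; 0 where either value is 0."""
    _check_matched(treatment, reference)
    t, r = treatment.values, reference.values
    folds = np.zeros_like(t)
    ok = (t > 0) & (r > 0)
    folds[ok] = t[ok] / r[ok]
    return FoldChangeMatrix(taxa=list(treatment.taxa), days=list(treatment.days), folds=folds)


def differential_status(
    folds: FoldChangeMatrix, thresholds: Thresholds | None = None
) -> np.ndarray:
    """Binary matrix: 1 where the fold change meets the threshold (>=)."""
    thr = thresholds or Thresholds()
    return (folds.folds >= thr.fold_threshold).astype(int)


def call_differential(
    index_matrix: np.ndarray,
    taxa: list[str],
    thresholds: Thresholds | None = None,
) -> list[DifferentialCall]:
    """Apply the early/late two-stage rule to per-taxon binary status rows.

    A taxon is differential iff its first ``t_cut`` statuses sum to at least
    ``early_min`` and the remaining ones to at least ``late_min``.
    """
    thr = thresholds or Thresholds()
    index_matrix = np.asarray(index_matrix)
    if index_matrix.ndim != 2 or index_matrix.shape[0] != len(taxa):
        raise ValueError("index matrix must be taxa x time points")
    t = index_matrix.shape[1]
    if thr.t_cut >= t:
        raise ValueError(f"t_cut={thr.t_cut} must be < number of time points {t}")
    calls = []
    for i, taxon in enumerate(taxa):
        vec = index_matrix[i]
        early = int(vec[: thr.t_cut].sum())
        late = int(vec[thr.t_cut :].sum())
        calls.append(
            DifferentialCall(
                taxon=taxon,
                index_vector=vec,
                early_sum=early,
                late_sum=late,
                is_differential=(early >= thr.early_min and late >= thr.late_min),
            )
        )
    return calls


class DifferentialAbundanceCaller(BaseEstimator):
    """Two-direction differential caller over a pair of condition tables.

    Parameters mirror :class:`~anaerobenet.table.Thresholds`. ``fit`` takes
    the mesophilic and thermophilic tables; per-taxon directions are then in
    ``calls_`` (a DataFrame) and ``directions_`` (taxon -> Direction).

    Direction semantics: UP means differential with the mesophilic table as
    reference (more abundant under thermophilic conditions); DN the
    converse; a taxon differential in both directions — possible only on
    pathological input — is flagged CONFLICT rather than dropped.
    """

    def __init__(
        self,
        fold_threshold: float = 2.0,
        t_cut: int = 7,
        early_min: int = 4,
        late_min: int = 2,
    ):
        self.fold_threshold = fold_threshold
        self.t_cut = t_cut
        self.early_min = early_min
        self.late_min = late_min

    def _thresholds(self) -> Thresholds:
        return Thresholds(
            fold_threshold=self.fold_threshold,
            t_cut=self.t_cut,
            early_min=self.early_min,
            late_min=self.late_min,
        )

    def fit(self, meso: AbundanceTable, thermo: AbundanceTable) -> "DifferentialAbundanceCaller":
        _check_matched(meso, thermo)
        thr = self._thresholds()

        up_calls = call_differential(
            differential_status(fold_change(thermo, meso), thr), meso.taxa, thr
        )
        dn_calls = call_differential(
            differential_status(fold_change(meso, thermo), thr), meso.taxa, thr
        )

        directions: dict[str, Direction] = {}
        rows = []
        for up, dn in zip(up_calls, dn_calls):
            if up.is_differential and dn.is_differential:
                d = Direction.CONFLICT
            elif up.is_differential:
                d = Direction.UP
            elif dn.is_differential:
                d = Direction.DN
            else:
                d = Direction.NONE
            directions[up.taxon] = d
            rows.append(
                (
                    up.taxon,
                    up.early_sum,
                    up.late_sum,
                    dn.early_sum,
                    dn.late_sum,
                    d.value,
                )
            )
        self.directions_ = directions
        self.calls_ = pd.DataFrame(
            rows,
            columns=[
                "taxon",
                "up_early_sum",
                "up_late_sum",
                "dn_early_sum",
                "dn_late_sum",
                "direction",
            ],
        )
        return self

    def predict(self, taxa: list[str] | None = None) -> list[Direction]:
        if not hasattr(self, "directions_"):
            raise RuntimeError("call fit first")
        taxa = taxa if taxa is not None else list(self.directions_)
        return [self.directions_[t] for t in taxa]


def differential_table(
    meso: AbundanceTable,
    thermo: AbundanceTable,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Per-taxon direction table (thin wrapper over the caller estimator)."""
    thr = thresholds or Thresholds()
    caller = DifferentialAbundanceCaller(
        fold_threshold=thr.fold_threshold,
        t_cut=thr.t_cut,
        early_min=thr.early_min,
        late_min=thr.late_min,
    ).fit(meso, thermo)
    return caller.calls_
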