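"""Family-level time-series abundance tables.

The central container is :class:`AbundanceTable`: a taxa x time-points matrix
of relative abundances from one reactor condition (e.g. mesophilic or
thermophilic anaerobic digestion), with integer day labels. Helpers cover
compositional closure, the nonzero-mean abundance statistic, the
high/low/rare abundance classification, Shannon diversity and analytic
rarefaction.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "AbundanceTable",
    "AbundanceClass",
    "Thresholds",
    "read_abundance_table",
    "mean_nonzero",
    "classify_abundance",
    "shannon_index",
    "rarefaction_curve",
]


class AbundanceClass(enum.Enum):
    """Mean-abundance class of a taxon.

    HIGH: mean relative abundance strictly above 1% of total sequences.
    LOW: between 0.1% and 1% inclusive ("low-abundance non-rare").
    RARE: strictly below 0.1%.
    """

    HIGH = "high"
    LOW = "low"
    RARE = "rare"


@dataclass(frozen=True)
class Thresholds:
    """All tunable cutoffs of the analysis chain, with study defaults.

    Parameters
    ----------
    high_cut, low_cut : float
        Abundance-class boundaries as fractions (1% and 0.1%).
    fold_threshold : float
        Fold-change ratio above which a time point counts as differential.
    t_cut : int
        Index splitting the time series into early (k <= t_cut) and late
        (k > t_cut) stages; the study used 7 of 10 samples.
    early_min, late_min : int
        Minimum number of differential time points required in each stage.
    p_threshold : float
        Consensus probability needed for a confident interaction (0.95).
    n_sim : int
        Number of resampled mixed-network fits (1000 in the study).
    n_nbrp_sample : int
        NBRP families drawn per resampling run (120 in the study).
    """

    high_cut: float = 0.01
    low_cut: float = 0.001
    fold_threshold: float = 2.0
    t_cut: int = 7
    early_min: int = 4
    late_min: int = 2
    p_threshold: float = 0.95
    n_sim: int = 1000
    n_nbrp_sample: int = 120

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut < 1:
            raise ValueError(
                f"need 0 < low_cut < high_cut < 1, got {self.low_cut}, {self.high_cut}"
            )
        if not 0.5 < self.p_threshold <= 1:
            raise ValueError(f"p_threshold must be in (0.5, 1], got {self.p_threshold}")
        if self.fold_threshold <= 0:
            raise ValueError("fold_threshold must be positive")
        if self.n_sim < 1 or self.n_nbrp_sample < 1:
            raise ValueError("n_sim and n_nbrp_sample must be >= 1")


@dataclass
class AbundanceTable:
    """Taxa x days matrix of relative abundances for one condition.

    Attributes
    ----------
    taxa : list of str
        Unique family-level labels, one per row.
    days : list of int
        Strictly increasing sampling-day labels, one per column.
    values : ndarray of shape (n_taxa, n_days)
        Nonnegative relative abundances (fractions).
    condition : str
        Free-text condition tag, e.g. ``"mesophilic"``.
    """

    taxa: list[str]
    days: list[int]
    values: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.taxa) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.taxa)} taxa but {self.values.shape[0]} rows"
            )
        if len(self.days) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.days)} days but {self.values.shape[1]} columns"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError(f"days must be strictly increasing, got {self.days}")
        if np.any(self.values < 0):
            raise ValueError("abundances must be nonnegative")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("abundances must be finite")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_times(self) -> int:
        return len(self.days)

    def row(self, taxon: str) -> np.ndarray:
        """Abundance vector of one taxon over time."""
        try:
            i = self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None
        return self.values[i]

    def subset(self, taxa: Sequence[str]) -> "AbundanceTable":
        """Row-subset preserving the requested taxon order."""
        idx = []
        for t in taxa:
            try:
                idx.append(self.taxa.index(t))
            except ValueError:
                raise KeyError(f"unknown taxon {t!r}") from None
        return AbundanceTable(
            taxa=list(taxa),
            days=list(self.days),
            values=self.values[idx].copy(),
            condition=self.condition,
        )

    def to_relative(self) -> "AbundanceTable":
        """Close each column to sum 1 (compositional closure).

        Raises
        ------
        ValueError
            If any column is all zero.
        """
        sums = self.values.sum(axis=0)
        if np.any(sums <= 0):
            bad = [self.days[k] for k in np.nonzero(sums <= 0)[0]]
            raise ValueError(f"all-zero column(s) at day(s) {bad}")
        return replace(self, values=self.values / sums)

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view with ``T_<day>`` column labels."""
        return pd.DataFrame(
            self.values, index=self.taxa, columns=[f"T_{d}" for d in self.days]
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "taxon"
        df.to_csv(path, sep="\t")


_DAY_RE = re.compile(r"^T[_\s]?(\d+)$|^(\d+)$")


def _parse_day(label: str) -> int:
    m = _DAY_RE.match(str(label).strip())
    if not m:
        raise ValueError(f"cannot parse day label {label!r} (expected 'T_<int>' or integer)")
    return int(m.group(1) or m.group(2))


def read_abundance_table(path, condition: str = "", percent: bool = False) -> AbundanceTable:
    """Read a taxa x days TSV into an :class:`AbundanceTable`.

    The header row holds day labels (``T_18`` style or bare integers); the
    first column holds taxon labels. ``percent=True`` divides all values by
    100 (tables reported as % of total sequences).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    days = [_parse_day(c) for c in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from None
    if percent:
        values = values / 100.0
    return AbundanceTable(
        taxa=[str(t) for t in df.index], days=days, values=values, condition=condition
    )


def mean_nonzero(table: AbundanceTable, taxon: str) -> float:
    """Mean relative abundance over the samples where the taxon is present.

    The sum of the taxon's abundances is divided by the number of time
    points with strictly positive abundance, so sporadic taxa are not
    diluted by their absences. A taxon that is zero everywhere returns 0.
    """
    x = table.row(taxon)
    n_nonzero = int(np.count_nonzero(x > 0))
    if n_nonzero == 0:
        return 0.0
    return float(x.sum() / n_nonzero)


def classify_abundance(
    mean_percent: float, thresholds: Thresholds | None = None
) -> AbundanceClass:
    """Classify a mean abundance (in percent) as HIGH, LOW or RARE.

    HIGH is strictly above ``high_cut`` (1%); the LOW band [0.1%, 1%] is
    inclusive on both ends; below it is RARE.
    """
    thr = thresholds or Thresholds()
    if mean_percent < 0:
        raise ValueError(f"mean abundance must be >= 0, got {mean_percent}")
    frac = mean_percent / 100.0
    if frac > thr.high_cut:
        return AbundanceClass.HIGH
    if frac >= thr.low_cut:
        return AbundanceClass.LOW
    return AbundanceClass.RARE


def annotate_classes(table: AbundanceTable, thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Per-taxon mean abundance (nonzero-mean) and abundance class."""
    rows = []
    for taxon in table.taxa:
        m = mean_nonzero(table, taxon)
        rows.append((taxon, m, classify_abundance(m * 100.0, thresholds).value))
    return pd.DataFrame(rows, columns=["taxon", "mean_abundance", "class"])


def shannon_index(column: np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) of one sample.

    The vector is normalized to proportions first; zero entries contribute
    nothing.
    """
    x = np.asarray(column, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot compute diversity of an all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def rarefaction_curve(counts: Sequence[int], depths: Sequence[int]) -> np.ndarray:
    """Expected taxon richness at each subsampling depth, computed exactly.

    Uses the hypergeometric expectation
    ``E[S(d)] = sum_i 1 - C(T - c_i, d) / C(T, d)`` with T the total count,
    which is the mean over all equally likely subsamples of size d — no
    random resampling involved.
    """
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        if not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integers")
        c = np.round(c).astype(int)
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    total = int(c.sum())
    c = c[c > 0]
    out = np.empty(len(depths), dtype=float)
    for k, d in enumerate(depths):
        d = int(d)
        if d < 0 or d > total:
            raise ValueError(f"depth {d} outside [0, {total}]")
        if d == 0:
            out[k] = 0.0
            continue
        # P(taxon i absent from the subsample) = C(T-c_i, d)/C(T, d),
        # evaluated in log space for numerical range.
        keep = total - c >= d
        log_absent = (
            gammaln(total - c[keep] + 1)
            - gammaln(d + 1)
            - gammaln(total - c[keep] - d + 1)
            - (gammaln(total + 1) - gammaln(d + 1) - gammaln(total - d + 1))
        )
        out[k] = (len(c) - keep.sum()) + float((1.0 - np.exp(log_absent)).sum())
    return out
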