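"""Pairwise Jaccard-family taxonomic beta-diversity and its additive
partition into turnover and nestedness-resultant dissimilarity.

For a pair of assemblages with a shared species, b unique to the first and c
unique to the second:

    beta     = (b + c) / (a + b + c)                      (Jaccard dissimilarity)
    turnover = 2 min(b, c) / (a + 2 min(b, c))
    nestedness = beta - turnover
               = (|b - c| / (a + b + c)) * (a / (a + 2 min(b, c)))

The partition is additive by construction; "nestedness" here is the
nestedness-resultant fraction of total dissimilarity, not a measure of true
nestedness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import OccurrenceMatrix


class UndefinedPairError(ValueError):
    """Both assemblages empty: the dissimilarity is undefined."""


@dataclass(frozen=True)
class PairCounts:
    """Shared (a) and unique (b, c) species counts for one basin pair."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("pair counts must be non-negative")


@dataclass(frozen=True)
class BetaTriple:
    """One pair's dissimilarity and its two additive components."""

    beta: float
    turnover: float
    nestedness: float


@dataclass
class PairwiseBetaTable:
    """All unordered basin-pair BetaTriples for one facet and scenario."""

    facet: str  # "taxonomic" | "functional"
    scenario: str
    basin_pairs: list[tuple[str, str]]
    values: np.ndarray  # n_pairs x 3 columns: beta, turnover, nestedness

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.basin_pairs), 3):
            raise ValueError("values must be n_pairs x 3")

    @property
    def n_pairs(self) -> int:
        return len(self.basin_pairs)

    @property
    def beta(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def turnover(self) -> np.ndarray:
        return self.values[:, 1]

    @property
    def nestedness(self) -> np.ndarray:
        return self.values[:, 2]

    def summary(self) -> dict[str, tuple[float, float]]:
        """Mean and sample SD (ddof=1) of each component over pairs."""
        out = {}
        for k, name in enumerate(("beta", "turnover", "nestedness")):
            col = self.values[:, k]
            out[name] = (float(col.mean()), float(col.std(ddof=1)))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "basin_i": [p[0] for p in self.basin_pairs],
                "basin_j": [p[1] for p in self.basin_pairs],
                "beta": self.values[:, 0],
                "turnover": self.values[:, 1],
                "nestedness": self.values[:, 2],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def pair_counts(x: Sequence[int] | np.ndarray, y: Sequence[int] | np.ndarray) -> PairCounts:
    """Shared/unique counts from two equal-length binary presence vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("presence vectors must be binary")
    xb = x.astype(bool)
    yb = y.astype(bool)
    return PairCounts(
        a=int((xb & yb).sum()),
        b=int((xb & ~yb).sum()),
        c=int((~xb & yb).sum()),
    )


def taxonomic_partition(pc: PairCounts) -> BetaTriple:
    """Jaccard dissimilarity partitioned into turnover + nestedness."""
    a, b, c = pc.a, pc.b, pc.c
    total = a + b + c
    if total == 0:
        raise UndefinedPairError("both assemblages empty: a = b = c = 0")
    beta = (b + c) / total
    mn = min(b, c)
    turnover = 2 * mn / (a + 2 * mn) if (a + 2 * mn) > 0 else 0.0
    nestedness = beta - turnover
    return BetaTriple(beta=beta, turnover=turnover, nestedness=nestedness)


def pairwise_taxonomic(occ: OccurrenceMatrix) -> PairwiseBetaTable:
    """BetaTriple for every unordered basin pair of an occurrence matrix.

    Raises :class:`UndefinedPairError` (naming the basins) if any basin is
    empty, since an empty assemblage makes its pairs undefined and silent
    NaNs would corrupt the pair means.
    """
    if occ.n_basins < 2:
        raise ValueError("need at least 2 basins")
    richness = occ.richness()
    empty = [occ.basins[j] for j in np.flatnonzero(richness == 0)]
    if empty:
        raise UndefinedPairError(f"empty basin(s): {empty}")
    X = occ.values.astype(np.int64)  # species x basins
    shared = X.T @ X  # a for every ordered pair
    only_i = richness[:, None] - shared  # b
    only_j = richness[None, :] - shared  # c
    iu, ju = np.triu_indices(occ.n_basins, k=1)
    a = shared[iu, ju].astype(float)
    b = only_i[iu, ju].astype(float)
    c = only_j[iu, ju].astype(float)
    total = a + b + c
    beta = (b + c) / total
    mn = np.minimum(b, c)
    denom = a + 2 * mn
    turnover = np.where(denom > 0, 2 * mn / np.where(denom > 0, denom, 1), 0.0)
    nestedness = beta - turnover
    pairs = [(occ.basins[i], occ.basins[j]) for i, j in zip(iu, ju)]
    return PairwiseBetaTable(
        facet="taxonomic",
        scenario=occ.scenario,
        basin_pairs=pairs,
        values=np.column_stack([beta, turnover, nestedness]),
    )
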