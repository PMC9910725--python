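"""Morpho-functional trait space: Gower distances and principal coordinates.

Five life-history traits describe each species: adult body length
(quantitative, cm) and four ordinal characters -- migration type (1-5),
adult diet (1-5), use of the water column (1-2: demersal/pelagic) and
fecundity class (1-4).  Gower distance range-normalises each trait over the
full species pool and averages absolute differences with equal weights, so
values lie in [0, 1].  Classical scaling (PCoA) of that matrix yields the
Euclidean axes on which assemblage convex hulls are built; the default is
the first three axes.

Ordinal traits are treated numerically with range normalisation (classic
Gower) rather than rank-transformed; body length enters untransformed.  Both
choices are switchable at table construction time by pre-transforming the
column, and are deliberately the simplest reading of mixed-trait Gower
coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import eigh

log = logging.getLogger(__name__)

#: trait name -> (kind, (lo, hi) for ordinal validation)
DEFAULT_TRAITS: dict[str, tuple[str, tuple[int, int] | None]] = {
    "body_length": ("quantitative", None),
    "migration": ("ordinal", (1, 5)),
    "diet": ("ordinal", (1, 5)),
    "water_column": ("ordinal", (1, 2)),
    "fecundity": ("ordinal", (1, 4)),
}


class DegenerateSpaceError(ValueError):
    """The requested embedding dimension is not supported by the data."""


@dataclass
class TraitTable:
    """Species x trait values with declared trait kinds."""

    species: list[str]
    data: pd.DataFrame  # columns = trait names, index = species
    kinds: dict[str, str] = field(
        default_factory=lambda: {k: v[0] for k, v in DEFAULT_TRAITS.items()}
    )

    def __post_init__(self) -> None:
        if list(self.data.index) != list(self.species):
            self.data = self.data.loc[self.species]
        unknown = set(self.data.columns) - set(self.kinds)
        if unknown:
            raise ValueError(f"traits without a declared kind: {sorted(unknown)}")
        if self.data.isna().any().any():
            missing = self.data.isna().stack()
            where = list(missing[missing].index[:3])
            raise ValueError(f"missing trait values (no imputation): {where}")
        for trait, (kind, bounds) in DEFAULT_TRAITS.items():
            if trait in self.data.columns and bounds is not None:
                col = self.data[trait]
                if ((col < bounds[0]) | (col > bounds[1])).any():
                    raise ValueError(
                        f"trait {trait!r} outside declared range {bounds}"
                    )

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def write_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "species_id"
        out.to_csv(path)


def read_trait_table(path: str | Path,
                     kinds: dict[str, str] | None = None) -> TraitTable:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str).str.strip()
    return TraitTable(
        species=list(df.index),
        data=df.astype(float),
        kinds=kinds or {k: v[0] for k, v in DEFAULT_TRAITS.items()},
    )


@dataclass
class DissimilarityMatrix:
    """Square symmetric dissimilarity matrix with species labels."""

    species: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if v.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        self.values = v


@dataclass
class FunctionalSpace:
    """Species coordinates on the first m principal axes of a PCoA."""

    species: list[str]
    coordinates: np.ndarray  # species x m
    eigenvalues: np.ndarray  # m, non-increasing, positive
    m: int
    quality: float | None = None

    def points_for(self, species_ids: list[str]) -> np.ndarray:
        idx = [self.species.index(s) for s in species_ids]
        return self.coordinates[idx]

    def write_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.coordinates,
            index=pd.Index(self.species, name="species_id"),
            columns=[f"axis_{k + 1}" for k in range(self.m)],
        )
        df.to_csv(path)


def gower_matrix(traits: TraitTable) -> DissimilarityMatrix:
    """Classic Gower distance: equal-weight mean of range-normalised
    absolute trait differences.

    Ranges are computed over the full species pool of the table, so a single
    shared space underlies all assemblage comparisons.  A trait with zero
    range contributes nothing and triggers a warning.
    """
    X = traits.data.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 species")
    D = np.zeros((n, n))
    for k in range(p):
        col = X[:, k]
        rng = col.max() - col.min()
        if rng == 0:
            log.warning("trait %r has zero range; it contributes 0 to Gower "
                        "distances", traits.traits[k])
            continue
        D += np.abs(col[:, None] - col[None, :]) / rng
    D /= p
    return DissimilarityMatrix(species=list(traits.species), values=D)


def pcoa_embed(d: DissimilarityMatrix, m: int = 3,
               correction: str | None = None) -> FunctionalSpace:
    """Classical scaling of a dissimilarity matrix onto its first m axes.

    Double-centres -d^2/2, eigendecomposes, and keeps the m leading positive
    eigenvalues.  Negative eigenvalues are dropped by default;
    ``correction="lingoes"`` adds the Lingoes constant to off-diagonal
    squared dissimilarities instead.  The sign of each axis is fixed so that
    its first nonzero loading is positive, making the embedding
    deterministic.
    """
    D = d.values
    n = D.shape[0]
    D2 = D ** 2
    if correction == "lingoes":
        B0 = _double_centre(D2)
        evals0 = eigh(B0, eigvals_only=True)
        cmin = evals0.min()
        if cmin < 0:
            off = ~np.eye(n, dtype=bool)
            D2 = D2.copy()
            D2[off] += 2.0 * (-cmin)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    B = _double_centre(D2)
    evals, evecs = eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals[0])) if evals.size else 0.0
    n_pos = int((evals > tol).sum())
    if m < 1 or m > n_pos:
        raise DegenerateSpaceError(
            f"requested m={m} axes but only {n_pos} positive eigenvalue(s) "
            f"are available"
        )
    lam = evals[:m]
    V = evecs[:, :m]
    coords = V * np.sqrt(lam)
    # deterministic sign convention: first nonzero loading of each axis > 0
    for k in range(m):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    return FunctionalSpace(
        species=list(d.species),
        coordinates=coords,
        eigenvalues=lam,
        m=m,
    )


def _double_centre(D2: np.ndarray) -> np.ndarray:
    n = D2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * J @ D2 @ J


def space_quality(d: DissimilarityMatrix, space: FunctionalSpace) -> float:
    """Mean squared deviation between the trait-based dissimilarities and the
    embedding's Euclidean distances; lower is better, 0 for a perfect
    embedding."""
    from scipy.spatial.distance import pdist, squareform

    e = squareform(pdist(space.coordinates))
    iu = np.triu_indices(len(d.species), k=1)
    dev = d.values[iu] - e[iu]
    return float(np.mean(dev ** 2))
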