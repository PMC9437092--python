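"""Functional trait space construction.

Builds everything downstream modules need from a raw species x trait table:

* pairwise Gower dissimilarity (mixed trait types, pairwise deletion of
  missing values),
* a Principal Coordinates Analysis (classical metric scaling) embedding,
* a regular grid over the first (up to) two axes whose occupied cells are
  the "functional entities",
* the species -> grid-cell assignment, and
* per-species functional distinctiveness D_i (mean dissimilarity to all
  other species, range [0, 1]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import rankdata

logger = logging.getLogger("funvul")

TRAIT_KINDS = ("continuous", "ordinal", "nominal", "binary")

#: species with coordinates outside the grid by more than this are a bug
GRID_TOLERANCE = 1e-9


class FunvulError(ValueError):
    """Base class for domain errors raised by this package."""


class IncomparableSpeciesPairError(FunvulError):
    """Two species share no jointly observed trait."""


# ---------------------------------------------------------------------------
# Trait table
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Species x trait values with a declared kind per trait.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by species id, one column per trait.  Missing values
        are NaN (continuous/ordinal) or NaN/None (categorical).
    kinds : dict
        Maps every column name to one of ``continuous``, ``ordinal``,
        ``nominal``, ``binary``.
    ordinal_levels : dict, optional
        For ordinal traits coded as labels, the ordered list of levels.
        Numeric ordinal columns need no declaration (their natural order
        is used).
    """

    values: pd.DataFrame
    kinds: dict[str, str]
    ordinal_levels: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[0] < 2:
            raise FunvulError("trait table needs at least 2 species")
        if df.shape[1] < 1:
            raise FunvulError("trait table needs at least 1 trait")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FunvulError(f"duplicate species ids in trait table: {dups}")
        missing_kind = [c for c in df.columns if c not in self.kinds]
        if missing_kind:
            raise FunvulError(f"no trait kind declared for: {missing_kind}")
        for col, kind in self.kinds.items():
            if kind not in TRAIT_KINDS:
                raise FunvulError(f"unknown trait kind {kind!r} for trait {col!r}")
        all_missing = df.index[df.isna().all(axis=1)].tolist()
        if all_missing:
            raise FunvulError(
                f"species with all trait values missing: {all_missing}"
            )

    @property
    def species_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    def subset(self, species: list) -> "TraitTable":
        return TraitTable(self.values.loc[species], self.kinds, self.ordinal_levels)


@dataclass
class DissimilarityMatrix:
    """Square symmetric matrix of pairwise dissimilarities in [0, 1]."""

    species_ids: list
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        s = len(self.species_ids)
        if d.shape != (s, s):
            raise FunvulError("dissimilarity matrix shape does not match species")
        if not np.allclose(d, d.T, atol=1e-12):
            raise FunvulError("dissimilarity matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise FunvulError("dissimilarity matrix has non-zero diagonal")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise FunvulError("dissimilarities must lie in [0, 1]")
        self.data = np.clip(d, 0.0, 1.0)
        np.fill_diagonal(self.data, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.species_ids, columns=self.species_ids)


# ---------------------------------------------------------------------------
# Gower dissimilarity
# ---------------------------------------------------------------------------


def _ordinal_ranks(col: pd.Series, levels: list | None) -> np.ndarray:
    """Rank-transform an ordinal column (Podani-style), NaN preserved."""
    vals = col.to_numpy(dtype=object)
    mask = pd.notna(vals)
    out = np.full(len(vals), np.nan)
    if levels is not None:
        coded = np.array(
            [float(levels.index(v)) if ok else np.nan for v, ok in zip(vals, mask)]
        )
    else:
        coded = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
    out[mask] = rankdata(coded[mask])
    return out


def compute_gower(traits: TraitTable) -> DissimilarityMatrix:
    """Pairwise Gower dissimilarity over mixed-type traits.

    Per-trait partial dissimilarities: continuous and (rank-transformed)
    ordinal traits use |x_i - x_j| divided by the trait's observed range;
    nominal/binary traits contribute 0 for a match and 1 otherwise.  Each
    pair is averaged over the traits both species have observed (pairwise
    deletion).  A trait with zero range is excluded with a warning; a pair
    of species sharing no observed trait is an error.
    """
    df = traits.values
    s = df.shape[0]
    partial_sum = np.zeros((s, s))
    valid_count = np.zeros((s, s))

    for col in df.columns:
        kind = traits.kinds[col]
        series = df[col]
        if kind in ("continuous", "ordinal"):
            if kind == "ordinal":
                x = _ordinal_ranks(series, traits.ordinal_levels.get(col))
            else:
                x = pd.to_numeric(series, errors="raise").to_numpy(dtype=float)
            mask = ~np.isnan(x)
            if mask.sum() == 0:
                continue
            rng = np.nanmax(x) - np.nanmin(x)
            if rng == 0:
                logger.warning(
                    "trait %r has zero range over observed values; excluded from Gower",
                    col,
                )
                continue
            diff = np.abs(x[:, None] - x[None, :]) / rng
        else:  # nominal / binary
            vals = series.to_numpy(dtype=object)
            mask = pd.notna(vals)
            eq = vals[:, None] == vals[None, :]
            diff = np.where(eq, 0.0, 1.0)
        both = mask[:, None] & mask[None, :]
        partial_sum += np.where(both, diff, 0.0)
        valid_count += both

    np.fill_diagonal(valid_count, np.maximum(np.diag(valid_count), 1))
    bad = np.argwhere(valid_count == 0)
    if bad.size:
        i, j = bad[0]
        ids = traits.species_ids
        raise IncomparableSpeciesPairError(
            f"incomparable species pair: {ids[i]!r} and {ids[j]!r} share no "
            "jointly observed trait"
        )
    d = partial_sum / valid_count
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against fp noise
    return DissimilarityMatrix(traits.species_ids, d)


# ---------------------------------------------------------------------------
# Principal Coordinates Analysis (classical metric scaling)
# ---------------------------------------------------------------------------


@dataclass
class TraitSpace:
    """PCoA embedding: per-species coordinates on axes ordered by eigenvalue.

    Only positive-eigenvalue axes are kept; ``n_axes_used`` records how
    many (at most two) feed the functional-entity grid.
    """

    species_ids: list
    coordinates: np.ndarray  # (S, n_positive_axes)
    eigenvalues: np.ndarray  # (n_positive_axes,), non-increasing
    n_axes_used: int

    def grid_coordinates(self) -> np.ndarray:
        """Coordinates on the axes used for the grid, always (S, 2).

        When only one axis is usable the second column is zero, which
        collapses the grid to a single row.
        """
        out = np.zeros((len(self.species_ids), 2))
        k = min(self.n_axes_used, 2)
        out[:, :k] = self.coordinates[:, :k]
        return out


def compute_pcoa(d: DissimilarityMatrix) -> TraitSpace:
    """Classical metric scaling of a dissimilarity matrix.

    Double-centers -0.5 * J D^2 J, eigendecomposes, and keeps eigenvectors
    scaled by sqrt(eigenvalue) for positive eigenvalues only.  Negative
    eigenvalues are dropped without correction (their count is logged).
    """
    dm = d.data
    s = dm.shape[0]
    if np.all(dm == 0):
        raise FunvulError("no trait variation: all dissimilarities are zero")
    j = np.eye(s) - np.ones((s, s)) / s
    b = -0.5 * j @ (dm**2) @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10
    positive = eigval > tol
    n_neg = int(np.sum(eigval < -tol))
    if n_neg:
        logger.info("PCoA dropped %d negative eigenvalue(s)", n_neg)
    if not positive.any():
        raise FunvulError("no trait variation: no positive PCoA eigenvalue")
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    n_used = min(2, int(positive.sum()))
    return TraitSpace(
        species_ids=list(d.species_ids),
        coordinates=coords,
        eigenvalues=eigval[positive],
        n_axes_used=n_used,
    )


# ---------------------------------------------------------------------------
# Functional-entity grid
# ---------------------------------------------------------------------------


@dataclass
class EntityGrid:
    """Regular R x R grid over the 2-D trait space.

    Bounds come from the extreme species; a degenerate axis (no spread)
    collapses to a single row or column so the grid is then R x 1.
    """

    resolution: int
    mins: np.ndarray  # (2,)
    maxs: np.ndarray  # (2,)

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise FunvulError("grid resolution must be >= 2")
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if not (np.isfinite(self.mins).all() and np.isfinite(self.maxs).all()):
            raise FunvulError("grid bounds must be finite")

    @property
    def axis_resolutions(self) -> tuple[int, int]:
        spans = self.maxs - self.mins
        return tuple(self.resolution if sp > 0 else 1 for sp in spans)

    @property
    def cell_widths(self) -> np.ndarray:
        spans = self.maxs - self.mins
        res = np.array(self.axis_resolutions, dtype=float)
        widths = np.where(spans > 0, spans / res, 1.0)
        return widths

    @property
    def diagonal(self) -> float:
        return float(np.sqrt(np.sum((self.maxs - self.mins) ** 2)))

    def cell_center(self, cell: tuple[int, int]) -> np.ndarray:
        idx = np.asarray(cell, dtype=float)
        return self.mins + (idx + 0.5) * self.cell_widths


def build_entity_grid(space: TraitSpace, resolution: int = 20) -> EntityGrid:
    """Place a regular grid over the used axes, bounded by extreme species."""
    coords = space.grid_coordinates()
    mins, maxs = coords.min(axis=0), coords.max(axis=0)
    if np.all(maxs - mins <= 0):
        raise FunvulError("degenerate trait space: fewer than 2 distinct positions")
    return EntityGrid(resolution=resolution, mins=mins, maxs=maxs)


@dataclass
class EntityAssignment:
    """Species -> grid cell (row, col); N = number of occupied cells."""

    species_ids: list
    cells: list[tuple[int, int]]

    @property
    def n_entities(self) -> int:
        return len(set(self.cells))

    def as_dict(self) -> dict:
        return dict(zip(self.species_ids, self.cells))


def assign_entities(space: TraitSpace, grid: EntityGrid) -> EntityAssignment:
    """Bin species into grid cells.

    Cells are half-open [low, high) except the last cell on each axis,
    which is closed above so the extreme species stay inside the grid.
    """
    coords = space.grid_coordinates()
    res = np.array(grid.axis_resolutions)
    widths = grid.cell_widths
    rel = coords - grid.mins
    span = grid.maxs - grid.mins
    if np.any(rel < -GRID_TOLERANCE) or np.any(rel - span > GRID_TOLERANCE):
        raise FunvulError("internal consistency: species coordinate outside grid bounds")
    idx = np.floor(rel / widths).astype(int)
    idx = np.clip(idx, 0, res - 1)
    cells = [tuple(map(int, row)) for row in idx]
    return EntityAssignment(list(space.species_ids), cells)


# ---------------------------------------------------------------------------
# Functional distinctiveness (D_i)
# ---------------------------------------------------------------------------


def compute_distinctiveness(d: DissimilarityMatrix) -> pd.Series:
    """Mean dissimilarity of each species to all others: D_i = sum_j d_ij / (S-1).

    Because the dissimilarities are standardized to [0, 1], so is D_i.
    Returned as a Series indexed by species id.
    """
    s = d.data.shape[0]
    if s < 2:
        raise FunvulError("distinctiveness needs at least 2 species")
    di = (d.data.sum(axis=1)) / (s - 1)
    return pd.Series(di, index=d.species_ids, name="distinctiveness")
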