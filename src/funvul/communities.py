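"""Observed community state and construction of extreme virtual communities.

A virtual community is an in-silico rearrangement of the observed one,
crossing three properties: the distribution of functional redundancy over
the occupied entities, the distribution of weights (abundance) over
species, and the sign of the distinctiveness-weight pairing.  The crossing
yields 15 virtual communities in abundance/suitability mode; occurrence
data support only the two opposite redundancy distributions.  Every virtual
community conserves the observed richness S, total weight T, and the set of
occupied functional entities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trait_space import EntityGrid, FunvulError

logger = logging.getLogger("funvul")

MODES = ("abundance", "occurrence", "suitability")

REDUNDANCY_MODALITIES = ("observed", "homogeneous", "heterogeneous")
WEIGHT_MODALITIES = ("observed", "homogeneous", "heterogeneous")
PAIRING_SIGNS = ("positive", "negative", "none")


@dataclass
class CommunityState:
    """One community: species ids, entity cells, and per-species weights.

    Weights are abundances, 0/1 occurrences, or habitat suitabilities in
    [0, 1] depending on ``mode``.  Only species with positive weight
    belong to the state (S = number of species).
    """

    species_ids: list
    cells: list[tuple[int, int]]
    weights: np.ndarray
    mode: str
    #: virtual rearrangements conserve total weight, so a single species may
    #: exceed the [0, 1] suitability bound that observed data must respect
    is_virtual: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.mode not in MODES:
            raise FunvulError(f"unknown mode {self.mode!r}")
        if not (len(self.species_ids) == len(self.cells) == len(self.weights)):
            raise FunvulError("species/cells/weights length mismatch")
        if len(self.species_ids) < 1:
            raise FunvulError("community must contain at least one species")
        if np.any(self.weights <= 0):
            raise FunvulError("community weights must be positive")
        if self.mode == "occurrence" and not np.all(self.weights == 1.0):
            raise FunvulError("occurrence weights must be exactly 1")
        if (
            self.mode == "suitability"
            and not self.is_virtual
            and np.any(self.weights > 1 + 1e-12)
        ):
            raise FunvulError("suitability weights must lie in (0, 1]")

    @property
    def s(self) -> int:
        """Species richness S."""
        return len(self.species_ids)

    @property
    def t(self) -> float:
        """Total weight T."""
        return float(self.weights.sum())

    @property
    def occupied_cells(self) -> frozenset:
        return frozenset(self.cells)

    @property
    def n(self) -> int:
        """Number of occupied functional entities N."""
        return len(self.occupied_cells)


@dataclass(frozen=True)
class VirtualSpec:
    """One extreme virtual community: redundancy x weights x pairing.

    ``pairing == "none"`` if and only if ``weights == "homogeneous"``
    (equal weights make the distinctiveness-weight relationship void).
    In occurrence mode weights/pairing are not applicable and both are
    set to "none"/"homogeneous" equivalents via :func:`enumerate_virtual_specs`.
    """

    redundancy: str
    weights: str
    pairing: str

    def __post_init__(self) -> None:
        if self.redundancy not in REDUNDANCY_MODALITIES:
            raise FunvulError(f"bad redundancy modality {self.redundancy!r}")
        if self.weights not in WEIGHT_MODALITIES:
            raise FunvulError(f"bad weight modality {self.weights!r}")
        if self.pairing not in PAIRING_SIGNS:
            raise FunvulError(f"bad pairing sign {self.pairing!r}")
        if (self.pairing == "none") != (self.weights == "homogeneous"):
            raise FunvulError(
                "pairing is 'none' exactly when weights are homogeneous"
            )

    @property
    def label(self) -> str:
        red = {"observed": "obs", "homogeneous": "homog", "heterogeneous": "heter"}
        sign = {"positive": "pos", "negative": "neg", "none": "na"}
        return f"red-{red[self.redundancy]}_ab-{red[self.weights]}_{sign[self.pairing]}"


def enumerate_virtual_specs(mode: str) -> list[VirtualSpec]:
    """The fixed, order-stable set of virtual-community specs for a mode.

    Abundance and suitability modes cross 3 redundancy modalities with 5
    weight configurations (heterogeneous x {positive, negative}, homogeneous,
    observed x {positive, negative}) = 15.  Occurrence mode keeps only the
    two opposite redundancy distributions (weights are all ones).
    """
    if mode not in MODES:
        raise FunvulError(f"unknown mode {mode!r}")
    if mode == "occurrence":
        return [
            VirtualSpec("homogeneous", "homogeneous", "none"),
            VirtualSpec("heterogeneous", "homogeneous", "none"),
        ]
    weight_configs = [
        ("heterogeneous", "positive"),
        ("heterogeneous", "negative"),
        ("homogeneous", "none"),
        ("observed", "positive"),
        ("observed", "negative"),
    ]
    return [
        VirtualSpec(red, w, p)
        for red in REDUNDANCY_MODALITIES
        for (w, p) in weight_configs
    ]


# ---------------------------------------------------------------------------
# Redundancy rearrangement
# ---------------------------------------------------------------------------


def _occupied_row_major(obs: CommunityState) -> list[tuple[int, int]]:
    return sorted(obs.occupied_cells)


def rearrange_redundancy(
    obs: CommunityState, modality: str
) -> list[tuple[int, int]]:
    """Redistribute species over the N occupied entities.

    homogeneous: each occupied entity holds floor(S/N) species and the
    S mod N leftover species go one per entity starting from the first
    occupied entity in row-major order.  heterogeneous: one species per
    entity, with the S - N surplus all stacked in the last occupied entity
    (row-major).  observed: identity.  Species fill entity slots in stable
    species-id order; returns one cell per species, aligned with
    ``obs.species_ids``.
    """
    if modality == "observed":
        return list(obs.cells)
    entities = _occupied_row_major(obs)
    s, n = obs.s, obs.n
    assert s >= n, "S < N is impossible: every occupied entity has a species"
    if modality == "homogeneous":
        base, extra = divmod(s, n)
        sizes = [base + (1 if i < extra else 0) for i in range(n)]
    elif modality == "heterogeneous":
        sizes = [1] * (n - 1) + [1 + (s - n)]
    else:
        raise FunvulError(f"bad redundancy modality {modality!r}")
    slots: list[tuple[int, int]] = []
    for cell, size in zip(entities, sizes):
        slots.extend([cell] * size)
    order = sorted(range(s), key=lambda i: str(obs.species_ids[i]))
    cells_by_species = [None] * s
    for slot_cell, i in zip(slots, order):
        cells_by_species[i] = slot_cell
    return cells_by_species  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Weight rearrangement
# ---------------------------------------------------------------------------


def assign_weights(obs: CommunityState, modality: str) -> np.ndarray:
    """Return the virtual weight multiset (ascending) for a modality.

    homogeneous gives every species T/S.  heterogeneous gives S-1 species
    a unit u and dumps the remainder T-(S-1)u on one species; u is 1
    individual for integer-count data with T >= 2S, otherwise T/(2S).
    observed returns the observed multiset.  The sum is always exactly T.
    """
    s, t = obs.s, obs.t
    if t <= 0:
        raise FunvulError("total weight must be positive")
    if modality == "observed":
        w = np.sort(obs.weights)
    elif modality == "homogeneous":
        w = np.full(s, t / s)
    elif modality == "heterogeneous":
        integer_counts = np.allclose(obs.weights, np.round(obs.weights), atol=1e-9)
        u = 1.0 if (integer_counts and t >= 2 * s) else t / (2 * s)
        rest = t - (s - 1) * u
        if rest <= u:
            warnings.warn(
                "heterogeneous weights are not extreme: remainder <= unit",
                stacklevel=2,
            )
        w = np.sort(np.array([u] * (s - 1) + [rest]))
    else:
        raise FunvulError(f"bad weight modality {modality!r}")
    np.testing.assert_allclose(w.sum(), t, rtol=1e-9)
    return w


def pair_distinctiveness_weights(
    distinctiveness: pd.Series, weights: np.ndarray, sign: str
) -> pd.Series:
    """Attribute weights to species by their distinctiveness rank.

    positive: highest weights to the most distinct species; negative:
    highest weights to the least distinct.  Ties in D are broken by stable
    species-id order.  Returns a Series indexed like ``distinctiveness``.
    """
    s = len(distinctiveness)
    if len(weights) != s:
        raise FunvulError("distinctiveness / weight length mismatch")
    if sign == "none":
        return pd.Series(np.asarray(weights, dtype=float), index=distinctiveness.index)
    if sign not in ("positive", "negative"):
        raise FunvulError(f"bad pairing sign {sign!r}")
    order = sorted(
        range(s), key=lambda i: (distinctiveness.iloc[i], str(distinctiveness.index[i]))
    )
    w_sorted = np.sort(np.asarray(weights, dtype=float))
    if sign == "negative":
        w_sorted = w_sorted[::-1]
    out = np.empty(s)
    for w, i in zip(w_sorted, order):
        out[i] = w
    return pd.Series(out, index=distinctiveness.index)


# ---------------------------------------------------------------------------
# Distinctiveness of a (possibly rearranged) configuration
# ---------------------------------------------------------------------------


def configuration_distinctiveness(
    species_ids: list,
    positions: np.ndarray,
    grid: EntityGrid,
) -> pd.Series:
    """D_i from 2-D positions: Euclidean distances normalized by the grid diagonal.

    Used for virtual configurations, where species have been moved in the
    trait space and their original trait vectors no longer describe them:
    a relocated species sits at its cell's center.  Normalizing by the grid
    diagonal keeps D_i in [0, 1].
    """
    s = len(species_ids)
    if s < 2:
        raise FunvulError("distinctiveness needs at least 2 species")
    diag = grid.diagonal
    if diag <= 0:
        raise FunvulError("degenerate grid: zero diagonal")
    diff = positions[:, None, :] - positions[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1)) / diag
    d = np.clip(d, 0.0, 1.0)
    di = d.sum(axis=1) / (s - 1)
    return pd.Series(di, index=species_ids, name="distinctiveness")


# ---------------------------------------------------------------------------
# Full virtual set
# ---------------------------------------------------------------------------


def build_virtual_set(
    obs: CommunityState,
    coords: np.ndarray,
    grid: EntityGrid,
    trait_distinctiveness: pd.Series | None = None,
    recompute_distinctiveness: bool = True,
) -> dict[VirtualSpec, CommunityState]:
    """Construct every virtual community for the observed state.

    Parameters
    ----------
    obs : CommunityState
        The observed community.
    coords : ndarray (S, 2)
        Grid-axis coordinates of the observed species (aligned with
        ``obs.species_ids``).
    grid : EntityGrid
        The functional-entity grid of the observed community.
    trait_distinctiveness : Series, optional
        Trait-based D_i (Gower) for the observed species; required when
        ``recompute_distinctiveness`` is False.
    recompute_distinctiveness : bool
        If True (default), D_i for each configuration is recomputed from
        the species' grid positions (cell centers after relocation, actual
        coordinates otherwise).  If False, the trait-space D_i is reused
        for every configuration.

    Every returned state has the same S, T, and occupied-entity set as
    ``obs``.
    """
    if not recompute_distinctiveness and trait_distinctiveness is None:
        raise FunvulError(
            "trait_distinctiveness is required when recompute_distinctiveness=False"
        )
    specs = enumerate_virtual_specs(obs.mode)
    out: dict[VirtualSpec, CommunityState] = {}
    for spec in specs:
        cells = rearrange_redundancy(obs, spec.redundancy)
        if obs.mode == "occurrence":
            w = np.ones(obs.s)
        else:
            multiset = assign_weights(obs, spec.weights)
            if spec.pairing == "none":
                w = multiset.copy()
            else:
                if recompute_distinctiveness:
                    if spec.redundancy == "observed":
                        positions = coords
                    else:
                        positions = np.array([grid.cell_center(c) for c in cells])
                    di = configuration_distinctiveness(
                        obs.species_ids, positions, grid
                    )
                else:
                    di = trait_distinctiveness.loc[obs.species_ids]
                w = pair_distinctiveness_weights(di, multiset, spec.pairing).to_numpy()
        state = CommunityState(
            species_ids=list(obs.species_ids),
            cells=cells,
            weights=w,
            mode=obs.mode,
            is_virtual=True,
        )
        _assert_conserved(obs, state)
        out[spec] = state
    return out


def _assert_conserved(obs: CommunityState, virt: CommunityState) -> None:
    assert virt.s == obs.s, "virtual community changed S"
    assert abs(virt.t - obs.t) <= 1e-9 * max(obs.t, 1.0), "virtual community changed T"
    assert virt.occupied_cells == obs.occupied_cells, (
        "virtual community changed the occupied-entity set"
    )


def dump_virtual_set(
    virtual: dict[VirtualSpec, CommunityState], path
) -> pd.DataFrame:
    """Audit dump: one row per (spec, species) with entity cell and weight."""
    rows = []
    for spec, state in virtual.items():
        for sp, cell, w in zip(state.species_ids, state.cells, state.weights):
            rows.append(
                {
                    "spec": spec.label,
                    "species": sp,
                    "cell_row": cell[0],
                    "cell_col": cell[1],
                    "weight": w,
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
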