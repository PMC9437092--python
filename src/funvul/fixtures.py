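"""Seeded synthetic communities for testing and demonstration.

The generator controls the two structural axes that drive functional
vulnerability: how clustered species are in trait space (cluster count k
and within-cluster spread sigma set the functional redundancy that the
entity grid will see) and how even the abundances are (a geometric series
with ratio p; p = 1 gives a perfectly even community, small p a strongly
dominated one).  Abundances are integer counts summing exactly to a fixed
total, so the count-data rules of the virtual-community construction are
exercised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trait_space import FunvulError, TraitTable

#: individuals per species on average in generated abundance data
INDIVIDUALS_PER_SPECIES = 20


@dataclass
class FixtureSpec:
    s: int
    k: int = 3  # latent trait-space clusters
    sigma: float = 0.15  # within-cluster spread (trait-space units)
    n_continuous: int = 2
    n_nominal: int = 1
    evenness: float = 1.0  # geometric ratio p in (0, 1]; 1 = even
    mode: str = "abundance"
    seed: int = 0
    total: int | None = None  # total abundance T; default 20 * S

    def __post_init__(self) -> None:
        if self.s < 2:
            raise FunvulError("fixture needs at least 2 species")
        if self.k > self.s:
            raise FunvulError("more clusters than species is infeasible")
        if self.sigma <= 0:
            raise FunvulError("sigma must be positive")
        if not (0 < self.evenness <= 1):
            raise FunvulError("evenness p must be in (0, 1]")
        if self.total is None:
            self.total = INDIVIDUALS_PER_SPECIES * self.s


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing exactly to ``total``, proportional to shares."""
    raw = shares / shares.sum() * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    # every species must exist: steal from the largest for any zero
    while (counts == 0).any():
        counts[np.argmax(counts)] -= 1
        counts[np.argmin(counts)] += 1
    return counts


def _species_ids(s: int) -> list[str]:
    width = len(str(s))
    return [f"sp{i + 1:0{width}d}" for i in range(s)]


def generate_community(spec: FixtureSpec) -> tuple[TraitTable, pd.Series]:
    """One synthetic community: a mixed-type trait table plus weights.

    Latent 2-D cluster centers are uniform on the unit square; species
    scatter around their center with spread sigma.  Continuous traits are
    the latent coordinates plus proportionally small noise; nominal traits
    are the cluster label with 10% flip noise.  Weights follow the mode:
    integer counts from a geometric series (abundance), all ones
    (occurrence), or the geometric series rescaled to max 1 (suitability).
    """
    rng = np.random.default_rng(spec.seed)
    ids = _species_ids(spec.s)
    centers = rng.uniform(0.0, 1.0, size=(spec.k, 2))
    labels = rng.permutation(np.arange(spec.s) % spec.k)
    positions = centers[labels] + rng.normal(0.0, spec.sigma, size=(spec.s, 2))

    cols: dict[str, object] = {}
    kinds: dict[str, str] = {}
    noise = 0.3 * spec.sigma
    for j in range(spec.n_continuous):
        name = f"cont{j + 1}"
        cols[name] = positions[:, j % 2] + rng.normal(0.0, noise, size=spec.s)
        kinds[name] = "continuous"
    for j in range(spec.n_nominal):
        name = f"nom{j + 1}"
        flips = rng.random(spec.s) < 0.1
        lab = labels.copy()
        lab[flips] = rng.integers(0, spec.k, size=int(flips.sum()))
        cols[name] = [f"c{v}" for v in lab]
        kinds[name] = "nominal"
    traits = TraitTable(pd.DataFrame(cols, index=ids), kinds)

    q = spec.evenness ** np.arange(spec.s, dtype=float)
    if spec.mode == "abundance":
        w = _largest_remainder(q, spec.total).astype(float)
    elif spec.mode == "occurrence":
        w = np.ones(spec.s)
    elif spec.mode == "suitability":
        w = q / q.max()
    else:
        raise FunvulError(f"unknown mode {spec.mode!r}")
    return traits, pd.Series(w, index=ids, name="weight")


def make_extreme_pair(
    s: int, seed: int
) -> tuple[tuple[TraitTable, pd.Series], tuple[TraitTable, pd.Series]]:
    """Two communities identical except for trait-space clustering.

    The "spread" member puts every species in its own tight cluster (high
    redundancy of entities, low redundancy within them); the "concentrated"
    member stacks all species in one spot plus a single outlier that fixes
    the grid extent.  Abundance vectors are identical, so any vulnerability
    difference comes from the redundancy structure alone.
    Returns ((spread_traits, weights), (concentrated_traits, weights)).
    """
    if s < 4:
        raise FunvulError("extreme pair needs at least 4 species")
    rng = np.random.default_rng(seed)
    ids = _species_ids(s)
    jitter = 1e-6

    spread_pos = rng.uniform(0.0, 1.0, size=(s, 2))
    conc_pos = np.tile(rng.uniform(0.3, 0.7, size=(1, 2)), (s, 1))
    conc_pos += rng.normal(0.0, jitter, size=(s, 2))
    conc_pos[-1] = conc_pos[-1] + 1.0  # the outlier

    def as_traits(pos: np.ndarray) -> TraitTable:
        df = pd.DataFrame(
            {
                "cont1": pos[:, 0] + rng.normal(0.0, jitter, size=s),
                "cont2": pos[:, 1] + rng.normal(0.0, jitter, size=s),
            },
            index=ids,
        )
        return TraitTable(df, {"cont1": "continuous", "cont2": "continuous"})

    q = 0.7 ** np.arange(s, dtype=float)
    w = _largest_remainder(q, INDIVIDUALS_PER_SPECIES * s).astype(float)
    weights = pd.Series(w, index=ids, name="weight")
    return (as_traits(spread_pos), weights), (as_traits(conc_pos), weights.copy())


def write_fixture(
    traits: TraitTable,
    weights: pd.Series | pd.DataFrame,
    out_dir,
    community_id: str = "site1",
) -> dict[str, Path]:
    """Write a fixture in the delimited formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(weights, pd.Series):
        matrix = weights.rename(community_id).to_frame().T
    else:
        matrix = weights
    matrix.index.name = "community"
    paths = {
        "community": out / "community.csv",
        "traits": out / "traits.csv",
        "trait_config": out / "traits.yaml",
    }
    matrix.to_csv(paths["community"])
    tdf = traits.values.copy()
    tdf.index.name = "species"
    tdf.to_csv(paths["traits"])
    decl = {}
    for col, kind in traits.kinds.items():
        if kind == "ordinal" and col in traits.ordinal_levels:
            decl[col] = "ordinal(" + "<".join(map(str, traits.ordinal_levels[col])) + ")"
        else:
            decl[col] = kind
    with open(paths["trait_config"], "w") as fh:
        yaml.safe_dump(decl, fh, default_flow_style=False, sort_keys=True)
    return paths
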