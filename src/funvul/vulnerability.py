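"""Functional-vulnerability index and end-to-end assessment.

The observed community and each of its virtual reference communities are
disturbed to collapse; each rarefaction curve is summarized by its
trapezoid area (AUC) on the normalized axes.  The functional vulnerability
FV locates the observed AUC inside the envelope spanned by the virtual
communities:

    FV = 100 * (AUC_max - AUC_obs) / (AUC_max - AUC_min)

so FV = 0% for a community that loses its functional entities as slowly as
the slowest (least vulnerable) reference, and FV = 100% for one matching
the fastest-collapsing (most vulnerable) reference.  The widely reprinted
form 100*(AUC_obs - AUC_min)/(AUC_max - AUC_min) assigns 100 to the least
vulnerable community instead; it is available through
``printed_orientation=True`` for auditing.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .communities import (
    CommunityState,
    VirtualSpec,
    build_virtual_set,
)
from .disturbance import DisturbanceConfig, RarefactionCurve, replicate_series
from .io import RunConfig
from .trait_space import (
    DissimilarityMatrix,
    EntityGrid,
    FunvulError,
    TraitSpace,
    TraitTable,
    assign_entities,
    build_entity_grid,
    compute_distinctiveness,
    compute_gower,
    compute_pcoa,
)

logger = logging.getLogger("funvul")


def _derive_seed(*parts) -> int:
    """Deterministic 31-bit sub-seed from arbitrary labelled parts."""
    key = ":".join(str(p) for p in parts)
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# AUC and the index
# ---------------------------------------------------------------------------


def compute_auc(curve: RarefactionCurve) -> float:
    """Trapezoid area under the rarefaction curve on x in [0, 1]."""
    if len(curve) < 2:
        raise FunvulError("rarefaction curve needs at least 2 points")
    return float(np.trapezoid(curve.y, curve.x))


def functional_vulnerability(
    auc_obs: float,
    auc_by_spec: dict,
    printed_orientation: bool = False,
) -> tuple[float, float, float, object, object]:
    """Position the observed AUC in the virtual envelope, on a 0-100 scale.

    Returns (FV, AUC_min, AUC_max, argmin spec, argmax spec).  The value
    is clamped to [0, 100] when stochastic noise pushes AUC_obs outside
    the envelope (logged).
    """
    if len(auc_by_spec) < 2:
        raise FunvulError("need at least 2 virtual AUCs")
    argmin_spec = min(auc_by_spec, key=lambda k: auc_by_spec[k])
    argmax_spec = max(auc_by_spec, key=lambda k: auc_by_spec[k])
    auc_min, auc_max = auc_by_spec[argmin_spec], auc_by_spec[argmax_spec]
    span = auc_max - auc_min
    if span < 1e-9:
        raise FunvulError("virtual envelope degenerate: AUC_max - AUC_min < 1e-9")
    if printed_orientation:
        fv = 100.0 * (auc_obs - auc_min) / span
    else:
        fv = 100.0 * (auc_max - auc_obs) / span
    if fv < 0 or fv > 100:
        logger.info(
            "observed AUC %.6f outside virtual envelope [%.6f, %.6f]; clamped",
            auc_obs,
            auc_min,
            auc_max,
        )
        fv = min(max(fv, 0.0), 100.0)
    return fv, auc_min, auc_max, argmin_spec, argmax_spec


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------


@dataclass
class VulnerabilityResult:
    community_id: object
    fv: float
    auc_obs: float
    auc_min: float
    auc_max: float
    auc_by_spec: dict[VirtualSpec, float]
    argmin_spec: VirtualSpec
    argmax_spec: VirtualSpec
    fv_rel_sd: float  # relative SD (%) of per-replicate FV values
    s: int
    n: int
    t: float
    fv_replicates: np.ndarray = field(repr=False, default=None)

    def to_row(self) -> dict:
        return {
            "community": self.community_id,
            "fv": self.fv,
            "auc_obs": self.auc_obs,
            "auc_min": self.auc_min,
            "auc_max": self.auc_max,
            "argmin_spec": self.argmin_spec.label,
            "argmax_spec": self.argmax_spec.label,
            "s": self.s,
            "n": self.n,
            "t": self.t,
            "fv_rel_sd": self.fv_rel_sd,
        }


# ---------------------------------------------------------------------------
# Pool context: trait space shared by all communities of a run
# ---------------------------------------------------------------------------


@dataclass
class PoolContext:
    """Gower + PCoA of the full species pool, reused across communities."""

    traits: TraitTable
    dissimilarity: DissimilarityMatrix
    space: TraitSpace
    coords: pd.DataFrame  # grid-axis coordinates (2 cols) indexed by species
    distinctiveness: pd.Series  # trait-based D_i over the pool


def build_pool_context(traits: TraitTable) -> PoolContext:
    d = compute_gower(traits)
    space = compute_pcoa(d)
    coords = pd.DataFrame(
        _canonical_signs(space.grid_coordinates(), traits.species_ids),
        index=traits.species_ids,
        columns=["axis1", "axis2"],
    )
    di = compute_distinctiveness(d)
    return PoolContext(traits, d, space, coords, di)


def _canonical_signs(coords: np.ndarray, species_ids: list) -> np.ndarray:
    """Flip PCoA axis signs to an ordering-independent convention.

    Eigenvector signs are arbitrary; each axis is oriented so that the
    species with the largest |coordinate| (ties broken by species id)
    has a positive coordinate.  This makes downstream grids invariant to
    input row permutations.
    """
    out = coords.copy()
    ids = [str(s) for s in species_ids]
    for ax in range(out.shape[1]):
        col = out[:, ax]
        amax = np.abs(col).max()
        if amax == 0:
            continue
        cand = [i for i in range(len(col)) if abs(abs(col[i]) - amax) <= 1e-12]
        pick = min(cand, key=lambda i: ids[i])
        if col[pick] < 0:
            out[:, ax] = -col
    return out


# ---------------------------------------------------------------------------
# Assessment of one community
# ---------------------------------------------------------------------------


def _disturbance_config(cfg: RunConfig, seed: int) -> DisturbanceConfig:
    return DisturbanceConfig(
        mode=cfg.mode,
        decrement_frac=cfg.decrement,
        suitability_decrement=cfg.suitability_decrement,
        species_per_step=cfg.species_per_step,
        replicates=cfg.replicates,
        seed=seed,
        allocation=cfg.allocation,
    )


def assess_state(
    obs: CommunityState,
    coords: np.ndarray,
    grid: EntityGrid,
    cfg: RunConfig,
    trait_distinctiveness: pd.Series | None = None,
    community_id: object = "community",
    seed: int | None = None,
) -> VulnerabilityResult:
    """Score a prepared community state against its virtual envelope.

    ``coords`` are the grid-axis coordinates of the state's species
    (aligned with ``obs.species_ids``); ``seed`` defaults to a value
    derived from the run seed and the community id.
    """
    if seed is None:
        seed = _derive_seed(cfg.seed, community_id)
    virtual = build_virtual_set(
        obs,
        coords,
        grid,
        trait_distinctiveness=trait_distinctiveness,
        recompute_distinctiveness=cfg.recompute_distinctiveness,
    )
    dcfg = _disturbance_config(cfg, seed)
    obs_curves = replicate_series(obs, dcfg)
    obs_aucs = np.array([compute_auc(c) for c in obs_curves])
    spec_aucs: dict[VirtualSpec, np.ndarray] = {}
    for spec, state in virtual.items():
        curves = replicate_series(state, dcfg)
        spec_aucs[spec] = np.array([compute_auc(c) for c in curves])

    mean_by_spec = {spec: float(a.mean()) for spec, a in spec_aucs.items()}
    auc_obs = float(obs_aucs.mean())
    fv, auc_min, auc_max, argmin_spec, argmax_spec = functional_vulnerability(
        auc_obs, mean_by_spec, printed_orientation=cfg.printed_orientation
    )

    fv_reps = _per_replicate_fv(obs_aucs, spec_aucs, cfg.printed_orientation)
    if fv_reps is not None and len(fv_reps) > 1 and np.mean(fv_reps) > 0:
        fv_rel_sd = 100.0 * float(np.std(fv_reps, ddof=1) / np.mean(fv_reps))
    else:
        fv_rel_sd = 0.0
    return VulnerabilityResult(
        community_id=community_id,
        fv=fv,
        auc_obs=auc_obs,
        auc_min=auc_min,
        auc_max=auc_max,
        auc_by_spec=mean_by_spec,
        argmin_spec=argmin_spec,
        argmax_spec=argmax_spec,
        fv_rel_sd=fv_rel_sd,
        s=obs.s,
        n=obs.n,
        t=obs.t,
        fv_replicates=fv_reps,
    )


def _per_replicate_fv(
    obs_aucs: np.ndarray,
    spec_aucs: dict[VirtualSpec, np.ndarray],
    printed_orientation: bool,
) -> np.ndarray | None:
    """FV recomputed per paired replicate, for dispersion reporting."""
    lengths = {len(a) for a in spec_aucs.values()} | {len(obs_aucs)}
    if len(lengths) != 1:
        return None  # deterministic virtuals vs stochastic obs: not paired
    n_rep = lengths.pop()
    out = np.empty(n_rep)
    mat = np.stack([spec_aucs[s] for s in spec_aucs])  # (n_spec, n_rep)
    for r in range(n_rep):
        lo, hi = mat[:, r].min(), mat[:, r].max()
        span = hi - lo
        if span < 1e-9:
            out[r] = np.nan
            continue
        if printed_orientation:
            fv = 100.0 * (obs_aucs[r] - lo) / span
        else:
            fv = 100.0 * (hi - obs_aucs[r]) / span
        out[r] = min(max(fv, 0.0), 100.0)
    return out


def prepare_state(
    weights: pd.Series,
    ctx: PoolContext,
    cfg: RunConfig,
) -> tuple[CommunityState, np.ndarray, EntityGrid]:
    """Turn a per-species weight vector into a gridded community state.

    Species are canonicalized to stable id order, zero weights dropped,
    and the entity grid is bounded by this community's extreme species.
    """
    w = weights[weights > 0]
    unknown = [s for s in w.index if s not in ctx.coords.index]
    if unknown:
        raise FunvulError(f"species missing from trait table: {unknown}")
    species = sorted(w.index, key=str)
    coords = ctx.coords.loc[species].to_numpy()
    sub_space = TraitSpace(
        species_ids=species,
        coordinates=coords,
        eigenvalues=ctx.space.eigenvalues[: coords.shape[1]],
        n_axes_used=ctx.space.n_axes_used,
    )
    grid = build_entity_grid(sub_space, cfg.grid_resolution)
    assignment = assign_entities(sub_space, grid)
    state = CommunityState(
        species_ids=species,
        cells=assignment.cells,
        weights=w.loc[species].to_numpy(dtype=float),
        mode=cfg.mode,
    )
    return state, coords, grid


def assess_community(
    weights: pd.Series,
    traits: TraitTable | PoolContext,
    cfg: RunConfig,
    community_id: object = "community",
) -> VulnerabilityResult:
    """Full pipeline for one community: trait space -> virtual set -> FV."""
    ctx = traits if isinstance(traits, PoolContext) else build_pool_context(traits)
    state, coords, grid = prepare_state(weights, ctx, cfg)
    di = compute_distinctiveness(
        DissimilarityMatrix(
            state.species_ids,
            ctx.dissimilarity.to_frame()
            .loc[state.species_ids, state.species_ids]
            .to_numpy(),
        )
    ) if state.s >= 2 else None
    return assess_state(
        state,
        coords,
        grid,
        cfg,
        trait_distinctiveness=di,
        community_id=community_id,
    )


def assess_dataset(
    matrix: pd.DataFrame,
    traits: TraitTable,
    cfg: RunConfig,
) -> tuple[pd.DataFrame, list[VulnerabilityResult]]:
    """Assess every community (row) of a community x species matrix.

    Per-community failures are reported (logged, row marked) without
    aborting the run.
    """
    ctx = build_pool_context(traits)
    rows, results = [], []
    for cid, weights in matrix.iterrows():
        try:
            res = assess_community(weights, ctx, cfg, community_id=cid)
        except FunvulError as exc:
            logger.error("community %r failed: %s", cid, exc)
            rows.append({"community": cid, "error": str(exc)})
            continue
        results.append(res)
        rows.append(res.to_row())
    return pd.DataFrame(rows), results


# ---------------------------------------------------------------------------
# Sensitivity sweeps
# ---------------------------------------------------------------------------

SENSITIVITY_AXES = ("replicates", "grid_resolution", "trait_subsets", "na_deletion")

#: independent batches used to estimate between-batch FV dispersion
N_BATCHES = 8
#: random trait combinations drawn per subset size
N_TRAIT_COMBOS = 20


def _batch_fv(
    weights: pd.Series, ctx: PoolContext, cfg: RunConfig, n_batches: int
) -> np.ndarray:
    """FV from independent replicate batches (distinct derived seeds)."""
    state, coords, grid = prepare_state(weights, ctx, cfg)
    di = ctx.distinctiveness.loc[state.species_ids]
    out = np.empty(n_batches)
    for b in range(n_batches):
        res = assess_state(
            state,
            coords,
            grid,
            cfg,
            trait_distinctiveness=di,
            seed=_derive_seed(cfg.seed, "batch", b),
        )
        out[b] = res.fv
    return out


def sensitivity_sweep(
    weights: pd.Series,
    traits: TraitTable,
    cfg: RunConfig,
    axes: dict[str, list],
) -> pd.DataFrame:
    """Re-run the assessment along requested sensitivity axes.

    ``axes`` maps axis name to the values to try: ``replicates`` and
    ``grid_resolution`` take numeric settings; ``trait_subsets`` takes
    subset sizes (20 seeded random trait combinations each);
    ``na_deletion`` takes booleans (True drops species with any missing
    trait).  One row per setting with mean FV and the relative SD (%) of
    FV over batches/combinations.
    """
    bad = set(axes) - set(SENSITIVITY_AXES)
    if bad:
        raise FunvulError(f"unknown sensitivity axes: {sorted(bad)}")
    ctx = build_pool_context(traits)
    records = []
    for axis, settings in axes.items():
        for setting in settings:
            if axis == "replicates":
                sub = replace_cfg(cfg, replicates=int(setting))
                fvs = _batch_fv(weights, ctx, sub, N_BATCHES)
            elif axis == "grid_resolution":
                sub = replace_cfg(cfg, grid_resolution=int(setting))
                fvs = _batch_fv(weights, ctx, sub, N_BATCHES)
            elif axis == "na_deletion":
                if setting:
                    keep = ctx.traits.values.dropna().index
                    sub_traits = ctx.traits.subset(list(keep))
                    sub_w = weights[weights.index.isin(keep)]
                    res = assess_community(sub_w, sub_traits, cfg)
                else:
                    res = assess_community(weights, ctx, cfg)
                fvs = np.array([res.fv])
            else:  # trait_subsets
                size = int(setting)
                all_traits = list(ctx.traits.values.columns)
                if size < 3:
                    logger.warning(
                        "trait subset size %d < 3: trait space may be unstable", size
                    )
                combos = list(itertools.combinations(all_traits, size))
                rng = np.random.default_rng(_derive_seed(cfg.seed, "traits", size))
                if len(combos) > N_TRAIT_COMBOS:
                    idx = rng.choice(len(combos), size=N_TRAIT_COMBOS, replace=False)
                    combos = [combos[i] for i in sorted(idx)]
                fvs = []
                for combo in combos:
                    sub_traits = TraitTable(
                        ctx.traits.values[list(combo)],
                        {c: ctx.traits.kinds[c] for c in combo},
                        {
                            c: v
                            for c, v in ctx.traits.ordinal_levels.items()
                            if c in combo
                        },
                    )
                    fvs.append(assess_community(weights, sub_traits, cfg).fv)
                fvs = np.array(fvs)
            mean_fv = float(np.mean(fvs))
            rel_sd = (
                100.0 * float(np.std(fvs, ddof=1) / mean_fv)
                if len(fvs) > 1 and mean_fv > 0
                else 0.0
            )
            records.append(
                {"axis": axis, "setting": setting, "fv": mean_fv, "rel_sd": rel_sd}
            )
    return pd.DataFrame(records)


def replace_cfg(cfg: RunConfig, **kwargs) -> RunConfig:
    from dataclasses import replace

    return replace(cfg, **kwargs)
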