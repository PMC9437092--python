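"""Readers, writers, run configuration and logging.

All tabular inputs and outputs are delimited text (comma or tab, sniffed).
The community matrix is communities x species (rows = sites or years); the
trait table is species x traits with kinds declared in a flat key-value
config file.
"""

from __future__ import annotations

import csv
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trait_space import TRAIT_KINDS, FunvulError, TraitTable

logger = logging.getLogger("funvul")


def setup_logging(log_file: str | None = None, level: int = logging.INFO) -> None:
    """Log to stderr, optionally teeing to a file."""
    root = logging.getLogger("funvul")
    root.setLevel(level)
    root.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    root.addHandler(h)
    if log_file:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        root.addHandler(fh)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a run needs besides the data files.

    ``min_richness`` defaults to 10 for occurrence and suitability runs
    (spatial screening of species-poor cells) and to no filter for
    abundance runs.
    """

    mode: str = "abundance"
    grid_resolution: int = 20
    decrement: float = 0.05
    suitability_decrement: float = 0.05
    species_per_step: int = 1
    replicates: int = 99
    seed: int = 0
    allocation: str = "species"  # abundance budget rule: species | individual
    min_richness: int | None = None
    log10_transform: bool = False
    trait_kinds: dict[str, str] = field(default_factory=dict)
    ordinal_levels: dict[str, list] = field(default_factory=dict)
    recompute_distinctiveness: bool = True
    printed_orientation: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("abundance", "occurrence", "suitability"):
            raise FunvulError(f"unknown mode {self.mode!r}")
        if self.grid_resolution < 2:
            raise FunvulError("grid resolution must be >= 2")
        if self.min_richness is None:
            self.min_richness = 10 if self.mode in ("occurrence", "suitability") else 0

    @property
    def effective_min_richness(self) -> int:
        return self.min_richness or 0


def read_trait_config(path) -> tuple[dict[str, str], dict[str, list]]:
    """Parse the flat key-value trait-kind file.

    Each key is a trait name; the value is a kind (``continuous``,
    ``ordinal``, ``nominal``, ``binary``).  Ordinal traits coded as labels
    declare their order as ``ordinal(low<mid<high)``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FunvulError(f"trait config {path} must be a flat key-value mapping")
    kinds: dict[str, str] = {}
    levels: dict[str, list] = {}
    for trait, val in raw.items():
        val = str(val).strip()
        if val.startswith("ordinal(") and val.endswith(")"):
            kinds[trait] = "ordinal"
            levels[trait] = [tok.strip() for tok in val[8:-1].split("<")]
        elif val in TRAIT_KINDS:
            kinds[trait] = val
        else:
            raise FunvulError(
                f"trait config: unknown kind {val!r} for trait {trait!r}"
            )
    return kinds, levels


# ---------------------------------------------------------------------------
# Delimited-text readers
# ---------------------------------------------------------------------------


def _read_delimited(path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table, first column as index."""
    with open(path) as fh:
        sample = fh.read(4096)
    try:
        sep = csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        sep = ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df


def read_community_matrix(
    path,
    cfg: RunConfig,
    trait_ids: list | None = None,
) -> pd.DataFrame:
    """Read and validate the community x species weight matrix.

    Rows are communities (sites or years), columns species.  If no column
    matches a known trait id but the rows do, the matrix is transposed
    (logged).  Zero-weight species are simply absent from that community;
    communities below the richness filter are dropped with a logged
    reason.  The optional log10(x+1) transform applies to abundance data.
    """
    df = _read_delimited(path)
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FunvulError(f"duplicate species columns: {dups}")
    if trait_ids is not None:
        cols = set(map(str, df.columns))
        rows = set(map(str, df.index))
        tids = set(map(str, trait_ids))
        if not (cols & tids) and (rows & tids):
            logger.info("community matrix looks transposed (species on rows); transposing")
            df = df.T
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for i, cid in enumerate(df.index):
            for j, sp in enumerate(df.columns):
                try:
                    float(df.iloc[i, j])
                except (TypeError, ValueError):
                    raise FunvulError(
                        f"non-numeric cell at community {cid!r}, species {sp!r}: "
                        f"{df.iloc[i, j]!r}"
                    ) from None
        raise
    bad = np.argwhere(values < 0)
    if bad.size:
        i, j = bad[0]
        raise FunvulError(
            f"negative weight at community {df.index[i]!r}, species {df.columns[j]!r}"
        )
    if cfg.mode == "occurrence":
        ok = np.isin(values, (0.0, 1.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise FunvulError(
                f"occurrence value not in {{0,1}} at community {df.index[i]!r}, "
                f"species {df.columns[j]!r}: {values[i, j]}"
            )
    if cfg.mode == "suitability" and values.max() > 1:
        i, j = np.argwhere(values > 1)[0]
        raise FunvulError(
            f"suitability value > 1 at community {df.index[i]!r}, "
            f"species {df.columns[j]!r}: {values[i, j]}"
        )
    df = pd.DataFrame(values, index=df.index, columns=df.columns)
    if cfg.log10_transform:
        if cfg.mode != "abundance":
            raise FunvulError("log10(x+1) transform applies to abundance data only")
        df = np.log10(df + 1.0)
    richness = (df > 0).sum(axis=1)
    min_s = cfg.effective_min_richness
    if min_s:
        drop = richness[richness < min_s].index.tolist()
        for cid in drop:
            logger.info(
                "community %r skipped: richness %d < minimum %d",
                cid,
                int(richness[cid]),
                min_s,
            )
        df = df.drop(index=drop)
    if df.empty:
        raise FunvulError("no community passed validation/filtering")
    return df


def read_trait_table(
    path,
    kinds: dict[str, str],
    ordinal_levels: dict[str, list] | None = None,
    community_species: list | None = None,
) -> TraitTable:
    """Read the species x trait table and cross-check against the communities.

    "NA"/empty tokens become missing values.  Species present in the
    communities but absent from the trait table are a fatal error (listed);
    trait-table species absent from every community only warn.
    """
    df = _read_delimited(path)
    missing_decl = [c for c in df.columns if c not in kinds]
    if missing_decl:
        raise FunvulError(f"no trait kind declared for column(s): {missing_decl}")
    for col, kind in kinds.items():
        if col not in df.columns:
            continue
        if kind == "continuous":
            try:
                df[col] = pd.to_numeric(df[col])
            except (TypeError, ValueError) as exc:
                raise FunvulError(
                    f"trait {col!r} declared continuous but not numeric: {exc}"
                ) from None
        if kind == "ordinal" and ordinal_levels and col in ordinal_levels:
            lv = ordinal_levels[col]
            bad = df[col].dropna()[~df[col].dropna().isin(lv)]
            if not bad.empty:
                raise FunvulError(
                    f"trait {col!r}: value(s) {sorted(set(bad))} outside declared "
                    f"ordinal levels {lv}"
                )
    if community_species is not None:
        absent = [s for s in community_species if s not in df.index]
        if absent:
            raise FunvulError(
                f"species in communities but missing from trait table: {absent}"
            )
        extra = [s for s in df.index if s not in set(community_species)]
        if extra:
            logger.warning(
                "%d trait-table species absent from every community", len(extra)
            )
    return TraitTable(df, {c: kinds[c] for c in df.columns}, ordinal_levels or {})


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_results(df: pd.DataFrame, path) -> None:
    """Write the per-community results table; floats keep full precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_matrix(df: pd.DataFrame, path) -> None:
    """Audit export for dissimilarity/coordinate matrices."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path)
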