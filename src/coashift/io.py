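"""Readers and writers for the pipeline's tabular and tree formats.

Stratum-level annual abundance indices, banding-event records and species
trait tables travel as plain CSV (comma separator, UTF-8, ``.`` decimal,
mandatory header); phylogenies travel as Newick. Every reader validates
its schema strictly and every reader/writer pair is a lossless round trip
at 12 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("coashift.io")

#: 95% interval width in standard-normal units: hi95 - lo95 = 3.92 sd
NORMAL_95_WIDTH = 3.92

STRATUM_COLUMNS = [
    "species",
    "season",
    "stratum_id",
    "centroid_lon",
    "centroid_lat",
    "year",
    "index_median",
    "index_lo95",
    "index_hi95",
]

BANDING_COLUMNS = ["species", "julian_day", "latitude", "age_class"]

AGE_CLASSES = ("HY", "AHY")
SEASONS = ("breeding", "nonbreeding")


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """A row violates a declared invariant."""


class MissingTipError(KeyError):
    """A requested species is absent from the phylogeny."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def sd_from_percentiles(lo95, hi95):
    """Posterior SD approximated from the 95th-percentile bounds.

    Bayesian posteriors of the survey index models are approximately
    normal around the median, so ``sd = (hi95 - lo95) / 3.92``.
    Accepts scalars or arrays; raises on ``hi95 < lo95``.
    """
    lo = np.asarray(lo95, dtype=float)
    hi = np.asarray(hi95, dtype=float)
    if np.any(hi < lo):
        raise ValidationError("hi95 < lo95")
    out = (hi - lo) / NORMAL_95_WIDTH
    return float(out) if out.ndim == 0 else out


def read_stratum_indices(path: str | Path) -> pd.DataFrame:
    """Read and validate a stratum-level annual index table.

    Returns a DataFrame with the schema columns plus a derived
    ``index_sd`` column. Duplicate (species, season, stratum_id, year)
    rows, interval-order violations, out-of-range coordinates and
    unknown seasons all raise :class:`ValidationError` naming the first
    offending row.
    """
    df = pd.read_csv(path)
    _require_columns(df, STRATUM_COLUMNS, "stratum index table")
    df = df[STRATUM_COLUMNS].copy()
    df["year"] = df["year"].astype(int)

    bad = df.index[~df["season"].isin(SEASONS)]
    if len(bad):
        raise ValidationError(f"unknown season at row {bad[0]}: {df.loc[bad[0], 'season']!r}")
    bad = df.index[df["index_lo95"] > df["index_hi95"]]
    if len(bad):
        raise ValidationError(f"index_lo95 > index_hi95 at row {bad[0]}")
    bad = df.index[(df["index_lo95"] > df["index_median"]) | (df["index_median"] > df["index_hi95"])]
    if len(bad):
        raise ValidationError(f"index_median outside [lo95, hi95] at row {bad[0]}")
    bad = df.index[(df["index_median"] < 0) | (df["index_lo95"] < 0)]
    if len(bad):
        raise ValidationError(f"negative abundance index at row {bad[0]}")
    bad = df.index[(df["centroid_lat"] < -90) | (df["centroid_lat"] > 90)]
    if len(bad):
        raise ValidationError(f"centroid_lat outside [-90, 90] at row {bad[0]}")
    bad = df.index[(df["centroid_lon"] < -180) | (df["centroid_lon"] > 180)]
    if len(bad):
        raise ValidationError(f"centroid_lon outside [-180, 180] at row {bad[0]}")

    key = ["species", "season", "stratum_id", "year"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValidationError(
            f"duplicate (species, season, stratum, year) at row {df.index[dup][0]}"
        )

    df["index_sd"] = sd_from_percentiles(df["index_lo95"].to_numpy(), df["index_hi95"].to_numpy())
    return df


def write_stratum_indices(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, STRATUM_COLUMNS, "stratum index table")
    df[STRATUM_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_banding(path: str | Path) -> pd.DataFrame:
    """Read banding-event records, dropping invalid rows with a logged tally.

    Rows with a Julian day outside 1-366, an age code other than HY/AHY,
    or a latitude outside [-90, 90] are dropped (opportunistic banding
    data are noisy; this mirrors routine curation). An empty table after
    filtering raises ``ValueError``.
    """
    df = pd.read_csv(path)
    _require_columns(df, BANDING_COLUMNS, "banding table")
    df = df[BANDING_COLUMNS].copy()
    n0 = len(df)
    keep = (
        df["julian_day"].between(1, 366)
        & df["age_class"].isin(AGE_CLASSES)
        & df["latitude"].between(-90, 90)
    )
    df = df.loc[keep].reset_index(drop=True)
    dropped = n0 - len(df)
    if dropped:
        logger.warning("read_banding: dropped %d invalid row(s) of %d", dropped, n0)
    if df.empty:
        raise ValueError(f"no valid banding records in {path}")
    df["julian_day"] = df["julian_day"].astype(int)
    return df


def write_banding(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, BANDING_COLUMNS, "banding table")
    df[BANDING_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a species trait table; only `species` is mandatory here.

    Column-level validation happens at assembly time, where the model
    variant determines which predictors are required.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["species"], "trait table")
    if df["species"].duplicated().any():
        raise ValidationError("duplicate species in trait table")
    return df


def write_traits(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Trees


def read_tree(path: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValidationError("negative branch length in tree")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tree_tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def prune_tree(tree: dendropy.Tree, species: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on the requested tips (patristic distances preserved).

    Raises :class:`MissingTipError` listing any requested species absent
    from the tree.
    """
    wanted = list(dict.fromkeys(species))
    have = set(tree_tip_labels(tree))
    missing = [s for s in wanted if s not in have]
    if missing:
        raise MissingTipError(f"species not in tree: {missing}")
    pruned = tree.extract_tree_with_taxa_labels(labels=wanted)
    # extract_tree preserves path lengths by summing suppressed unifurcations
    return pruned
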