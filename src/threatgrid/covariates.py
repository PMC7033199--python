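"""Derived covariates and richness layers from raw gridded inputs.

Implements the data-preparation rules of the analysis: range-polygon
rasterization (presence on any intersection with a cell), richness
counting under the IUCN status filter, insularity (area of the connected
land mass a cell belongs to), Shannon land-cover diversity, long-term
climate stability from paleo-climate snapshots, majority-coverage zonal
labelling, and the data-deficient reclassification used in the
sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import STRtree
from shapely.geometry import box

from .world import WorldGrid, connectivity_structure

__all__ = [
    "THREATENED_STATUSES",
    "VALID_STATUSES",
    "rasterize_ranges",
    "richness",
    "insularity",
    "shannon_diversity",
    "climate_stability",
    "majority_label",
    "reclassify_dd",
    "percentage_change",
]

logger = logging.getLogger(__name__)

#: IUCN Red List codes counted as threatened
THREATENED_STATUSES = frozenset({"VU", "EN", "CR"})
VALID_STATUSES = frozenset({"LC", "NT", "VU", "EN", "CR", "DD"})


def rasterize_ranges(
    range_geometries: pd.DataFrame,
    grid: WorldGrid,
    cell_size: float = 1.0,
    apply_filter: bool = True,
) -> pd.DataFrame:
    """Convert species range polygons to a per-cell presence matrix.

    ``range_geometries`` needs columns ``species_id`` and ``geometry``
    (shapely geometries in the grid's coordinate frame, where cell
    ``(row, col)`` spans ``[col, col+1) x [row, row+1)`` in units of
    ``cell_size``); optional metadata columns ``taxon``, ``status``,
    ``native``, ``extant``, ``breeding_or_resident`` are carried through.

    A species is present in a cell iff its polygon intersects the cell's
    rectangle — touching the boundary counts, and covering any sliver of
    the cell marks the species present in the entire cell.  Sea cells are
    excluded.  Records failing the native / extant / breeding-or-resident
    filter are dropped (when ``apply_filter``); invalid or empty
    geometries are skipped with a warning.
    """
    rows, cols = grid.shape
    land = grid.land_cell_ids
    land_rc = np.column_stack(np.unravel_index(land, (rows, cols)))
    cell_boxes = [
        box(
            c * cell_size,
            r * cell_size,
            (c + 1) * cell_size,
            (r + 1) * cell_size,
        )
        for r, c in land_rc
    ]
    tree = STRtree(cell_boxes)

    records: list[dict] = []
    meta_cols = [
        c
        for c in ("taxon", "status", "native", "extant", "breeding_or_resident")
        if c in range_geometries.columns
    ]
    for rec in range_geometries.itertuples(index=False):
        geom = rec.geometry
        if geom is None or geom.is_empty or not geom.is_valid:
            logger.warning("skipping invalid/empty geometry for %s", rec.species_id)
            continue
        if apply_filter:
            ok = all(
                getattr(rec, flag, True)
                for flag in ("native", "extant", "breeding_or_resident")
            )
            if not ok:
                continue
        hits = tree.query(geom, predicate="intersects")
        for i in hits:
            row = {"species_id": rec.species_id, "cell_id": int(land[i])}
            for c in meta_cols:
                row[c] = getattr(rec, c)
            records.append(row)

    columns = ["species_id", "cell_id", *meta_cols]
    if not records:
        return pd.DataFrame(columns=columns)
    presence = pd.DataFrame.from_records(records)[columns]
    return presence.drop_duplicates(subset=["species_id", "cell_id"], ignore_index=True)


def richness(presence: pd.DataFrame, per_taxon: bool = True) -> pd.DataFrame:
    """Count total, threatened and data-deficient species per cell.

    ``presence`` is a presence matrix with columns ``species_id``,
    ``cell_id``, ``status`` and (optionally) ``taxon``.  Total richness
    counts distinct species; threatened richness counts those with
    status VU, EN or CR; DD richness counts status DD.  Returned per
    taxon group and for the ``combined`` assemblage.
    """
    if presence.empty:
        return pd.DataFrame(
            columns=[
                "cell_id",
                "taxon",
                "total_richness",
                "threatened_richness",
                "dd_richness",
            ]
        )
    unknown = set(presence["status"].unique()) - VALID_STATUSES
    if unknown:
        raise ValueError(f"unknown IUCN status code(s): {sorted(unknown)}")

    work = presence.drop_duplicates(subset=["species_id", "cell_id"]).copy()
    work["is_threatened"] = work["status"].isin(THREATENED_STATUSES)
    work["is_dd"] = work["status"].eq("DD")
    if per_taxon and "taxon" in work.columns:
        groups = [work.assign(_taxon=work["taxon"]), work.assign(_taxon="combined")]
    else:
        groups = [work.assign(_taxon="combined")]

    out = []
    for g in groups:
        agg = g.groupby(["cell_id", "_taxon"]).agg(
            total_richness=("species_id", "size"),
            threatened_richness=("is_threatened", "sum"),
            dd_richness=("is_dd", "sum"),
        )
        out.append(agg.reset_index().rename(columns={"_taxon": "taxon"}))
    result = pd.concat(out, ignore_index=True)
    return result.sort_values(["taxon", "cell_id"], ignore_index=True)


def insularity(world: WorldGrid) -> pd.Series:
    """Total area (km^2) of the land mass each land cell belongs to.

    Constant within each connected component of the land mask; smaller
    values indicate more insular cells (islands).  Indexed by cell id
    over land cells only; sea cells are undefined and omitted.
    """
    structure = connectivity_structure(world.connectivity)
    labels, n = ndimage.label(world.is_land, structure=structure)
    flat = labels.ravel()
    land = world.land_cell_ids
    counts = np.bincount(flat[land], minlength=n + 1)
    area = counts[flat[land]] * world.cell_area_km2
    return pd.Series(area, index=pd.Index(land, name="cell_id"), name="insularity")


def shannon_diversity(class_fractions) -> float:
    """Shannon information index H = -sum(p_i ln p_i) of cover fractions.

    Fractions must be non-negative and not all zero; they are
    renormalised to sum to one, and zero-fraction classes contribute
    nothing (0 ln 0 := 0).
    """
    p = np.asarray(class_fractions, dtype=float)
    if (p < 0).any():
        raise ValueError("class fractions must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("class fractions sum to zero; diversity undefined")
    p = p / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def climate_stability(stack: pd.DataFrame, pooled_z: bool = True) -> pd.Series:
    """Long-term climate stability from a paleo-climate snapshot stack.

    ``stack`` has columns ``cell_id``, ``time_step``, ``temperature``,
    ``precipitation``, with the same ordered set of (at least two) time
    steps in every cell.  Temperature and precipitation are z-transformed
    (by default over the pooled cell x time stack, so values are
    comparable across cells; ``pooled_z=False`` standardises each
    snapshot separately); for each consecutive temporal transition the
    Euclidean distance between the (T_z, P_z) points is taken, and the
    per-cell mean distance across transitions is returned.  Smaller
    values mean more stable climate.
    """
    required = {"cell_id", "time_step", "temperature", "precipitation"}
    missing = required - set(stack.columns)
    if missing:
        raise ValueError(f"stack missing columns: {sorted(missing)}")
    steps = np.sort(stack["time_step"].unique())
    if steps.size < 2:
        raise ValueError("need at least two time steps")
    per_cell = stack.groupby("cell_id")["time_step"].nunique()
    if (per_cell != steps.size).any():
        raise ValueError("every cell must have the same set of time steps")

    work = stack.sort_values(["cell_id", "time_step"]).copy()
    for var in ("temperature", "precipitation"):
        if pooled_z:
            sd = work[var].std(ddof=0)
            if sd == 0:
                raise ValueError(f"{var} has zero variance; z-transform undefined")
            work[var + "_z"] = (work[var] - work[var].mean()) / sd
        else:
            grouped = work.groupby("time_step")[var]
            sd = grouped.transform("std").replace(0.0, np.nan)
            if sd.isna().any():
                raise ValueError(f"{var} has zero variance; z-transform undefined")
            work[var + "_z"] = (work[var] - grouped.transform("mean")) / sd

    g = work.groupby("cell_id")
    dt = g["temperature_z"].diff()
    dp = g["precipitation_z"].diff()
    dist = np.sqrt(dt**2 + dp**2)
    out = dist.groupby(work["cell_id"]).mean()
    out.name = "climate_stability"
    return out


def majority_label(subcell_coverage: pd.DataFrame) -> pd.Series:
    """Assign each cell the label with the greatest sub-cell coverage.

    ``subcell_coverage`` is indexed by cell id with one column per label
    holding non-negative coverage fractions.  Ties break to the smallest
    label (column order after sorting); cells with all-zero coverage are
    left unlabelled (NA).
    """
    cov = subcell_coverage.reindex(sorted(subcell_coverage.columns), axis=1)
    if (cov.to_numpy() < 0).any():
        raise ValueError("coverage fractions must be non-negative")
    values = cov.to_numpy(dtype=float)
    best = values.argmax(axis=1)  # first (smallest) label wins ties
    labels = pd.Series(
        np.asarray(cov.columns)[best], index=cov.index, name="majority_label"
    )
    labels[values.sum(axis=1) == 0] = pd.NA
    return labels


def reclassify_dd(layer: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Randomly reclassify a fraction of data-deficient species as threatened.

    Per cell (and taxon), a Binomial(dd_richness, fraction) draw is added
    to the threatened count; DD species are already included in total
    richness, which is unchanged.  ``fraction = 0`` returns the input
    unchanged; ``fraction = 1`` adds the full DD count.  Values outside
    {0, 0.5, 1} are allowed but flagged as non-standard.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("reclassification fraction must lie in [0, 1]")
    if fraction not in (0.0, 0.5, 1.0):
        logger.warning("non-standard DD reclassification fraction %s", fraction)
    if fraction == 0.0:
        return layer.copy()
    out = layer.copy()
    rng = np.random.default_rng(seed)
    added = rng.binomial(out["dd_richness"].to_numpy(), fraction)
    out["threatened_richness"] = out["threatened_richness"] + added
    return out


def percentage_change(before, after) -> np.ndarray:
    """Generic percentage-change helper for land-cover-area columns."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(before != 0, 100.0 * (after - before) / before, np.nan)
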