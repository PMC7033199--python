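"""Seeded synthetic gridded worlds with planted richness drivers.

The generator produces an equal-area land/sea lattice partitioned into
land masses, ecoregions and zoogeographic regions, a set of spatially
autocorrelated environmental (E) and human-impact (H) covariate fields
(including one pair with a controlled high correlation), and per-cell
total / threatened / data-deficient species counts for four vertebrate
taxon groups, drawn from known smooth responses to a planted subset of
the covariates.  Everything is deterministic given the master seed, so
every downstream stage of the analysis can be tested without any real
range-map or climate data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "WorldConfig",
    "WorldGrid",
    "CovariateTable",
    "SpeciesEffectSpec",
    "EffectTerm",
    "TAXA",
    "generate_world",
    "generate_covariates",
    "generate_species",
    "default_effect_spec",
]

TAXA = ("amphibians", "reptiles", "birds", "mammals")

# stage offsets used to derive independent child seeds from the master seed
_STAGE_WORLD = 11
_STAGE_COVARIATES = 23
_STAGE_SPECIES = 37


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a synthetic world.

    ``autocorr_range`` is the Gaussian smoothing length scale, in cell
    units, applied to the white-noise fields that underlie both the land
    mask and the covariates.  ``n_landmasses`` is a target: land masses
    are emergent connected components of the thresholded field seeded by
    that many Gaussian bumps, so the realised count can differ slightly.
    """

    seed: int = 0
    grid_rows: int = 60
    grid_cols: int = 120
    land_fraction: float = 0.3
    n_landmasses: int = 8
    n_ecoregions: int = 40
    n_regions: int = 8
    autocorr_range: float = 1.5
    cell_area_km2: float = 3091.0  # area of a 0.5 deg Behrman cell
    connectivity: int = 8  # 4 or 8; adjacency for land-mass labelling

    def validate(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.grid_rows * self.grid_cols < 100:
            raise ValueError("grid must contain at least 100 cells")
        if not 0.0 < self.land_fraction <= 1.0:
            raise ValueError("land_fraction must lie in (0, 1]")
        if self.n_regions < 1 or self.n_ecoregions < self.n_regions:
            raise ValueError("need n_ecoregions >= n_regions >= 1")
        if self.n_landmasses < 1:
            raise ValueError("n_landmasses must be positive")
        if self.autocorr_range < 0:
            raise ValueError("autocorr_range must be non-negative")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class WorldGrid:
    """Equal-area cell lattice with land/sea mask and nested region labels.

    All label arrays are 2-D ``(grid_rows, grid_cols)``; sea cells carry
    ``-1`` in every label array.  Cell ids are 0-based row-major.
    """

    is_land: np.ndarray
    landmass_id: np.ndarray
    ecoregion_id: np.ndarray
    region_id: np.ndarray
    cell_area_km2: float
    connectivity: int = 8

    @property
    def shape(self) -> tuple[int, int]:
        return self.is_land.shape

    @property
    def n_cells(self) -> int:
        return self.is_land.size

    @property
    def land_cell_ids(self) -> np.ndarray:
        return np.flatnonzero(self.is_land.ravel())

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.indices(self.shape)
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "row": rows.ravel(),
                "col": cols.ravel(),
                "area_km2": self.cell_area_km2,
                "is_land": self.is_land.ravel(),
                "landmass_id": self.landmass_id.ravel(),
                "ecoregion_id": self.ecoregion_id.ravel(),
                "region_id": self.region_id.ravel(),
            }
        )


@dataclass
class CovariateTable:
    """Per-land-cell covariate values plus the category registry.

    ``data`` is indexed by cell id (land cells only); ``categories`` maps
    each covariate name to ``"E"`` (environmental) or ``"H"`` (human
    impact).  Total species richness, when added for modelling, carries
    category ``"S"``.
    """

    data: pd.DataFrame
    categories: dict[str, str]
    correlated_pair: tuple[str, str] | None = None
    target_rho: float | None = None

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def to_long(self) -> pd.DataFrame:
        long = self.data.reset_index().melt(
            id_vars="cell_id", var_name="layer", value_name="value"
        )
        return long.sort_values(["layer", "cell_id"], ignore_index=True)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """Binary structuring element for connected-component labelling."""
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma <= 0:
        return noise
    smoothed = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
    return smoothed


def generate_world(config: WorldConfig) -> WorldGrid:
    """Generate the land/sea lattice and its nested spatial partitions.

    The land mask thresholds a smoothed random field (seeded with
    ``n_landmasses`` Gaussian bumps so land clusters into roughly that
    many masses) at the quantile that yields ``land_fraction``.  Land
    masses are the connected components of the mask; ecoregions are a
    nearest-seed tessellation of the land cells, and zoogeographic
    regions are unions of ecoregions (each ecoregion is attached to the
    nearest of ``n_regions`` region seeds, which are themselves ecoregion
    seeds, so every region spans at least one ecoregion).
    """
    config.validate()
    rng = _stage_rng(config.seed, _STAGE_WORLD)
    rows, cols = config.grid_rows, config.grid_cols

    fld = _smooth_field(rng, (rows, cols), config.autocorr_range)
    std = fld.std()
    if std > 0:
        fld = (fld - fld.mean()) / std
    # Gaussian bumps pull land together into ~n_landmasses masses
    rr, cc = np.indices((rows, cols))
    bump_sigma = 0.5 * np.sqrt(config.land_fraction * rows * cols / config.n_landmasses)
    for _ in range(config.n_landmasses):
        cy, cx = rng.uniform(0, rows), rng.uniform(0, cols)
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        fld = fld + 1.5 * np.exp(-d2 / (2.0 * bump_sigma**2))

    if config.land_fraction >= 1.0:
        is_land = np.ones((rows, cols), dtype=bool)
    else:
        threshold = np.quantile(fld, 1.0 - config.land_fraction)
        is_land = fld >= threshold

    structure = connectivity_structure(config.connectivity)
    labels, _ = ndimage.label(is_land, structure=structure)
    landmass_id = np.where(is_land, labels - 1, -1)

    land_idx = np.flatnonzero(is_land.ravel())
    if config.n_ecoregions > land_idx.size:
        raise ValueError(
            f"cannot place {config.n_ecoregions} ecoregions on "
            f"{land_idx.size} land cells"
        )

    eco_seed_cells = rng.choice(land_idx, size=config.n_ecoregions, replace=False)
    seed_rc = np.column_stack(np.unravel_index(eco_seed_cells, (rows, cols)))
    land_rc = np.column_stack(np.unravel_index(land_idx, (rows, cols)))
    # nearest-seed tessellation; argmin breaks ties by smallest seed index
    d2 = ((land_rc[:, None, :] - seed_rc[None, :, :]) ** 2).sum(axis=2)
    eco_of_land = d2.argmin(axis=1)
    ecoregion_id = np.full(rows * cols, -1, dtype=int)
    ecoregion_id[land_idx] = eco_of_land

    # first n_regions ecoregion seeds double as region seeds, so region r
    # always contains ecoregion r
    region_seed_rc = seed_rc[: config.n_regions]
    d2r = ((seed_rc[:, None, :] - region_seed_rc[None, :, :]) ** 2).sum(axis=2)
    region_of_eco = d2r.argmin(axis=1)
    region_id = np.full(rows * cols, -1, dtype=int)
    region_id[land_idx] = region_of_eco[eco_of_land]

    return WorldGrid(
        is_land=is_land,
        landmass_id=landmass_id.reshape(rows, cols),
        ecoregion_id=ecoregion_id.reshape(rows, cols),
        region_id=region_id.reshape(rows, cols),
        cell_area_km2=config.cell_area_km2,
        connectivity=config.connectivity,
    )


# default covariate registry: 15 layers mirroring the categories used in
# global threatened-richness analyses (E = environmental, H = human impact)
DEFAULT_COVARIATES: dict[str, str] = {
    "mean_temperature": "E",
    "temperature_seasonality": "E",
    "annual_precipitation": "E",
    "precipitation_seasonality": "E",
    "min_elevation": "E",
    "elevation_sd": "E",
    "landcover_diversity": "E",
    "insularity": "E",
    "climate_stability": "E",
    "human_landuse_area": "H",
    "human_influence_index": "H",
    "protected_area_coverage": "H",
    "landcover_change_short": "H",
    "landcover_change_long": "H",
    "invasive_species": "H",
}

CORRELATED_PAIR = ("mean_temperature", "temperature_seasonality")
TARGET_RHO = 0.85


def generate_covariates(
    world: WorldGrid,
    config: WorldConfig,
    registry: Mapping[str, str] | None = None,
    correlated_pair: tuple[str, str] | None = CORRELATED_PAIR,
    target_rho: float = TARGET_RHO,
) -> CovariateTable:
    """Generate spatially autocorrelated covariate fields over land cells.

    Each covariate is smoothed white noise (length scale
    ``config.autocorr_range``), standardised to mean 0 / SD 1 over land
    cells.  The designated pair is constructed so that its sample Pearson
    correlation over land cells equals ``target_rho`` exactly (the second
    member is a mixture of the first and an orthogonalised residual
    field), emulating the strong temperature / seasonality collinearity
    seen in real bioclim layers.  All other pairs are independent fields.
    """
    registry = dict(DEFAULT_COVARIATES if registry is None else registry)
    rng = _stage_rng(config.seed, _STAGE_COVARIATES)
    land = world.land_cell_ids

    def standardised_field() -> np.ndarray:
        f = _smooth_field(rng, world.shape, config.autocorr_range).ravel()[land]
        sd = f.std()
        if sd == 0:
            raise ValueError("degenerate covariate field (zero variance)")
        return (f - f.mean()) / sd

    columns: dict[str, np.ndarray] = {name: standardised_field() for name in registry}

    if correlated_pair is not None:
        a_name, b_name = correlated_pair
        if a_name not in registry or b_name not in registry:
            raise ValueError(f"correlated pair {correlated_pair} not in registry")
        a = columns[a_name]
        b_raw = columns[b_name]
        # Gram-Schmidt on the sample so corr(a, b) == target_rho exactly
        resid = b_raw - (a @ b_raw / (a @ a)) * a
        resid = (resid - resid.mean()) / resid.std()
        mixed = target_rho * a + np.sqrt(1.0 - target_rho**2) * resid
        columns[b_name] = (mixed - mixed.mean()) / mixed.std()

    data = pd.DataFrame(columns, index=pd.Index(land, name="cell_id"))
    return CovariateTable(
        data=data,
        categories=registry,
        correlated_pair=correlated_pair,
        target_rho=target_rho if correlated_pair is not None else None,
    )


# ---------------------------------------------------------------------------
# species generation


@dataclass(frozen=True)
class EffectTerm:
    """One planted smooth response of richness to a covariate.

    ``form`` is one of ``linear+``, ``linear-``, ``unimodal``,
    ``asymptotic``, ``threshold``; covariates are standardised, so the
    forms are defined on the z scale: ``unimodal`` peaks at z = 0 and
    ``asymptotic`` saturates for large z.
    """

    covariate: str
    form: str
    size: float

    def evaluate(self, z: np.ndarray) -> np.ndarray:
        if not np.isfinite(self.size):
            raise ValueError(f"effect size for {self.covariate} must be finite")
        if self.form == "linear+":
            return self.size * z
        if self.form == "linear-":
            return -self.size * z
        if self.form == "unimodal":
            return self.size * (1.0 - z**2) / 2.0
        if self.form == "asymptotic":
            return self.size * (1.0 - np.exp(-(z + 2.0) / 1.5))
        if self.form == "threshold":
            return self.size * (z > 0.0).astype(float)
        raise ValueError(f"unknown effect form {self.form!r}")


@dataclass(frozen=True)
class SpeciesEffectSpec:
    """Generative recipe for per-cell species counts.

    Total richness per taxon is negative binomial with log-mean a sum of
    ``baseline_total_response`` terms; threatened richness is binomial in
    the total with a logistic-linear probability driven by the planted
    ``threatened_effects``; DD species are a second multinomial slice of
    the non-threatened pool, at rate ``dd_rate``.
    """

    threatened_effects: tuple[EffectTerm, ...]
    baseline_total_response: tuple[EffectTerm, ...]
    base_threat_logit: float = -1.73  # logit(0.15); ~1 in 6 species threatened
    dd_rate: float = 0.10
    nb_dispersion: float = 10.0  # NB size parameter; smaller = noisier counts
    taxon_log_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "amphibians": np.log(20.0),
            "reptiles": np.log(25.0),
            "birds": np.log(120.0),
            "mammals": np.log(60.0),
        }
    )

    @property
    def driver_names(self) -> list[str]:
        return [t.covariate for t in self.threatened_effects]

    def validate(self, covariate_names: Sequence[str]) -> None:
        for term in self.threatened_effects + self.baseline_total_response:
            if term.covariate not in covariate_names:
                raise ValueError(
                    f"effect spec names covariate {term.covariate!r} which is "
                    f"not in the covariate table"
                )
        if not 0.0 <= self.dd_rate <= 1.0:
            raise ValueError("dd_rate must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def default_effect_spec(**overrides) -> SpeciesEffectSpec:
    """The canonical planted-driver recipe used across tests and examples.

    Three covariates drive threat beyond the size of the species pool:
    two environmental (elevational heterogeneity, linear and positive;
    annual precipitation, asymptotic) and one human-impact (area of
    human-dominated land uses, linear and positive).  Total richness
    responds to mean temperature (positive), land-cover diversity
    (positive) and human land use (intermediate maximum), so human land
    use shows the classic contrast: monotone-positive for threatened
    richness, unimodal for total richness.  Because threatened counts
    are binomial in the total, the two human-land-use amplitudes are
    balanced so the planted threatened response really is monotone over
    the central 90% of the covariate's range (d/dz[log mu + log p] > 0):
    a strong unimodal total response would drag threatened counts down
    with it at high land use no matter what the threat probability does.
    """
    defaults = dict(
        threatened_effects=(
            EffectTerm("elevation_sd", "linear+", 1.2),
            EffectTerm("annual_precipitation", "asymptotic", 1.0),
            EffectTerm("human_landuse_area", "linear+", 1.2),
        ),
        baseline_total_response=(
            EffectTerm("mean_temperature", "linear+", 0.8),
            EffectTerm("landcover_diversity", "linear+", 0.4),
            EffectTerm("human_landuse_area", "unimodal", 0.15),
        ),
    )
    defaults.update(overrides)
    return SpeciesEffectSpec(**defaults)


def _sum_effects(terms: Sequence[EffectTerm], table: pd.DataFrame) -> np.ndarray:
    total = np.zeros(len(table))
    for term in terms:
        total = total + term.evaluate(table[term.covariate].to_numpy())
    return total


def generate_species(
    world: WorldGrid,
    covariates: CovariateTable,
    spec: SpeciesEffectSpec | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-cell species counts for the four taxon groups.

    Returns ``(richness, truth)``.  ``richness`` is a long table
    ``(cell_id, taxon, total_richness, threatened_richness,
    dd_richness)`` including a ``combined`` taxon equal to the cell-wise
    sum of the four groups.  ``truth`` carries the per-cell expected
    total count and threat probability per taxon, for oracle tests.

    Counts per taxon and cell: ``total ~ NB(mu, k)`` with ``log mu`` the
    planted baseline response; then a multinomial split of ``total`` into
    (threatened, data-deficient, other) with threat probability
    ``sigmoid(base_threat_logit + planted effects)`` applied to the
    non-DD fraction, so ``threatened + dd <= total`` in every cell.
    """
    if spec is None:
        spec = default_effect_spec()
    spec.validate(covariates.names)
    if seed is None:
        seed = 0
    rng = _stage_rng(seed, _STAGE_SPECIES)

    table = covariates.data
    n = len(table)
    log_mu_base = _sum_effects(spec.baseline_total_response, table)
    threat_logit = spec.base_threat_logit + _sum_effects(spec.threatened_effects, table)
    p_threat_assessed = 1.0 / (1.0 + np.exp(-threat_logit))

    frames = []
    truths = []
    for taxon in TAXA:
        mu = np.exp(spec.taxon_log_means[taxon] + log_mu_base)
        k = spec.nb_dispersion
        # NB as Poisson-gamma mixture
        lam = rng.gamma(shape=k, scale=mu / k)
        total = rng.poisson(lam)
        p_thr = (1.0 - spec.dd_rate) * p_threat_assessed
        p_dd = np.full(n, spec.dd_rate)
        threatened = rng.binomial(total, p_thr)
        remaining = total - threatened
        with np.errstate(divide="ignore", invalid="ignore"):
            p_dd_given_rest = np.where(p_thr < 1.0, p_dd / (1.0 - p_thr), 0.0)
        dd = rng.binomial(remaining, np.clip(p_dd_given_rest, 0.0, 1.0))
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": table.index.to_numpy(),
                    "taxon": taxon,
                    "total_richness": total,
                    "threatened_richness": threatened,
                    "dd_richness": dd,
                }
            )
        )
        truths.append(
            pd.DataFrame(
                {
                    "cell_id": table.index.to_numpy(),
                    "taxon": taxon,
                    "expected_total": mu,
                    "threat_probability": p_thr,
                    "dd_probability": p_dd,
                }
            )
        )

    richness = pd.concat(frames, ignore_index=True)
    combined = (
        richness.groupby("cell_id", as_index=False)[
            ["total_richness", "threatened_richness", "dd_richness"]
        ]
        .sum()
        .assign(taxon="combined")
    )
    richness = pd.concat([richness, combined], ignore_index=True)[
        ["cell_id", "taxon", "total_richness", "threatened_richness", "dd_richness"]
    ]
    truth = pd.concat(truths, ignore_index=True)
    return richness, truth
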