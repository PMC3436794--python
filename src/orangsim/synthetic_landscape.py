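"""Synthetic landscapes with a known hurdle response surface.

Every downstream stage of the pipeline (gridding, hurdle SDM, land-cover
simulation, climate projection, scenario engine) is exercised against
landscapes produced here, for which the generating process — and therefore
the correct answer — is known exactly.

A landscape is a stack of aligned rasters on a regular grid of square cells
(default 2.5 km, the scale of a female orangutan territory): smooth terrain
(elevation, slope), Euclidean distances to roads / rivers / settlements,
land-cover classes with reserve and strict-protection masks, and climate
fields.  The true response is a hurdle process: a logistic presence surface
and a log-linear expected-count surface, both linear in the z-scored
predictors with user-chosen coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .climate_proj import AnomalySchedule, ClimateStack

#: canonical land-cover legend; order matters (it is the tie-break order
#: used by the land-cover change simulator).
DEFAULT_CLASSES = ("forest", "degraded", "mangrove", "cleared", "water")

#: predictor layers every generated landscape carries
PREDICTOR_NAMES = (
    "elevation", "slope", "roaddist", "riverdist", "popdist",
    "forest", "degraded", "mangrove",
    "temperature", "wet_precip", "dry_precip",
)


def _default_transition() -> np.ndarray:
    """Annual land-cover transition matrix used as ground truth.

    Forest is lost to degraded/cleared at ~1.2 %/yr overall, echoing the
    magnitude of recent regional deforestation estimates; degraded land
    slowly converts to cleared; mangrove, cleared and water are near-inert.
    """
    m = np.eye(5)
    m[0, 0], m[0, 1], m[0, 3] = 0.988, 0.008, 0.004     # forest
    m[1, 1], m[1, 3] = 0.990, 0.010                      # degraded
    m[2, 2], m[2, 1] = 0.998, 0.002                      # mangrove
    return m


def _default_presence_coefficients() -> dict[str, float]:
    # presence most likely in warm forest far from roads, unlikely on
    # degraded/cleared land
    return {"forest": 1.5, "roaddist": 0.8, "temperature": 0.6, "degraded": -0.8}


def _default_abundance_coefficients() -> dict[str, float]:
    # abundance highest at low elevation and shallow slope, away from
    # settlements and roads, in forest; magnitudes keep per-cell expected
    # counts in the realistic 0-30 range of aerial nest surveys
    return {"elevation": -0.6, "slope": -0.3, "popdist": 0.5,
            "roaddist": 0.4, "forest": 0.6}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study system."""

    grid_shape: tuple[int, int] = (64, 64)
    cell_size: float = 2.5                      # km
    seed: int = 0
    landcover_classes: tuple[str, ...] = DEFAULT_CLASSES
    reserve_fraction: float = 0.30
    sfm_fraction: float = 0.20                  # fraction of reserves under SFM
    strict_fraction: float = 0.05               # strictly protected, non-reserve
    n_reserves: int = 8
    smooth_sigma: float = 6.0                   # Gaussian-field kernel width, cells
    presence_coefficients: dict[str, float] = field(
        default_factory=_default_presence_coefficients)
    abundance_coefficients: dict[str, float] = field(
        default_factory=_default_abundance_coefficients)
    presence_intercept: float = 0.0
    abundance_intercept: float = 1.0
    transition_truth: np.ndarray = field(default_factory=_default_transition)

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if len(set(self.landcover_classes)) != len(self.landcover_classes):
            raise ValueError("landcover_classes must be unique")
        t = np.asarray(self.transition_truth, dtype=float)
        k = len(self.landcover_classes)
        if t.shape != (k, k):
            raise ValueError(f"transition_truth must be {k}x{k}, got {t.shape}")
        if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition_truth rows must be non-negative and sum to 1")
        self.transition_truth = t


def strong_signal_config(**overrides) -> SyntheticConfig:
    """A high signal-to-noise variant of the default configuration.

    Doubles every presence and abundance effect size, giving response
    surfaces dominated by the predictors rather than sampling noise; used
    for parameter-recovery experiments where the question is whether the
    fitting machinery can find structure that is unambiguously present.
    """
    cfg = SyntheticConfig(**overrides)
    cfg.presence_coefficients = {k: 2 * v
                                 for k, v in cfg.presence_coefficients.items()}
    cfg.abundance_coefficients = {k: 2 * v
                                  for k, v in cfg.abundance_coefficients.items()}
    return cfg


@dataclass
class GridLandscape:
    """Aligned raster stack: predictors, land cover and protection masks."""

    predictors: dict[str, np.ndarray]
    landcover: np.ndarray                      # int codes into `classes`
    classes: tuple[str, ...]
    reserve_id: np.ndarray                     # int, 0 = not a reserve
    sfm_mask: np.ndarray                       # bool, reserves under SFM
    strict_mask: np.ndarray                    # bool, strictly protected (non-reserve)
    cell_size: float                           # km

    @property
    def shape(self) -> tuple[int, int]:
        return self.landcover.shape

    @property
    def reserve_mask(self) -> np.ndarray:
        return self.reserve_id > 0

    def validate(self) -> None:
        shp = self.shape
        for name, arr in self.predictors.items():
            if arr.shape != shp:
                raise ValueError(f"predictor {name!r} shape {arr.shape} != grid {shp}")
        for name, arr in (("reserve_id", self.reserve_id),
                          ("sfm_mask", self.sfm_mask),
                          ("strict_mask", self.strict_mask)):
            if arr.shape != shp:
                raise ValueError(f"{name} shape {arr.shape} != grid {shp}")


@dataclass
class TruthSurfaces:
    """The generating hurdle process on the grid."""

    presence_probability: np.ndarray           # in [0, 1]
    expected_count: np.ndarray                 # Poisson mean given presence, >= 0

    def validate(self) -> None:
        p, mu = self.presence_probability, self.expected_count
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("presence_probability outside [0, 1]")
        if not np.all(np.isfinite(mu)) or np.any(mu < 0):
            raise ValueError("expected_count must be finite and non-negative")


@dataclass
class NestSurvey:
    """Point survey records plus (optional) pseudoabsence points.

    ``records`` columns: transect_id, year, row, col, count.
    ``pseudoabsences`` columns: row, col.
    """

    records: pd.DataFrame
    pseudoabsences: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "col"]))


# ---------------------------------------------------------------------------
# landscape generation

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Gaussian random field: smoothed white noise, re-standardized."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _random_lines_mask(rng: np.random.Generator, shape: tuple[int, int],
                       n_lines: int) -> np.ndarray:
    """Rasterize straight lines between random boundary points."""
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_lines):
        if rng.random() < 0.5:  # roughly north-south
            r0, r1 = 0, rows - 1
            c0, c1 = rng.integers(0, cols, size=2)
        else:                   # roughly east-west
            c0, c1 = 0, cols - 1
            r0, r1 = rng.integers(0, rows, size=2)
        n = 2 * max(rows, cols)
        rr = np.clip(np.round(np.linspace(r0, r1, n)).astype(int), 0, rows - 1)
        cc = np.clip(np.round(np.linspace(c0, c1, n)).astype(int), 0, cols - 1)
        mask[rr, cc] = True
    return mask


def _distance_layer(mask: np.ndarray, cell_size: float) -> np.ndarray:
    if not mask.any():
        return np.full(mask.shape, np.hypot(*mask.shape) * cell_size)
    return ndimage.distance_transform_edt(~mask) * cell_size


def _place_reserves(rng: np.random.Generator, shape: tuple[int, int],
                    target_fraction: float, n_reserves: int) -> np.ndarray:
    """Contiguous rectangular reserves labelled 1..R, covering ~target_fraction."""
    rows, cols = shape
    reserve_id = np.zeros(shape, dtype=int)
    target_cells = target_fraction * rows * cols
    mean_side = max(2, int(round(np.sqrt(target_cells / max(n_reserves, 1)))))
    rid = 0
    for _ in range(10 * n_reserves):
        if reserve_id.astype(bool).sum() >= target_cells or rid >= n_reserves:
            break
        h = int(rng.integers(max(2, mean_side - 2), mean_side + 3))
        w = int(rng.integers(max(2, mean_side - 2), mean_side + 3))
        r = int(rng.integers(0, max(rows - h, 1)))
        c = int(rng.integers(0, max(cols - w, 1)))
        block = reserve_id[r:r + h, c:c + w]
        if (block > 0).any():
            continue
        rid += 1
        block[:] = rid
    return reserve_id


def zscore(arr: np.ndarray) -> np.ndarray:
    """z-score over the grid; constant layers map to zero."""
    sd = arr.std()
    return (arr - arr.mean()) / sd if sd > 0 else np.zeros_like(arr, dtype=float)


def generate_landscape(config: SyntheticConfig) -> tuple[GridLandscape, TruthSurfaces]:
    """Generate an aligned raster stack and its true hurdle surfaces.

    Deterministic: identical config (including seed) gives bit-identical
    output. Truth surfaces are logistic / log-linear in the z-scored
    predictors using ``config.presence_coefficients`` and
    ``config.abundance_coefficients``.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.grid_shape
    rows, cols = shape
    sigma = config.smooth_sigma

    # terrain: Gaussian random field scaled to a lowland-to-upland range (m)
    elev_field = _smooth_field(rng, shape, sigma)
    elevation = 10.0 + 700.0 * (elev_field - elev_field.min())
    gy, gx = np.gradient(elevation, config.cell_size * 1000.0)  # m per m
    slope = np.degrees(np.arctan(np.hypot(gy, gx)))

    # anthropogenic / habitat distance layers (km)
    n_lines = max(2, rows // 16)
    roaddist = _distance_layer(_random_lines_mask(rng, shape, n_lines),
                               config.cell_size)
    riverdist = _distance_layer(_random_lines_mask(rng, shape, n_lines),
                                config.cell_size)
    n_towns = max(2, (rows * cols) // 1024)
    towns = np.zeros(shape, dtype=bool)
    towns[rng.integers(0, rows, n_towns), rng.integers(0, cols, n_towns)] = True
    popdist = _distance_layer(towns, config.cell_size)

    # protection masks
    reserve_id = _place_reserves(rng, shape, config.reserve_fraction,
                                 config.n_reserves)
    n_res = int(reserve_id.max())
    n_sfm = int(round(config.sfm_fraction * n_res))
    sfm_ids = rng.choice(np.arange(1, n_res + 1), size=n_sfm, replace=False) \
        if n_sfm > 0 else np.array([], dtype=int)
    sfm_mask = np.isin(reserve_id, sfm_ids)
    strict_mask = np.zeros(shape, dtype=bool)
    if config.strict_fraction > 0:
        side = max(2, int(round(np.sqrt(config.strict_fraction * rows * cols / 2))))
        for _ in range(40):
            if strict_mask.sum() >= config.strict_fraction * rows * cols:
                break
            r = int(rng.integers(0, max(rows - side, 1)))
            c = int(rng.integers(0, max(cols - side, 1)))
            block = (slice(r, r + side), slice(c, c + side))
            if (reserve_id[block] > 0).any() or strict_mask[block].any():
                continue
            strict_mask[block] = True

    # land cover: thresholds on a smooth suitability field; reserves and
    # strictly protected land are pushed toward forest; mangrove fringes the
    # southern (bottom) edge standing in for a coastline
    g = _smooth_field(rng, shape, sigma / 2)
    g = g + 1.2 * (reserve_id > 0) + 1.2 * strict_mask
    classes = config.landcover_classes
    k = {name: i for i, name in enumerate(classes)}
    landcover = np.full(shape, k["forest"], dtype=int)
    q = np.quantile(g, [0.03, 0.15, 0.40])
    # classes beyond forest are optional in reduced legends
    for qi, name in zip((q[2], q[1], q[0]), ("degraded", "cleared", "water")):
        if name in k:
            landcover[g < qi] = k[name]
    if "mangrove" in k:
        coast = np.zeros(shape, dtype=bool)
        coast[-max(1, rows // 20):, :] = True
        landcover[coast & (landcover == k["forest"]) &
                  (reserve_id == 0)] = k["mangrove"]

    # climate: lapse-rate temperature plus smooth anomaly; seasonal rainfall
    temperature = 27.0 - 6.5 * elevation / 1000.0 + 0.5 * _smooth_field(rng, shape, sigma)
    wet_precip = np.clip(250.0 + 60.0 * _smooth_field(rng, shape, sigma), 0, None)
    dry_precip = np.clip(120.0 + 40.0 * _smooth_field(rng, shape, sigma), 0, None)

    predictors = {
        "elevation": elevation,
        "slope": slope,
        "roaddist": roaddist,
        "riverdist": riverdist,
        "popdist": popdist,
        "forest": (landcover == k["forest"]).astype(float),
        "degraded": (landcover == k.get("degraded", -1)).astype(float),
        "mangrove": (landcover == k.get("mangrove", -1)).astype(float),
        "temperature": temperature,
        "wet_precip": wet_precip,
        "dry_precip": dry_precip,
    }

    landscape = GridLandscape(predictors=predictors, landcover=landcover,
                              classes=classes, reserve_id=reserve_id,
                              sfm_mask=sfm_mask, strict_mask=strict_mask,
                              cell_size=config.cell_size)
    landscape.validate()
    truth = compute_truth_surfaces(landscape, config)
    return landscape, truth


def compute_truth_surfaces(landscape: GridLandscape,
                           config: SyntheticConfig) -> TruthSurfaces:
    """Logistic presence and log-linear count surfaces from config coefficients.

    Predictors are z-scored over the grid before the coefficients apply, so
    coefficient magnitudes are scale-free.
    """
    z = {name: zscore(arr) for name, arr in landscape.predictors.items()}
    eta_p = np.full(landscape.shape, config.presence_intercept, dtype=float)
    for name, coef in config.presence_coefficients.items():
        eta_p += coef * z[name]
    eta_a = np.full(landscape.shape, config.abundance_intercept, dtype=float)
    for name, coef in config.abundance_coefficients.items():
        eta_a += coef * z[name]
    from scipy.special import expit
    truth = TruthSurfaces(presence_probability=expit(eta_p),
                          expected_count=np.exp(eta_a))
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# survey generation

def generate_survey(landscape: GridLandscape, truth: TruthSurfaces,
                    transect_spacing: float, repeat_years: list[int],
                    reserve_bias: float, seed: int) -> NestSurvey:
    """Simulate aerial nest-count transects over the landscape.

    Transects are parallel north-south lines ``transect_spacing`` km apart.
    A fraction ``reserve_bias`` of transects is restricted to reserve cells,
    emulating the survey effort concentrated on forest reserves. Each cell a
    transect crosses in a survey year yields an independent draw
    ``Bernoulli(p) * Poisson(mu)`` from the truth surfaces.
    """
    if transect_spacing < landscape.cell_size:
        raise ValueError("transect_spacing must be >= cell_size")
    rows, cols = landscape.shape
    step = int(round(transect_spacing / landscape.cell_size))
    transect_cols = np.arange(step // 2, cols, step)
    if transect_cols.size == 0:
        raise ValueError("transect spacing wider than the grid: no transects")

    rng = np.random.default_rng(seed)
    n_biased = int(round(reserve_bias * transect_cols.size))
    biased = set(rng.choice(transect_cols.size, size=n_biased, replace=False).tolist())

    recs: list[tuple[int, int, int, int, int]] = []
    for tid, c in enumerate(transect_cols):
        rows_here = np.arange(rows)
        if tid in biased:
            rows_here = rows_here[landscape.reserve_mask[:, c]]
        for year in repeat_years:
            p = truth.presence_probability[rows_here, c]
            mu = truth.expected_count[rows_here, c]
            present = rng.random(rows_here.size) < p
            counts = np.where(present, rng.poisson(mu), 0)
            recs.extend((tid, year, int(r), int(c), int(n))
                        for r, n in zip(rows_here, counts))
    records = pd.DataFrame(recs, columns=["transect_id", "year", "row", "col", "count"])
    return NestSurvey(records=records)


# ---------------------------------------------------------------------------
# two-epoch land cover and climate anomalies

def generate_two_epoch_landcover(landscape: GridLandscape,
                                 transition_truth: np.ndarray,
                                 interval_years: int,
                                 seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Apply the interval transition kernel cell-wise to make an epoch pair.

    The kernel is the annual matrix raised to ``interval_years``; each cell
    draws its end-state independently from the row of its start class.
    """
    if interval_years < 1:
        raise ValueError("interval_years must be >= 1")
    t = np.asarray(transition_truth, dtype=float)
    if np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
        raise ValueError("transition_truth rows must sum to 1")
    kernel = np.linalg.matrix_power(t, interval_years)
    rng = np.random.default_rng(seed)
    lc0 = landscape.landcover
    lc1 = lc0.copy()
    for c in range(t.shape[0]):
        idx = np.flatnonzero(lc0.ravel() == c)
        if idx.size:
            lc1.ravel()[idx] = rng.choice(t.shape[0], size=idx.size, p=kernel[c])
    return lc0.copy(), lc1


def baseline_climate(landscape: GridLandscape, year: int) -> ClimateStack:
    """Package the landscape's climate layers as the baseline climatology."""
    return ClimateStack(temperature=landscape.predictors["temperature"].copy(),
                        wet_precip=landscape.predictors["wet_precip"].copy(),
                        dry_precip=landscape.predictors["dry_precip"].copy(),
                        year=year)


#: end-of-century state-mean temperature increase (degC) by scenario label
SCENARIO_WARMING = {"Ref": 2.5, "Pol": 1.2}


def generate_climate_deltas(landscape: GridLandscape, epochs: list[int],
                            scenario_label: str, seed: int,
                            warming_2100: float | None = None,
                            precip_amplitude: float = 5.0) -> AnomalySchedule:
    """Smooth anomaly stacks per epoch for a named warming scenario.

    Temperature deltas are additive (degC) and ramp linearly from zero at the
    first epoch to a spatial pattern whose state mean equals the scenario's
    end-of-century warming. Precipitation deltas are multiplicative (per
    cent, 100 = no change) and stay close to 100, emulating forecasts of
    relatively stable rainfall.
    """
    if list(epochs) != sorted(set(epochs)):
        raise ValueError("epochs must be strictly increasing")
    if warming_2100 is None:
        warming_2100 = SCENARIO_WARMING.get(scenario_label, 0.0)
    rng = np.random.default_rng(seed)
    shape = landscape.shape
    pattern = _smooth_field(rng, shape, 8.0)
    temp_pattern = 1.0 + 0.3 * pattern          # mean exactly 1
    temp_pattern -= temp_pattern.mean() - 1.0
    wet_pattern = _smooth_field(rng, shape, 8.0)
    dry_pattern = _smooth_field(rng, shape, 8.0)

    e0, e_last = epochs[0], epochs[-1]
    temp, wet, dry = {}, {}, {}
    for e in epochs:
        frac = 0.0 if e_last == e0 else (e - e0) / (e_last - e0)
        temp[e] = warming_2100 * frac * temp_pattern
        wet[e] = 100.0 + precip_amplitude * frac * wet_pattern
        dry[e] = 100.0 + precip_amplitude * frac * dry_pattern
    return AnomalySchedule(scenario=scenario_label, epochs=list(epochs),
                           temp_delta=temp, wet_delta=wet, dry_delta=dry)
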