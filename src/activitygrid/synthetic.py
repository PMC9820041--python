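"""Synthetic scenario generator with known ground truth.

Emulates the structure of the study data — categorized POIs on a
regular analysis grid, 48-bin diurnal activity-intensity curves for one
baseline day and three restriction/recovery days, and eight per-cell
attributes — with every quantity planted, so each downstream stage can
be validated against a known answer.  Nothing here attempts to mimic
real geography or real epidemic curves; the generator reproduces the
*statistical shape* of the inputs (multinomial POI mixes with dominant
classes, multiplicative window suppression, spatially smooth attribute
fields with a stated monotone attribute-to-change link).

Default magnitudes follow the study conditions: the three period
effects centre near -25%, -8% and -6.5%; GDP carries the largest
attribute effect, followed by road-junction density; residential POIs
are nationally the rarest class because residential cells are a
minority of the grid.

RNG discipline: one independent stream per stage, seeded ``seed +
fixed offset``, so stages are reproducible in isolation and any
scenario is bit-identical under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .change import DAY_LABELS, N_BINS, PERIODS, DEFAULT_WINDOWS, WindowPolicy
from .grid import GridDefinition, broadcast_city_values
from .taxonomy import CategoryTaxonomy, LAND_USE_CLASSES, MIXED, OTHER

# stage offsets for per-stage RNG streams
_OFF_LABELS, _OFF_POIS, _OFF_ATTRS, _OFF_INTENSITY = 11, 23, 37, 53

ATTRIBUTE_NAMES = (
    "gdp", "population_density", "urban_rural", "admin_level",
    "built_up_area", "bus_stop_density", "junction_density",
    "cumulative_cases",
)

#: planted-label mix (shares of cells), shaped like the study's class
#: counts: working most common, entertainment least among the four.
DEFAULT_LABEL_MIX = {
    "residential": 0.16,
    "working": 0.54,
    "entertainment": 0.12,
    MIXED: 0.18,
}

#: attribute effects on the planted change rate, percent per SD of the
#: (standardized) attribute; GDP dominates, junction density second.
DEFAULT_EFFECT_SPEC = {
    "period1": {"intercept": -25.0, "gdp": -9.0, "junction_density": -5.0,
                "population_density": -1.5, "built_up_area": -1.0,
                "bus_stop_density": -1.0, "cumulative_cases": -1.5},
    "period2": {"intercept": -8.0, "gdp": -5.0, "junction_density": -3.0,
                "bus_stop_density": -2.0, "population_density": -1.5,
                "built_up_area": -0.5, "cumulative_cases": -1.0},
    "period3": {"intercept": -6.5, "gdp": -4.5, "junction_density": -2.5,
                "bus_stop_density": -1.0, "population_density": -1.0,
                "built_up_area": -0.5, "cumulative_cases": -0.75},
}

#: relative within-class frequency of each first-level category
DEFAULT_CATEGORY_WEIGHTS = {
    "Residential community": 0.6, "Community service": 0.4,
    "Private company": 0.30, "Office building": 0.20,
    "Financial sector": 0.12, "Legal sector": 0.05,
    "Government institution": 0.13, "Education institution": 0.20,
    "Commercial site": 0.28, "Hotel": 0.17, "Tourism": 0.10,
    "Sport/gym": 0.12, "Catering site": 0.33,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one synthetic scenario.

    ``dominance`` is the target share (Eq.-2 scale, 0..1) that a pure
    cell's planted class receives of its normalized-frequency mass;
    ``noise_sd`` is the SD of the uniform perturbation applied to each
    cell's window-scaling rate (fractional change-rate units, so 0.05
    means 5 percentage points of rate noise).
    """

    n_rows: int = 20
    n_cols: int = 20
    cell_size: float = 5.0
    seed: int = 0
    label_mix: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_MIX))
    dominance: float = 0.7
    pois_per_cell: float = 120.0
    effect_spec: dict = field(
        default_factory=lambda: {p: dict(v)
                                 for p, v in DEFAULT_EFFECT_SPEC.items()})
    noise_sd: float = 0.05
    category_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS))
    city_block: int = 5  # cities are city_block x city_block cell blocks
    smoothness: float = 2.0  # Gaussian field correlation length, in cells

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 < self.dominance <= 1:
            raise ValueError("dominance must lie in (0, 1]")
        tot = sum(self.label_mix.values())
        if not np.isclose(tot, 1.0):
            raise ValueError("label_mix shares must sum to 1")
        if self.pois_per_cell <= 0:
            raise ValueError("zero total POIs requested")

    @property
    def grid(self) -> GridDefinition:
        return GridDefinition(origin=(0.0, 0.0), cell_size=self.cell_size,
                              n_rows=self.n_rows, n_cols=self.n_cols)

    def replace(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted per-cell truth: labels, sector labels, change rates
    (percent), and the attribute -> effect-size map actually used."""

    labels: pd.Series
    sector_labels: pd.Series
    change_rates: pd.DataFrame | None = None
    attributes: pd.DataFrame | None = None
    effects: dict | None = None


# ---------------------------------------------------------------------------
# labels

def plant_labels(config: ScenarioConfig,
                 taxonomy: CategoryTaxonomy | None = None) -> GroundTruth:
    """Draw a planted land-use label (and sector, where applicable) per
    cell from the configured label mix."""
    taxonomy = taxonomy or CategoryTaxonomy()
    rng = np.random.default_rng(config.seed + _OFF_LABELS)
    names = list(config.label_mix)
    probs = np.array([config.label_mix[k] for k in names])
    n = config.grid.n_cells
    labels = pd.Series(rng.choice(names, size=n, p=probs),
                       index=pd.RangeIndex(n, name="cell_id"), name="label")
    sectors = pd.Series("", index=labels.index, name="sector_label")
    for cls in taxonomy.sector_classes:
        mask = labels == cls
        if mask.any():
            sectors[mask] = rng.choice(taxonomy.sectors(cls),
                                       size=int(mask.sum()))
    return GroundTruth(labels=labels, sector_labels=sectors)


# ---------------------------------------------------------------------------
# POIs

def _calibrate_class_mixtures(label_mix: dict, dominance: float):
    """Per-label class-draw probabilities whose expected *normalized*
    shares (the classifier's Eq.-2 scale) hit the dominance target.

    Normalized frequencies divide by national class totals, which are
    themselves sums of the draws, so a pure cell's raw multinomial
    probabilities must be calibrated against the composition the whole
    grid will realize.  Writing pi[l] for the class-probability vector
    of label l and rho for the expected national class composition
    (mixed-use cells draw at rho, which pins their expected shares at
    exactly 1/3 each), we solve

        expected share of class l in an l-cell  =  dominance

    for the three pure labels, choosing among the feasible solutions
    the one with the most balanced rho (maximum sum log rho): a
    collapsed rho would make rare-class counts so noisy that the
    dominance planting is destroyed in the draws.

    Returns ``(pi, rho)`` with pi a dict label -> 3-vector.
    """
    from scipy import optimize

    pure = [l for l in LAND_USE_CLASSES]
    w = np.array([label_mix.get(l, 0.0) for l in pure])
    wm = label_mix.get(MIXED, 0.0)
    denom = w.sum() + wm
    if denom <= 0:
        raise ValueError("label_mix contains no classifiable labels")
    w, wm = w / denom, wm / denom

    present = w > 0
    if not present.any():
        # mixed-only scenario: every cell draws the same composition,
        # so expected shares are exactly 1/3 regardless of it
        rho = np.full(3, 1 / 3)
        pi_mat = np.tile(rho, (3, 1))
    elif dominance >= 1.0:
        pi_mat = np.eye(3)
        rho = (w[:, None] * pi_mat).sum(axis=0) / (1 - wm) if wm < 1 \
            else np.full(3, 1 / 3)
        rho = np.where(rho <= 0, 1e-12, rho)
    else:
        d = dominance
        off = (1 - d) / 2

        def expand(u):
            t = u.reshape(3, 3)
            t = np.exp(t - t.max(axis=1, keepdims=True))
            return t / t.sum(axis=1, keepdims=True)

        def achieved(pi_m):
            r = (w[:, None] * pi_m).sum(axis=0) / (1 - wm)
            F = pi_m / r
            return F / F.sum(axis=1, keepdims=True), r

        def diag_resid(u):
            a, _ = achieved(expand(u))
            return np.diag(a)[present] - d

        def balance(u):
            _, r = achieved(expand(u))
            r = r / r.sum()
            return -np.sum(np.log(r))

        u0 = np.log(np.full((3, 3), off) + np.eye(3) * (d - off)).ravel()
        res = optimize.minimize(
            balance, u0, constraints=[{"type": "eq", "fun": diag_resid}],
            method="SLSQP", options={"maxiter": 500, "ftol": 1e-14})
        if not res.success or np.abs(diag_resid(res.x)).max() > 1e-6:
            raise ValueError(
                f"cannot calibrate dominance {dominance} for label mix "
                f"{label_mix}")
        pi_mat, rho = expand(res.x), achieved(expand(res.x))[1]

    pi = {l: pi_mat[j] for j, l in enumerate(pure)}
    pi[MIXED] = rho / rho.sum()
    return pi, rho / rho.sum()


def generate_pois(config: ScenarioConfig,
                  truth: GroundTruth | None = None,
                  taxonomy: CategoryTaxonomy | None = None):
    """Draw categorized POIs cell by cell.

    Each cell receives ``Poisson(pois_per_cell)`` POIs (at least 1 for
    labelled cells) distributed multinomially over the 13 first-level
    categories so that the planted class's expected normalized-share is
    the configured dominance fraction.  Cells planted "other" receive
    POIs of a non-taxonomy category ("Park").  Positions are uniform
    within the cell.

    Returns ``(pois, truth)`` where pois has columns poi_id, x, y,
    category, cell_id.
    """
    taxonomy = taxonomy or CategoryTaxonomy()
    for cats in (config.category_weights,):
        unknown = set(cats) - set(taxonomy.categories)
        if unknown:
            raise ValueError(f"profile references unknown categories: "
                             f"{sorted(unknown)}")
    truth = truth or plant_labels(config, taxonomy)
    rng = np.random.default_rng(config.seed + _OFF_POIS)
    grid = config.grid
    labels = truth.labels

    pi, _rho = _calibrate_class_mixtures(config.label_mix, config.dominance)
    class_p = np.stack([pi.get(l, np.zeros(3)) for l in labels.to_numpy()])

    # expand class probabilities to the 13 categories via within-class
    # weights; planted-sector cells concentrate their class mass on a
    # sector-targeted redistribution of those weights
    cats = list(taxonomy.categories)
    cat_idx = {c: k for k, c in enumerate(cats)}
    w = np.array([config.category_weights.get(c, 0.0) for c in cats])
    cls_of = np.array([LAND_USE_CLASSES.index(taxonomy.class_of(c))
                       for c in cats])

    n_cells = grid.n_cells
    cat_p = np.zeros((n_cells, len(cats)))
    for j in range(3):
        sel = cls_of == j
        wj = w[sel] / w[sel].sum()
        cat_p[:, sel] = class_p[:, [j]] * wj
    # sector planting: reweight within the planted class toward the
    # planted sector so its within-class normalized share ~ dominance
    sec = truth.sector_labels.to_numpy()
    for i in np.flatnonzero(sec != ""):
        cls = labels.iloc[i]
        j = LAND_USE_CLASSES.index(cls)
        sel = cls_of == j
        k = sel.sum()
        tgt = np.full(k, (1 - config.dominance) / (k - 1)) \
            if k > 1 else np.ones(1)
        names_j = [c for c in cats if cat_idx[c] in np.flatnonzero(sel)]
        tgt[names_j.index(sec[i])] = config.dominance
        wj = w[sel] * tgt
        cat_p[i, sel] = class_p[i, j] * wj / wj.sum()

    counts = rng.poisson(config.pois_per_cell, size=n_cells)
    counts[(labels != OTHER).to_numpy() & (counts == 0)] = 1

    rows_x, rows_y, rows_cat, rows_cid = [], [], [], []
    rcell, ccell = np.divmod(np.arange(n_cells), grid.n_cols)
    for i in range(n_cells):
        m = int(counts[i])
        if m == 0:
            continue
        if labels.iloc[i] == OTHER:
            drawn = np.full(m, "Park", dtype=object)
        else:
            drawn = rng.choice(len(cats), size=m, p=cat_p[i])
            drawn = np.asarray(cats, dtype=object)[drawn]
        x0 = grid.origin[0] + ccell[i] * grid.cell_size
        y0 = grid.origin[1] + rcell[i] * grid.cell_size
        rows_x.append(x0 + rng.random(m) * grid.cell_size)
        rows_y.append(y0 + rng.random(m) * grid.cell_size)
        rows_cat.append(drawn)
        rows_cid.append(np.full(m, i))
    pois = pd.DataFrame({
        "x": np.concatenate(rows_x),
        "y": np.concatenate(rows_y),
        "category": np.concatenate(rows_cat),
        "cell_id": np.concatenate(rows_cid),
    })
    pois.insert(0, "poi_id", np.arange(len(pois)))
    return pois, truth


# ---------------------------------------------------------------------------
# attributes

def _smooth_field(rng, shape, smoothness):
    """Standardized spatially smooth Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), smoothness,
                                mode="wrap")
    return (f - f.mean()) / f.std()


def generate_attributes(config: ScenarioConfig,
                        truth: GroundTruth) -> GroundTruth:
    """Attach the eight attributes and the planted change rates.

    Continuous fields (GDP, population density, built-up area, bus-stop
    and junction densities) are spatially smooth positive surfaces;
    urban/rural is binary (population above its 70th percentile);
    administrative level is an ordinal 1..4 from GDP quartiles;
    cumulative cases are a city-level draw broadcast to member cells
    (cities are square blocks of cells).  The planted change rate of
    each period is the configured linear (hence monotone) function of
    the standardized active attributes — deterministic here; all
    change-rate noise enters later through the intensity scaling.
    """
    rng = np.random.default_rng(config.seed + _OFF_ATTRS)
    shape = (config.n_rows, config.n_cols)
    n = config.grid.n_cells
    idx = pd.RangeIndex(n, name="cell_id")

    z_gdp = _smooth_field(rng, shape, config.smoothness).ravel()
    z_pop = 0.6 * z_gdp + 0.4 * _smooth_field(rng, shape,
                                              config.smoothness).ravel()
    z_bu = 0.5 * z_pop + 0.5 * _smooth_field(rng, shape,
                                             config.smoothness).ravel()
    z_bus = _smooth_field(rng, shape, config.smoothness).ravel()
    z_jun = 0.4 * z_gdp + 0.6 * _smooth_field(rng, shape,
                                              config.smoothness).ravel()

    attrs = pd.DataFrame(index=idx)
    attrs["gdp"] = np.exp(1.2 * z_gdp) * 1e4          # currency per cell
    attrs["population_density"] = np.exp(1.0 * z_pop) * 500.0
    pop_cut = np.quantile(attrs["population_density"], 0.7)
    attrs["urban_rural"] = (attrs["population_density"] > pop_cut).astype(int)
    attrs["admin_level"] = 1 + pd.qcut(attrs["gdp"], 4, labels=False,
                                       duplicates="drop").astype(int)
    area = config.grid.cell_area
    attrs["built_up_area"] = area / (1 + np.exp(-1.5 * z_bu)) * 0.6
    attrs["bus_stop_density"] = np.exp(0.8 * z_bus) * 2.0 / area
    attrs["junction_density"] = np.exp(0.9 * z_jun) * 8.0 / area

    # cities: square blocks of cells, city-level cumulative case count
    b = max(1, config.city_block)
    rcell, ccell = np.divmod(np.arange(n), config.n_cols)
    n_city_cols = -(-config.n_cols // b)
    city = pd.Series((rcell // b) * n_city_cols + (ccell // b), index=idx,
                     name="city_id")
    n_cities = int(city.max()) + 1
    city_cases = pd.Series(
        np.round(np.exp(rng.normal(3.0, 1.2, size=n_cities))).astype(int),
        index=pd.RangeIndex(n_cities, name="city_id"),
        name="cumulative_cases")
    attrs["cumulative_cases"] = broadcast_city_values(city, city_cases)
    attrs["city_id"] = city

    # planted rates: linear in standardized attributes.  Skewed positive
    # fields enter through their logarithm (still monotone in the raw
    # attribute) so the link has Gaussian, not lognormal, tails and the
    # planted rates stay well above -100%.
    log_attrs = {"gdp", "population_density", "built_up_area",
                 "bus_stop_density", "junction_density",
                 "cumulative_cases"}
    z = {}
    for a in ATTRIBUTE_NAMES:
        v = attrs[a].to_numpy(dtype=float)
        if a in log_attrs:
            v = np.log1p(v)
        sd = v.std()
        z[a] = (v - v.mean()) / sd if sd > 0 else np.zeros(n)
    rates = pd.DataFrame(index=idx)
    for period in PERIODS:
        spec = config.effect_spec.get(period, {})
        r = np.full(n, float(spec.get("intercept", 0.0)))
        for a, coef in spec.items():
            if a == "intercept":
                continue
            if a not in z:
                raise ValueError(f"effect_spec references unknown "
                                 f"attribute {a!r}")
            r = r + float(coef) * z[a]
        rates[period] = r
    if not np.isfinite(rates.to_numpy()).all():
        raise ValueError("planted change rates are not finite")

    truth.attributes = attrs
    truth.change_rates = rates
    truth.effects = {p: dict(config.effect_spec.get(p, {})) for p in PERIODS}
    return truth


# ---------------------------------------------------------------------------
# intensity

def diurnal_baseline(n_bins: int = N_BINS) -> np.ndarray:
    """Fixed smooth two-peak (morning/evening) diurnal shape, mean 1.

    The exact shape is irrelevant to the change statistics — only
    window sums enter them — but a realistic curve keeps every window
    sum strictly positive.
    """
    t = (np.arange(n_bins) + 0.5) * 0.5  # bin-center hour
    shape = (0.25
             + 1.0 * np.exp(-0.5 * ((t - 8.5) / 2.0) ** 2)
             + 1.3 * np.exp(-0.5 * ((t - 19.0) / 2.5) ** 2))
    return shape / shape.mean()


def generate_intensity(config: ScenarioConfig,
                       truth: GroundTruth) -> pd.DataFrame:
    """Four 48-bin intensity days per cell with planted change rates.

    Day 1 is the baseline curve scaled by a per-cell amplitude; each
    later day copies day 1 and multiplies the bins inside the cell's
    class window by ``1 + (rate + eps)/100`` where ``rate`` is the
    planted period rate (percent) and ``eps`` is uniform noise with
    standard deviation ``100 * noise_sd`` percentage points.  Realized
    window-sum change rates therefore equal the planted rates exactly
    at ``noise_sd = 0``.
    """
    if truth.change_rates is None:
        raise ValueError("ground truth lacks planted change rates; run "
                         "generate_attributes first")
    rates = truth.change_rates
    if (rates.to_numpy() < -100.0).any():
        raise ValueError("planted rate below -100% would force negative "
                         "intensities")
    rng = np.random.default_rng(config.seed + _OFF_INTENSITY)
    n = config.grid.n_cells
    base_shape = diurnal_baseline()
    policy = WindowPolicy()

    amp = 50.0 * np.exp(
        0.5 * np.log(truth.attributes["population_density"] /
                     truth.attributes["population_density"].mean())
    ).to_numpy() if truth.attributes is not None else np.full(n, 50.0)

    half_width = config.noise_sd * np.sqrt(3.0)  # uniform, SD = noise_sd
    frames = []
    day1 = amp[:, None] * base_shape[None, :]
    labels = truth.labels.to_numpy()
    masks = {l: policy.bin_mask(l) for l in DEFAULT_WINDOWS}
    full_mask = np.ones(N_BINS, dtype=bool)
    for k, day in enumerate(DAY_LABELS):
        if k == 0:
            bins = day1
        else:
            period = PERIODS[k - 1]
            eps = rng.uniform(-half_width, half_width, size=n)
            scale = 1.0 + rates[period].to_numpy() / 100.0 + eps
            if (scale < 0).any():
                raise ValueError("rate noise drives a window scale factor "
                                 "negative; reduce noise_sd")
            bins = day1.copy()
            for i in range(n):
                m = masks.get(labels[i], full_mask)
                bins[i, m] = day1[i, m] * scale[i]
        df = pd.DataFrame(bins, columns=[f"bin_{b}" for b in range(N_BINS)])
        df.insert(0, "day", day)
        df.insert(0, "cell_id", np.arange(n))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# whole scenarios

@dataclass
class Scenario:
    config: ScenarioConfig
    grid: GridDefinition
    pois: pd.DataFrame
    intensity: pd.DataFrame
    truth: GroundTruth


def generate_scenario(config: ScenarioConfig | None = None,
                      **overrides) -> Scenario:
    """Generate a complete scenario: labels, POIs, attributes, planted
    rates and intensity days."""
    config = (config or ScenarioConfig()).replace(**overrides) \
        if overrides else (config or ScenarioConfig())
    truth = plant_labels(config)
    pois, truth = generate_pois(config, truth)
    truth = generate_attributes(config, truth)
    intensity = generate_intensity(config, truth)
    return Scenario(config=config, grid=config.grid, pois=pois,
                    intensity=intensity, truth=truth)
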