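"""Virtual climates, virtual species and presence samples with known truth.

Every pipeline stage can be exercised without downloading occurrence or
climate data: this module builds a smooth, spatially autocorrelated
monthly climate on a lat-lon grid, defines a virtual species whose true
suitability is an analytic Gaussian function of derived bioclim
variables, samples presence points proportional to that truth, and
produces a future climate by a known uniform warming and precipitation
scaling.  Because the truth is analytic, parameter-recovery tests can
ask whether the fitted pipeline reproduces known quantities (e.g. the
sign of the suitable-area change under warming).

The default landscape is a 100 x 100 grid of 0.2 degree cells spanning
latitudes 40-60 N.  Monthly mean temperature follows

    tmean[m] = t_ref - lat_gradient * |lat| + A * cos(2 pi (m - 7) / 12) + noise

(a poleward-cooling gradient with a July-peaked seasonal cycle);
tmin/tmax sit a fixed half-range below/above tmean.  Precipitation has
an analogous structure, clipped at zero.  Noise is seeded white noise
smoothed with a Gaussian kernel, which yields spatial autocorrelation
without heavier geostatistics; the same noise field is shared between
baseline and future so the future differs by exactly the prescribed
uniform shift.

The default virtual species has a Gaussian niche in BIO1 (annual mean
temperature) centred warmer than most of the landscape, so uniform
warming genuinely expands its suitable area -- a known-sign truth for
end-to-end recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .bioclim import MonthlyClimate, derive_bioclim
from .grids import ClimateStack, GridSpec, Layer, write_ascii_grid
from .occurrences import OccurrenceSet


class SyntheticError(ValueError):
    pass


DEFAULT_SPEC = GridSpec(n_rows=100, n_cols=100, x_min=-120.0, y_min=40.0, cell_size=0.2)


@dataclass
class ClimateParams:
    """Knobs of the synthetic climate; temperatures degC, precipitation mm."""

    t_ref: float = 30.0  # tmean at the equator, before seasonality/noise
    lat_gradient: float = 0.6  # degC lost per degree of |latitude|
    seasonal_amplitude: float = 15.0  # July-peaked annual cycle, +-
    diurnal_half_range: float = 5.0  # tmax/tmin = tmean +- this
    temp_noise_sd: float = 1.0
    prec_mean: float = 50.0  # mm/month at the reference latitude
    prec_lat_gradient: float = 1.0  # mm/month gained per degree north of 40N
    prec_seasonal_amplitude: float = 20.0
    prec_noise_sd: float = 10.0
    noise_smooth_sigma: float = 2.0  # cells; spatial autocorrelation scale
    delta_t: float = 3.0  # uniform future warming, degC
    precip_factor: float = 1.1  # uniform future precipitation multiplier


@dataclass
class ClimateScenario:
    baseline: MonthlyClimate
    future: MonthlyClimate
    params: ClimateParams


def _smooth_noise(shape: tuple[int, int], sd: float, sigma: float, rng) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    white = rng.normal(0.0, 1.0, size=shape)
    smooth = gaussian_filter(white, sigma=sigma, mode="nearest")
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def generate_climate(
    spec: GridSpec = DEFAULT_SPEC,
    seed: int = 0,
    params: ClimateParams | None = None,
) -> ClimateScenario:
    """Build seeded baseline and future monthly climatologies on a grid.

    The future equals the baseline plus ``delta_t`` on every monthly
    temperature and times ``precip_factor`` on every monthly
    precipitation, so derived anomalies are exactly known (e.g.
    BIO1_future - BIO1_baseline = delta_t at every cell).
    """
    p = params or ClimateParams()
    rng = np.random.default_rng(seed)
    lats = spec.lat_centers()[:, None] * np.ones((1, spec.n_cols))
    t_noise = _smooth_noise(lats.shape, p.temp_noise_sd, p.noise_smooth_sigma, rng)
    p_noise = _smooth_noise(lats.shape, p.prec_noise_sd, p.noise_smooth_sigma, rng)

    months = np.arange(1, 13)
    t_season = p.seasonal_amplitude * np.cos(2 * np.pi * (months - 7) / 12.0)
    p_season = p.prec_seasonal_amplitude * np.cos(2 * np.pi * (months - 7) / 12.0)

    t_base = p.t_ref - p.lat_gradient * np.abs(lats) + t_noise
    prec_base = p.prec_mean + p.prec_lat_gradient * (lats - 40.0) + p_noise

    tmean = t_base[None] + t_season[:, None, None]
    prec = np.clip(prec_base[None] + p_season[:, None, None], 0.0, None)

    def monthly(tm: np.ndarray, pr: np.ndarray) -> MonthlyClimate:
        return MonthlyClimate(
            spec=spec,
            tmin=tm - p.diurnal_half_range,
            tmax=tm + p.diurnal_half_range,
            prec=pr,
        )

    baseline = monthly(tmean, prec)
    future = monthly(tmean + p.delta_t, prec * p.precip_factor)
    return ClimateScenario(baseline=baseline, future=future, params=p)


@dataclass
class VirtualSpecies:
    """Species with an analytic Gaussian niche in bioclim space.

    True suitability s(x) = exp(-sum_v (v(x) - mu_v)^2 / (2 sigma_v^2)),
    in (0, 1]; cells with s >= ``cutoff`` count as "truly suitable".
    """

    name: str = "virtual_species"
    variables: tuple[str, ...] = ("BIO1", "BIO12")
    optima: tuple[float, ...] = (8.0, 700.0)
    breadths: tuple[float, ...] = (2.5, 400.0)
    cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not (len(self.variables) == len(self.optima) == len(self.breadths)):
            raise SyntheticError("variables, optima and breadths must have equal length")
        if any(s <= 0 for s in self.breadths):
            raise SyntheticError("niche breadths must be positive")

    def suitability(self, stack: ClimateStack) -> Layer:
        """True suitability layer on the stack's grid (nodata propagated)."""
        z = np.zeros((stack.spec.n_rows, stack.spec.n_cols))
        for var, mu, sigma in zip(self.variables, self.optima, self.breadths):
            v = stack[var].values
            z = z + (v - mu) ** 2 / (2.0 * sigma**2)
        return Layer(spec=stack.spec, name="true_suitability", values=np.exp(-z))


def sample_presences(
    sp: VirtualSpecies, stack: ClimateStack, n: int = 500, seed: int = 0
) -> OccurrenceSet:
    """Sample n presence cells with probability proportional to true
    suitability; coordinates are cell centres (sampling is with
    replacement -- per-cell thinning dedupes downstream)."""
    suit = sp.suitability(stack)
    valid = stack.joint_valid_mask() & suit.valid_mask
    rows, cols = np.nonzero(valid)
    weights = suit.values[rows, cols]
    total = weights.sum()
    if not total > 0:
        raise SyntheticError("true suitability is zero on every valid cell")
    rng = np.random.default_rng(seed)
    picks = rng.choice(rows.size, size=n, replace=True, p=weights / total)
    points = [stack.spec.cell_center(int(rows[i]), int(cols[i])) for i in picks]
    return OccurrenceSet(
        species=sp.name, points=points, provenance=f"synthetic (seed={seed})"
    )


def sample_uniform_presences(
    stack: ClimateStack, n: int = 200, seed: int = 0, name: str = "null_species"
) -> OccurrenceSet:
    """Niche-free presences: uniform over valid cells (null calibration)."""
    valid = stack.joint_valid_mask()
    rows, cols = np.nonzero(valid)
    if rows.size == 0:
        raise SyntheticError("no valid cells to sample")
    rng = np.random.default_rng(seed)
    picks = rng.choice(rows.size, size=n, replace=True)
    points = [stack.spec.cell_center(int(rows[i]), int(cols[i])) for i in picks]
    return OccurrenceSet(species=name, points=points, provenance=f"uniform (seed={seed})")


def true_suitable_area(
    sp: VirtualSpecies, stack: ClimateStack, areas: Layer, cutoff: float | None = None
) -> float:
    """km^2 of cells whose true suitability reaches the cutoff."""
    cutoff = sp.cutoff if cutoff is None else cutoff
    suit = sp.suitability(stack)
    mask = stack.joint_valid_mask() & (suit.values >= cutoff)
    return float(areas.values[mask].sum())


def write_workspace(
    out_dir: str | Path,
    spec: GridSpec = DEFAULT_SPEC,
    seed: int = 0,
    n_presences: int = 500,
    params: ClimateParams | None = None,
    species: VirtualSpecies | None = None,
) -> dict:
    """Write a complete ready-to-run study workspace.

    Layout: monthly/<scenario>/{tmin,tmax,prec}_MM.asc, bioclim
    rasters under bioclim/<scenario>/BIO*.asc, occurrences.csv, and a
    truth.yml with the species parameters and true suitable areas.
    Returns a manifest dict (also written as truth.yml).
    """
    import yaml

    from .grids import cell_areas

    out = Path(out_dir)
    sp = species or VirtualSpecies()
    scenario = generate_climate(spec=spec, seed=seed, params=params)
    stacks = {}
    for tag, monthly in (("baseline", scenario.baseline), ("future", scenario.future)):
        mdir = out / "monthly" / tag
        mdir.mkdir(parents=True, exist_ok=True)
        for var in ("tmin", "tmax", "prec"):
            arr = getattr(monthly, var)
            for m in range(12):
                lyr = Layer(spec=spec, name=f"{var}_{m + 1:02d}", values=arr[m])
                write_ascii_grid(lyr, mdir / f"{lyr.name}.asc")
        stack = derive_bioclim(monthly)
        bdir = out / "bioclim" / tag
        bdir.mkdir(parents=True, exist_ok=True)
        for lyr in stack:
            write_ascii_grid(lyr, bdir / f"{lyr.name}.asc")
        stacks[tag] = stack

    occ = sample_presences(sp, stacks["baseline"], n=n_presences, seed=seed)
    occ.to_frame().to_csv(out / "occurrences.csv", index=False)

    # a plausible filled scorecard so the risk/prioritisation stages run
    cards = out / "scorecards"
    cards.mkdir(exist_ok=True)
    (cards / f"{sp.name}.yml").write_text(
        yaml.safe_dump(
            {
                "species": sp.name,
                "answers": {
                    "imp_ecosystem": "major",
                    "imp_community": "severe",
                    "imp_trophic": "moderate",
                    "imp_disturbance": "major",
                    "inv_life_history": "strong",
                    "inv_reproduction": "prolific",
                    "inv_stress_tolerance": "intermediate",
                    "inv_climate_breadth": "intermediate",
                    "inv_competitive": "strong",
                    "inv_allelopathy": "unknown",
                    "inv_soil_alteration": "none",
                    "dsp_long_distance": "high",
                    "dsp_human": "high",
                    "dsp_propagule_pressure": "moderate",
                    "dsp_seed_longevity": "persistent",
                    "dsp_range_expansion": "rapid",
                    "ctl_detection": "moderate",
                    "ctl_eradication": "hard",
                    "ctl_regrowth": "likely",
                    "ctl_nontarget": "unknown",
                    "ctl_cost": "high",
                },
                "notes": "synthetic scorecard for the virtual species",
            },
            sort_keys=False,
        )
    )

    (out / "config.yml").write_text(
        yaml.safe_dump(
            {
                "paths": {
                    "occurrences": "occurrences.csv",
                    "baseline_dir": "bioclim/baseline",
                    "future_dir": "bioclim/future",
                    "scorecards_dir": "scorecards",
                    "out_dir": "outputs",
                },
                "params": {"seed": seed},
            },
            sort_keys=False,
        )
    )

    areas = cell_areas(spec)
    truth = {
        "seed": seed,
        "species": {
            "name": sp.name,
            "variables": list(sp.variables),
            "optima": list(sp.optima),
            "breadths": list(sp.breadths),
            "cutoff": sp.cutoff,
        },
        "true_area_baseline_km2": true_suitable_area(sp, stacks["baseline"], areas),
        "true_area_future_km2": true_suitable_area(sp, stacks["future"], areas),
        "n_presences": n_presences,
    }
    (out / "truth.yml").write_text(yaml.safe_dump(truth, sort_keys=False))
    return truth
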