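"""Derivation of the 19 bioclimatic variables (BIO1..BIO19).

The bioclim variables are the standard ANUCLIM/Worldclim summaries of
monthly temperature and precipitation climatologies: annual means and
extremes, seasonality, and statistics over "quarters", i.e. circular
windows of three consecutive calendar months.  They are the covariate
set used by most climate-envelope species distribution models.

Conventions used here:

* temperatures in deg C, precipitation in mm (no integer x10 packing);
* ``tmean[m] = (tmin[m] + tmax[m]) / 2``;
* BIO4 is the *population* standard deviation of monthly means x100;
* BIO15 is the coefficient of variation of monthly precipitation with
  the mean offset by +1 mm so fully arid cells are defined;
* quarter ties (two windows with equal total precipitation or equal
  mean temperature) resolve to the earliest window in calendar order;
* BIO3 is defined as 0 where the annual range BIO7 is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import ClimateStack, GridError, GridSpec, Layer, read_ascii_grid

MONTHS = range(1, 13)

BIOCLIM_NAMES = {
    "BIO1": "annual mean temperature",
    "BIO2": "mean diurnal range",
    "BIO3": "isothermality (100 BIO2/BIO7)",
    "BIO4": "temperature seasonality (100 sd of monthly means)",
    "BIO5": "max temperature of warmest month",
    "BIO6": "min temperature of coldest month",
    "BIO7": "temperature annual range",
    "BIO8": "mean temperature of wettest quarter",
    "BIO9": "mean temperature of driest quarter",
    "BIO10": "mean temperature of warmest quarter",
    "BIO11": "mean temperature of coldest quarter",
    "BIO12": "annual precipitation",
    "BIO13": "precipitation of wettest month",
    "BIO14": "precipitation of driest month",
    "BIO15": "precipitation seasonality (CV)",
    "BIO16": "precipitation of wettest quarter",
    "BIO17": "precipitation of driest quarter",
    "BIO18": "precipitation of warmest quarter",
    "BIO19": "precipitation of coldest quarter",
}


class MonthlyClimateError(ValueError):
    """Missing months or physically inconsistent monthly layers."""


@dataclass
class MonthlyClimate:
    """Monthly tmin/tmax/prec climatology on one grid.

    Arrays are shaped (12, n_rows, n_cols), index 0 = January.
    """

    spec: GridSpec
    tmin: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tmin", "tmax", "prec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12, self.spec.n_rows, self.spec.n_cols):
                raise MonthlyClimateError(
                    f"{name} must have shape (12, {self.spec.n_rows}, {self.spec.n_cols}), "
                    f"got {arr.shape}"
                )
            setattr(self, name, arr)
        valid = self.valid_mask
        if np.any((self.tmax < self.tmin) & valid[None, :, :].repeat(12, 0) & np.isfinite(self.tmax) & np.isfinite(self.tmin)):
            raise MonthlyClimateError("tmax < tmin on one or more valid cells")
        if np.any(self.prec[np.isfinite(self.prec)] < 0):
            raise MonthlyClimateError("negative monthly precipitation")

    @property
    def tmean(self) -> np.ndarray:
        return (self.tmin + self.tmax) / 2.0

    @property
    def valid_mask(self) -> np.ndarray:
        """Cells with all 36 monthly values present."""
        return (
            np.isfinite(self.tmin).all(axis=0)
            & np.isfinite(self.tmax).all(axis=0)
            & np.isfinite(self.prec).all(axis=0)
        )

    @classmethod
    def from_stack(cls, stack: ClimateStack) -> "MonthlyClimate":
        """Assemble from layers named tmin_01..tmin_12, tmax_*, prec_*."""
        missing = [
            f"{var}_{m:02d}"
            for var in ("tmin", "tmax", "prec")
            for m in MONTHS
            if f"{var}_{m:02d}" not in stack
        ]
        if missing:
            raise MonthlyClimateError(f"missing monthly layer(s): {', '.join(missing)}")
        build = lambda var: np.stack(
            [stack[f"{var}_{m:02d}"].values for m in MONTHS]
        )
        return cls(spec=stack.spec, tmin=build("tmin"), tmax=build("tmax"), prec=build("prec"))

    @classmethod
    def from_directory(cls, directory: str | Path) -> "MonthlyClimate":
        directory = Path(directory)
        layers = []
        for var in ("tmin", "tmax", "prec"):
            for m in MONTHS:
                p = directory / f"{var}_{m:02d}.asc"
                if p.exists():
                    layers.append(read_ascii_grid(p))
        if not layers:
            raise MonthlyClimateError(f"no monthly rasters found in {directory}")
        return cls.from_stack(ClimateStack.from_layers(layers))


def _quarter_stats(tmean: np.ndarray, prec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean temperature and total precipitation of the 12 circular
    three-month windows; window w covers months (w, w+1, w+2) mod 12."""
    qt = np.empty_like(tmean)
    qp = np.empty_like(prec)
    for w in range(12):
        idx = [w, (w + 1) % 12, (w + 2) % 12]
        qt[w] = tmean[idx].mean(axis=0)
        qp[w] = prec[idx].sum(axis=0)
    return qt, qp


def derive_bioclim(monthly: MonthlyClimate) -> ClimateStack:
    """Compute BIO1..BIO19 from a monthly climatology.

    Returns a 19-layer stack on the input grid.  Cells missing any
    monthly value are nodata in every output layer.
    """
    tmean, tmin, tmax, prec = monthly.tmean, monthly.tmin, monthly.tmax, monthly.prec
    qt, qp = _quarter_stats(tmean, prec)

    bio: dict[str, np.ndarray] = {}
    bio["BIO1"] = tmean.mean(axis=0)
    bio["BIO2"] = (tmax - tmin).mean(axis=0)
    bio["BIO4"] = 100.0 * tmean.std(axis=0)
    bio["BIO5"] = tmax.max(axis=0)
    bio["BIO6"] = tmin.min(axis=0)
    bio["BIO7"] = bio["BIO5"] - bio["BIO6"]
    with np.errstate(invalid="ignore", divide="ignore"):
        bio["BIO3"] = np.where(bio["BIO7"] != 0.0, 100.0 * bio["BIO2"] / bio["BIO7"], 0.0)

    # np.argmax/argmin return the first maximal index, which is the
    # earliest calendar window -- the documented tie-break.
    take = lambda arr, idx: np.take_along_axis(arr, idx[None], axis=0)[0]
    wettest = np.argmax(qp, axis=0)
    driest = np.argmin(qp, axis=0)
    warmest = np.argmax(qt, axis=0)
    coldest = np.argmin(qt, axis=0)
    bio["BIO8"] = take(qt, wettest)
    bio["BIO9"] = take(qt, driest)
    bio["BIO10"] = qt.max(axis=0)
    bio["BIO11"] = qt.min(axis=0)

    bio["BIO12"] = prec.sum(axis=0)
    bio["BIO13"] = prec.max(axis=0)
    bio["BIO14"] = prec.min(axis=0)
    bio["BIO15"] = 100.0 * prec.std(axis=0) / (prec.mean(axis=0) + 1.0)
    bio["BIO16"] = qp.max(axis=0)
    bio["BIO17"] = qp.min(axis=0)
    bio["BIO18"] = take(qp, warmest)
    bio["BIO19"] = take(qp, coldest)

    invalid = ~monthly.valid_mask
    layers = []
    for i in range(1, 20):
        name = f"BIO{i}"
        vals = np.asarray(bio[name], dtype=float).copy()
        vals[invalid] = np.nan
        layers.append(Layer(spec=monthly.spec, name=name, values=vals))
    return ClimateStack.from_layers(layers)
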