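"""Reading, cleaning, thinning and splitting species presence records.

Occurrence tables follow the Darwin Core column convention
(``species``, ``decimalLongitude``, ``decimalLatitude``); column names
are matched case-insensitively and the short aliases ``lon``/``lat``
(also ``longitude``/``latitude``) are accepted, since exports from
aggregators vary.  Cleaning drops rows with missing, non-numeric or
out-of-range coordinates and reports the counts; thinning keeps at most
one record per grid cell so a heavily collected locality does not count
many times at the model's spatial grain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import ClimateStack, GridSpec


class OccurrenceError(ValueError):
    """Schema or content problem in an occurrence table."""


_LON_ALIASES = ("decimallongitude", "lon", "longitude", "x")
_LAT_ALIASES = ("decimallatitude", "lat", "latitude", "y")


@dataclass
class CleaningReport:
    n_input: int = 0
    n_kept: int = 0
    drops_missing: int = 0
    drops_out_of_range: int = 0
    n_thinned_duplicates: int = 0
    n_thinned_nodata: int = 0

    def as_text(self) -> str:
        return (
            f"records in: {self.n_input}\n"
            f"records kept: {self.n_kept}\n"
            f"dropped (missing/non-numeric coordinates): {self.drops_missing}\n"
            f"dropped (coordinates out of range): {self.drops_out_of_range}\n"
            f"thinned (duplicate grid cell): {self.n_thinned_duplicates}\n"
            f"thinned (nodata cell): {self.n_thinned_nodata}\n"
        )


@dataclass
class OccurrenceSet:
    """Cleaned presence coordinates for one species."""

    species: str
    points: list[tuple[float, float]]  # (lon, lat), degrees
    provenance: str = ""
    report: CleaningReport = field(default_factory=CleaningReport)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def lons(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)

    def cell_indices(self, spec: GridSpec) -> list[tuple[int, int] | None]:
        return [spec.cell_index(lon, lat) for lon, lat in self.points]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "decimalLongitude": self.lons,
                "decimalLatitude": self.lats,
            }
        )


def _resolve_columns(columns: list[str]) -> tuple[str, str, str | None]:
    lower = {c.lower(): c for c in columns}
    lon = next((lower[a] for a in _LON_ALIASES if a in lower), None)
    lat = next((lower[a] for a in _LAT_ALIASES if a in lower), None)
    if lon is None or lat is None:
        raise OccurrenceError(
            "occurrence table must have decimalLongitude/decimalLatitude "
            f"(or lon/lat) columns; found: {', '.join(columns)}"
        )
    return lon, lat, lower.get("species")


def clean_frame(df: pd.DataFrame, species: str, provenance: str = "") -> OccurrenceSet:
    """Drop rows with unusable coordinates and build an OccurrenceSet."""
    lon_col, lat_col, species_col = _resolve_columns(list(df.columns))
    if species_col is not None and len(df):
        df = df[df[species_col].astype(str) == species]
    report = CleaningReport(n_input=len(df))
    lon = pd.to_numeric(df[lon_col], errors="coerce")
    lat = pd.to_numeric(df[lat_col], errors="coerce")
    present = lon.notna() & lat.notna()
    report.drops_missing = int((~present).sum())
    in_range = present & lon.between(-180, 180) & lat.between(-90, 90)
    report.drops_out_of_range = int((present & ~in_range).sum())
    report.n_kept = int(in_range.sum())
    points = list(zip(lon[in_range].tolist(), lat[in_range].tolist()))
    return OccurrenceSet(species=species, points=points, provenance=provenance, report=report)


def read_occurrences(path: str | Path, species: str) -> OccurrenceSet:
    """Read one species' presences from a Darwin-Core-style CSV."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    occ = clean_frame(df, species=species, provenance=str(path))
    if len(occ) == 0:
        import warnings

        warnings.warn(f"{path}: no usable records for species {species!r}", stacklevel=2)
    return occ


def list_species(path: str | Path) -> list[str]:
    """Distinct species names in a CSV, in first-appearance order."""
    df = pd.read_csv(path, comment="#")
    _, _, species_col = _resolve_columns(list(df.columns))
    if species_col is None:
        raise OccurrenceError(f"{path}: no species column")
    return list(dict.fromkeys(df[species_col].astype(str)))


def thin_to_cells(
    occ: OccurrenceSet, spec: GridSpec, stack: ClimateStack | None = None
) -> OccurrenceSet:
    """Keep the first record per grid cell; drop records off-grid or on
    nodata cells of the stack's joint mask."""
    valid = stack.joint_valid_mask() if stack is not None else None
    seen: set[tuple[int, int]] = set()
    points: list[tuple[float, float]] = []
    report = CleaningReport(n_input=len(occ))
    for lon, lat in occ.points:
        idx = spec.cell_index(lon, lat)
        if idx is None or (valid is not None and not valid[idx]):
            report.n_thinned_nodata += 1
            continue
        if idx in seen:
            report.n_thinned_duplicates += 1
            continue
        seen.add(idx)
        points.append((lon, lat))
    report.n_kept = len(points)
    return OccurrenceSet(
        species=occ.species, points=points, provenance=occ.provenance, report=report
    )


def split_train_test(
    occ: OccurrenceSet, train_fraction: float = 0.75, seed: int = 0
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Uniform random disjoint partition into training and testing sets.

    ``|train| = round(train_fraction * n)`` clamped so that both parts
    are non-empty; the same seed always yields the same member lists.
    """
    n = len(occ)
    if n < 2:
        raise OccurrenceError("need at least 2 records to split")
    if not 0 < train_fraction < 1:
        raise OccurrenceError("train_fraction must be in (0, 1)")
    n_train = int(np.clip(round(train_fraction * n), 1, n - 1))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    mk = lambda idx, tag: OccurrenceSet(
        species=occ.species,
        points=[occ.points[i] for i in idx],
        provenance=f"{occ.provenance} [{tag}]".strip(),
    )
    return mk(train_idx, "train"), mk(test_idx, "test")
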