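"""Grid-cell incidence construction from georeferenced species records.

Survey records — abundance-bearing forest-plot rows or presence-only
occurrence rows — are snapped to 1°x1° latitude/longitude cells, degraded
to presence/absence, and pooled into per-region incidence structures.  A
sampling unit is a grid cell with at least one record; the incidence
frequency ``Y_k`` of species *k* is the number of distinct units it
occupies.  Every downstream estimator consumes only the frequency tallies
derived here.

Cell convention: cell id is ``(floor(lat), floor(lon))``; cells are
lower-left-closed and upper-right-open, so lat −0.0001 falls in cell −1.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ABUNDANCE_COLUMNS = ["species", "lat", "lon", "stems", "plot_id", "region"]
OCCURRENCE_COLUMNS = ["species", "lat", "lon", "region"]

__all__ = [
    "ABUNDANCE_COLUMNS",
    "OCCURRENCE_COLUMNS",
    "EmptyRegionError",
    "GridIncidence",
    "FrequencyCounts",
    "assign_cells",
    "build_incidence",
    "tally_frequencies",
    "normalize_species",
    "read_records",
]


class EmptyRegionError(ValueError):
    """Raised when a region has no usable records (distinct from S_obs = 0)."""


def normalize_species(names: pd.Series) -> pd.Series:
    """Canonicalize species names: whitespace-trim and case-fold only.

    Taxonomic synonym resolution is deliberately not attempted; two
    spellings that differ beyond whitespace/case remain distinct species.
    """
    return names.astype("string").str.strip().str.casefold()


def read_records(path, source: str) -> pd.DataFrame:
    """Read an abundance or occurrence survey table from delimited text.

    ``source`` is ``"abundance"`` (columns species,lat,lon,stems,plot_id,
    region) or ``"occurrence"`` (species,lat,lon,region).
    """
    if source not in ("abundance", "occurrence"):
        raise ValueError(f"unknown source {source!r}")
    df = pd.read_csv(path)
    expected = ABUNDANCE_COLUMNS if source == "abundance" else OCCURRENCE_COLUMNS
    missing = set(expected) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.loc[:, expected].copy()
    df["source"] = source
    return df


def assign_cells(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Snap records to 1° grid cells; reject invalid rows with logged reasons.

    Returns the accepted records with integer ``cell_lat``/``cell_lon``
    columns added, plus a tally of rejection reasons.  Rejected rows
    (coordinates out of range, blank species) are counted and logged,
    never silently dropped.
    """
    df = records.copy()
    rejections = {"bad_lat": 0, "bad_lon": 0, "blank_species": 0}

    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    ok_lat = lat.between(-90.0, 90.0) & lat.notna()
    ok_lon = (lon >= -180.0) & (lon < 180.0) & lon.notna()
    species = normalize_species(df["species"])
    ok_sp = species.notna() & (species.str.len() > 0)

    rejections["bad_lat"] = int((~ok_lat).sum())
    rejections["bad_lon"] = int((ok_lat & ~ok_lon).sum())
    rejections["blank_species"] = int((ok_lat & ok_lon & ~ok_sp).sum())

    keep = ok_lat & ok_lon & ok_sp
    df = df.loc[keep].copy()
    df["species"] = species.loc[keep]
    df["cell_lat"] = np.floor(lat.loc[keep]).astype(int)
    df["cell_lon"] = np.floor(lon.loc[keep]).astype(int)

    n_rej = sum(rejections.values())
    if n_rej:
        logger.warning("assign_cells: rejected %d of %d records (%s)",
                       n_rej, len(records), rejections)
    logger.info("assign_cells: accepted %d records in %d cells",
                len(df), df.groupby(["cell_lat", "cell_lon"]).ngroups if len(df) else 0)
    return df, rejections


@dataclass
class GridIncidence:
    """Per-region incidence summary over grid-cell sampling units.

    ``T`` is the number of sampling units (cells with ≥1 record) and
    ``incidence`` maps each species to its incidence frequency Y_k, the
    number of distinct cells it occupies (1 ≤ Y_k ≤ T).  ``cell_species``
    retains the full cell → species-set membership so that unit-level
    resampling (bootstrap bands) and multi-region pooling stay possible.
    """

    region: str
    T: int
    incidence: dict[str, int]
    cell_species: dict[object, frozenset] = field(default_factory=dict, repr=False)

    @property
    def s_obs(self) -> int:
        return len(self.incidence)

    def y_values(self) -> np.ndarray:
        return np.asarray(sorted(self.incidence.values()), dtype=int)


def build_incidence(records: pd.DataFrame, region: str) -> GridIncidence:
    """Pool cell-assigned records of one region into a GridIncidence.

    Abundance records are degraded to presence: a species x cell pair
    counts once no matter how many records (from either source) support
    it, so the operation is idempotent under re-application.
    """
    if "cell_lat" not in records.columns:
        raise ValueError("records lack cell ids; call assign_cells first")
    sub = records.loc[records["region"] == region]
    if sub.empty:
        raise EmptyRegionError(f"region {region!r} has no records")

    cell_species: dict[object, frozenset] = {
        cell: frozenset(grp["species"])
        for cell, grp in sub.groupby(["cell_lat", "cell_lon"])
    }
    incidence: dict[str, int] = {}
    for members in cell_species.values():
        for sp in members:
            incidence[sp] = incidence.get(sp, 0) + 1
    inc = GridIncidence(region=region, T=len(cell_species),
                        incidence=incidence, cell_species=cell_species)
    logger.info("build_incidence[%s]: T=%d units, S_obs=%d, presences=%d",
                region, inc.T, inc.s_obs, sum(incidence.values()))
    return inc


@dataclass(frozen=True)
class FrequencyCounts:
    """The low-order frequency tallies every richness estimator consumes.

    Incidence mode: ``q1..q4`` count species present in exactly 1
    (unique), 2 (duplicate), 3 (triplicate), 4 (quadruplicate) sampling
    units; ``T`` is the number of units and ``n`` the total number of
    species x unit presences.  Abundance mode: ``q1..q4`` are read as
    f1..f4 — species with exactly 1 (singleton), 2 (doubleton), 3, 4
    individuals; ``T`` is None and ``n`` the total individuals.
    """

    mode: str  # "incidence" | "abundance"
    n: int
    s_obs: int
    q1: int
    q2: int
    q3: int
    q4: int
    T: int | None = None

    def __post_init__(self):
        if self.mode not in ("incidence", "abundance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "incidence" and self.T is None:
            raise ValueError("incidence-mode counts require T")
        if min(self.q1, self.q2, self.q3, self.q4) < 0:
            raise ValueError("negative frequency tally")
        if self.q1 + self.q2 + self.q3 + self.q4 > self.s_obs:
            raise ValueError("tallies exceed S_obs")

    # abundance-mode vocabulary
    @property
    def f1(self) -> int:
        return self.q1

    @property
    def f2(self) -> int:
        return self.q2

    @property
    def f3(self) -> int:
        return self.q3

    @property
    def f4(self) -> int:
        return self.q4


def tally_frequencies(
    data: GridIncidence | Iterable[int] | Mapping[str, int],
    mode: str | None = None,
) -> FrequencyCounts:
    """Tally Q1–Q4 (incidence) or f1–f4 (abundance) from raw frequencies.

    Accepts a :class:`GridIncidence` (incidence mode), or a vector /
    species→count mapping of per-species frequencies.  For a bare vector
    the mode must be given explicitly; for incidence vectors ``T`` is
    taken as ``max(Y)`` unless the input is a GridIncidence.
    """
    if isinstance(data, GridIncidence):
        values = np.asarray(list(data.incidence.values()), dtype=int)
        mode = "incidence"
        T = data.T
    else:
        if isinstance(data, Mapping):
            values = np.asarray(list(data.values()), dtype=int)
        else:
            values = np.asarray(list(data), dtype=int)
        if mode is None:
            raise ValueError("mode required for bare frequency vectors")
        T = int(values.max()) if (mode == "incidence" and values.size) else None
    if values.size == 0:
        raise ValueError("empty frequency input")
    if (values < 1).any():
        raise ValueError("frequencies must be >= 1")

    counts = np.bincount(values, minlength=5)
    return FrequencyCounts(
        mode=mode,
        n=int(values.sum()),
        s_obs=int(values.size),
        q1=int(counts[1]),
        q2=int(counts[2]),
        q3=int(counts[3]),
        q4=int(counts[4]),
        T=T,
    )
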