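"""Synthetic multi-region tree communities and survey datasets.

Generates the statistical structure the richness estimators assume —
log-series species-abundance distributions per region, spatially
clustered species ranges that yield long-tailed incidence-frequency
distributions, configurable cross-region species sharing, and a
misidentification process that splits one species' records into spurious
names ("false uniques") — so the whole pipeline can be exercised against
known ground truth.

Geography is a stylized square lattice of 1°x1° cells per region, with
regions laid out in disjoint longitude bands so their sampling units can
never collide.  No attempt is made to emulate real plot networks, biome
geometry, or climate; only the frequency structure the estimators
consume.

Seeding: one root seed in the config; every stochastic operation derives
an independent child stream from (root seed, operation name, region), so
each operation is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._util import child_rng

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "sample_abundance_survey",
    "sample_occurrence_survey",
    "inject_misidentification",
    "logseries_pmf",
    "sample_logseries_counts",
    "write_surveys",
]


# ---------------------------------------------------------------------------
# log-series draws


def logseries_pmf(x: float, tail: float = 1e-12) -> np.ndarray:
    """Log-series pmf P(k) = x^k / (-k ln(1-x)) on support truncated where
    the remaining tail mass drops below ``tail``."""
    if not 0.0 < x < 1.0:
        raise ValueError("log-series parameter x must be in (0, 1)")
    size = 1024
    norm = -np.log1p(-x)
    while True:
        k = np.arange(1, size + 1, dtype=float)
        pmf = np.exp(k * np.log(x) - np.log(k)) / norm
        if 1.0 - pmf.sum() < tail or size > 50_000_000:
            return pmf
        size *= 4


def sample_logseries_counts(
    alpha: float, n_individuals: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one log-series community sample as a species-abundance vector.

    Uses the Poisson representation of Fisher's model: the number of
    species with abundance k is Poisson(alpha * x^k / k) independently,
    with x = n/(n + alpha).  The expected number of distinct species is
    exactly alpha * ln(1 + n/alpha) and the expected total count is n.
    """
    x = n_individuals / (n_individuals + alpha)
    pmf = logseries_pmf(x)
    means = alpha * (-np.log1p(-x)) * pmf  # = alpha * x^k / k
    counts = rng.poisson(means)
    ks = np.nonzero(counts)[0] + 1
    return np.repeat(ks, counts[counts > 0]).astype(int)


def _draw_logseries_abundances(
    x: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """iid abundance-class draws by inverse CDF on the truncated support."""
    cdf = np.cumsum(logseries_pmf(x))
    u = rng.random(size)
    return np.searchsorted(cdf, u, side="left") + 1


# ---------------------------------------------------------------------------
# configuration and world


@dataclass
class WorldConfig:
    """Parameters of one synthetic multi-region world.

    ``sharing_matrix[i, j]`` is the fraction of the smaller of the two
    regional pools shared between regions i and j (symmetric, unit
    diagonal).  ``range_clustering`` scales how many cells a species
    occupies (smaller → spatially rarer); range size grows with regional
    abundance.  ``detection_prob`` drives the presence-only survey,
    ``misid_rate`` the false-unique injection.
    """

    regions: list[str]
    pool_size_per_region: int = 400
    fisher_alpha_per_region: float = 30.0
    total_individuals_per_region: int = 30_000
    sharing_matrix: np.ndarray | None = None
    grid_extent_per_region: int = 12
    plots_per_cell: int = 2
    range_clustering: float = 1.0
    detection_prob: float = 0.7
    misid_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        r = len(self.regions)
        if r == 0 or len(set(self.regions)) != r:
            raise ValueError("regions must be nonempty and unique")
        if self.sharing_matrix is None:
            self.sharing_matrix = np.eye(r)
        self.sharing_matrix = np.asarray(self.sharing_matrix, dtype=float)
        m = self.sharing_matrix
        if m.shape != (r, r):
            raise ValueError("sharing_matrix shape must match regions")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
            raise ValueError("sharing_matrix must be symmetric with unit diagonal")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("sharing_matrix entries must lie in [0, 1]")
        if min(self.pool_size_per_region, self.total_individuals_per_region,
               self.grid_extent_per_region) < 1:
            raise ValueError("pool size, individuals, and grid extent must be >= 1")
        if self.plots_per_cell < 0:
            raise ValueError("plots_per_cell must be >= 0")
        if self.fisher_alpha_per_region <= 0 or self.range_clustering <= 0:
            raise ValueError("fisher alpha and range_clustering must be > 0")
        if not 0.0 < self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in (0, 1]")
        if not 0.0 <= self.misid_rate < 1.0:
            raise ValueError("misid_rate must be in [0, 1)")
        # shared species requested from each region may not exceed its pool
        pool = self.pool_size_per_region
        for i in range(r):
            requested = sum(
                int(round(m[i, j] * pool)) for j in range(r) if j != i
            )
            if requested > pool:
                raise ValueError(
                    f"region {self.regions[i]!r}: sharing_matrix requests "
                    f"{requested} shared species but the pool holds {pool}"
                )

    def region_origin(self, region: str) -> tuple[int, int]:
        """(lat, lon) of the region's grid corner; disjoint longitude bands."""
        i = self.regions.index(region)
        span = self.grid_extent_per_region + 2
        lon0 = -180 + i * span
        if lon0 + self.grid_extent_per_region > 180:
            raise ValueError("too many regions / too wide a grid for the longitude range")
        return 0, lon0

    def region_cells(self, region: str) -> list[tuple[int, int]]:
        lat0, lon0 = self.region_origin(region)
        g = self.grid_extent_per_region
        return [(lat0 + a, lon0 + b) for a in range(g) for b in range(g)]


@dataclass
class SyntheticWorld:
    """One realized world: species pools, abundance weights, range maps.

    ``species`` maps region → species names; ``weights`` the matching
    relative-abundance vectors; ``ranges`` maps (region, species) → the
    frozenset of occupied grid cells.  Ground truth for recovery tests
    comes from :meth:`true_richness`.
    """

    config: WorldConfig
    species: dict[str, list[str]]
    weights: dict[str, np.ndarray]
    abundance_class: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    ranges: dict[tuple[str, str], frozenset] = field(repr=False, default_factory=dict)

    def true_richness(self, regions: list[str] | None = None) -> int:
        """True richness of a region subset: size of the pooled species union."""
        regions = list(self.config.regions) if regions is None else list(regions)
        pool: set[str] = set()
        for r in regions:
            pool.update(self.species[r])
        return len(pool)

    def truth_summary(self) -> dict:
        """True richness for every nonempty region subset, JSON-serializable."""
        labels = self.config.regions
        out = {}
        for k in range(1, len(labels) + 1):
            for combo in combinations(labels, k):
                out["+".join(combo)] = self.true_richness(list(combo))
        return out


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Realize species pools, log-series abundance weights, and ranges.

    Shared species are allocated pairwise from the sharing matrix; the
    remainder of each pool is endemic.  Each species' regional abundance
    class is an iid inverse-CDF log-series draw at the configured alpha;
    its range is a compact blob of the nearest cells around a uniformly
    drawn center, sized proportionally to sqrt(abundance) so that common
    species are widespread and the incidence tail stays unique-rich.
    """
    labels = config.regions
    m = config.sharing_matrix
    pool = config.pool_size_per_region

    species: dict[str, list[str]] = {r: [] for r in labels}
    for i, j in combinations(range(len(labels)), 2):
        n_shared = int(round(m[i, j] * pool))
        for s in range(n_shared):
            # casefolded to be invariant under ingest name normalization
            name = f"shared_{labels[i]}_{labels[j]}_{s:05d}".casefold()
            species[labels[i]].append(name)
            species[labels[j]].append(name)
    for r in labels:
        n_endemic = pool - len(species[r])
        species[r].extend(
            f"{r}_endemic_{s:05d}".casefold() for s in range(n_endemic)
        )

    world = SyntheticWorld(config=config, species=species, weights={})
    n_cells = config.grid_extent_per_region**2
    x = config.total_individuals_per_region / (
        config.total_individuals_per_region + config.fisher_alpha_per_region
    )
    for r in labels:
        rng_ab = child_rng(config.seed, "abundances", r)
        classes = _draw_logseries_abundances(x, pool, rng_ab)
        world.abundance_class[r] = classes
        world.weights[r] = classes / classes.sum()

        rng_rg = child_rng(config.seed, "ranges", r)
        cells = np.asarray(config.region_cells(r))
        for sp, k in zip(species[r], classes):
            # 1 + sqrt(k): at default clustering even the rarest species get
            # two occupiable cells, so uniques arise from incomplete detection
            # (the sampling process Chao2 models) rather than from genuinely
            # single-cell ranges; sub-unity clustering can still force size 1.
            target = int(min(n_cells, max(1, round(config.range_clustering
                                                   * (1.0 + np.sqrt(k))))))
            center = cells[rng_rg.integers(0, n_cells)]
            d2 = ((cells - center) ** 2).sum(axis=1)
            order = np.lexsort((cells[:, 1], cells[:, 0], d2))
            chosen = cells[order[:target]]
            world.ranges[(r, sp)] = frozenset(map(tuple, chosen))
    return world


# ---------------------------------------------------------------------------
# surveys

_ABUND_COLS = ["species", "lat", "lon", "stems", "plot_id", "region"]
_OCC_COLS = ["species", "lat", "lon", "region"]


def sample_abundance_survey(
    world: SyntheticWorld, config: WorldConfig | None = None
) -> pd.DataFrame:
    """Plot-based stem counts: the forest-inventory style survey.

    Places ``plots_per_cell`` plots uniformly inside every cell, divides
    each region's individual budget evenly over the plots whose cell is
    covered by at least one species' range, and draws each plot's stems
    multinomially over the covering species' abundance weights.  Total
    stems per region equal the configured budget exactly.
    """
    config = world.config if config is None else config
    rows = []
    for r in config.regions:
        if config.plots_per_cell == 0:
            continue
        rng = child_rng(config.seed, "abundance_survey", r)
        sp_names = world.species[r]
        weights = world.weights[r]
        cover: dict[tuple[int, int], list[int]] = {}
        for idx, sp in enumerate(sp_names):
            for cell in world.ranges[(r, sp)]:
                cover.setdefault(cell, []).append(idx)

        plots = []
        for cell in config.region_cells(r):
            if cell not in cover:
                continue
            for p in range(config.plots_per_cell):
                u, v = rng.random(2)
                plots.append((cell, cell[0] + u, cell[1] + v))
        if not plots:
            continue
        n_plots = len(plots)
        budget = config.total_individuals_per_region
        base, extra = divmod(budget, n_plots)
        for p_idx, (cell, plat, plon) in enumerate(plots):
            n_here = base + (1 if p_idx < extra else 0)
            if n_here == 0:
                continue
            members = cover[cell]
            w = weights[members]
            stems = rng.multinomial(n_here, w / w.sum())
            plot_id = f"{r}_plot_{p_idx:05d}"
            for m_idx, s in zip(members, stems):
                if s > 0:
                    rows.append((sp_names[m_idx], plat, plon, int(s), plot_id, r))
    df = pd.DataFrame(rows, columns=_ABUND_COLS)
    df["source"] = "abundance"
    return df


def sample_occurrence_survey(
    world: SyntheticWorld, config: WorldConfig | None = None
) -> pd.DataFrame:
    """Presence-only records: each species x occupied-cell pair is
    reported with probability ``detection_prob``; coordinates are the
    cell center; no stem counts."""
    config = world.config if config is None else config
    rows = []
    for r in config.regions:
        rng = child_rng(config.seed, "occurrence_survey", r)
        for sp in world.species[r]:
            for cell in sorted(world.ranges[(r, sp)]):
                if rng.random() < config.detection_prob:
                    rows.append((sp, cell[0] + 0.5, cell[1] + 0.5, r))
    df = pd.DataFrame(rows, columns=_OCC_COLS)
    df["source"] = "occurrence"
    return df


def inject_misidentification(
    records: pd.DataFrame, misid_rate: float, seed: int
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Split a fraction of multi-cell species into spurious names.

    For ``misid_rate`` of the species occurring in ≥ 2 sampling units
    (1° cells), all records in one randomly chosen unit are relabeled to
    a new spurious name — e.g. a duplicate becomes two false uniques.
    Acting at the unit level (not per record) matches the error process
    the true-uniques adjustment corrects.  Returns the corrupted records
    and the spurious → true name map as ground truth.
    """
    if not 0.0 <= misid_rate < 1.0:
        raise ValueError("misid_rate must be in [0, 1)")
    if records.empty:
        raise ValueError("no records to corrupt")
    out = records.copy()
    if misid_rate == 0.0:
        return out, {}

    rng = child_rng(seed, "misidentification")
    cell_lat = np.floor(out["lat"].to_numpy()).astype(int)
    cell_lon = np.floor(out["lon"].to_numpy()).astype(int)
    cells = pd.Series(
        [f"{a}:{b}" for a, b in zip(cell_lat, cell_lon)], index=out.index
    )

    by_species = out.groupby("species").groups
    eligible = sorted(
        sp for sp, idx in by_species.items() if cells.loc[idx].nunique() >= 2
    )
    n_split = int(round(misid_rate * len(eligible)))
    chosen = rng.choice(len(eligible), size=n_split, replace=False)
    mapping: dict[str, str] = {}
    for k, ei in enumerate(sorted(chosen)):
        sp = eligible[ei]
        idx = by_species[sp]
        occupied = sorted(cells.loc[idx].unique())
        victim = occupied[rng.integers(0, len(occupied))]
        spurious = f"{sp}__pseudo_{k:04d}"
        hit = idx[(cells.loc[idx] == victim).to_numpy()]
        out.loc[hit, "species"] = spurious
        mapping[spurious] = sp
    return out, mapping


def write_surveys(
    abundance: pd.DataFrame,
    occurrence: pd.DataFrame,
    world: SyntheticWorld,
    outdir,
    misid_map: dict[str, str] | None = None,
) -> dict[str, str]:
    """Write the two survey CSVs plus a ground-truth JSON sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": str(outdir / "abundance_survey.csv"),
        "occurrence": str(outdir / "occurrence_survey.csv"),
        "truth": str(outdir / "ground_truth.json"),
    }
    abundance.loc[:, _ABUND_COLS].to_csv(paths["abundance"], index=False)
    occurrence.loc[:, _OCC_COLS].to_csv(paths["occurrence"], index=False)
    truth = {
        "seed": world.config.seed,
        "true_richness": world.truth_summary(),
        "misidentification_map": misid_map or {},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
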