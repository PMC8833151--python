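"""Shared fixtures and toy-data builders for the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import treerich as tr
from treerich.grid import FrequencyCounts, GridIncidence, assign_cells, build_incidence

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def incidence_from_cells(cells, region: str = "toy") -> GridIncidence:
    """Build a GridIncidence from explicit per-unit species sets."""
    cell_species = {(0, i): frozenset(m) for i, m in enumerate(cells)}
    incidence: dict[str, int] = {}
    for members in cell_species.values():
        for sp in members:
            incidence[sp] = incidence.get(sp, 0) + 1
    return GridIncidence(region=region, T=len(cells),
                         incidence=incidence, cell_species=cell_species)


def make_counts(s_obs, T, q1, q2, q3=0, q4=0, n=None, mode="incidence"):
    """FrequencyCounts with an explicit tally (n defaults to a consistent value)."""
    if n is None:
        # smallest consistent total: tallied species plus the rest at freq 5
        rest = s_obs - (q1 + q2 + q3 + q4)
        n = q1 + 2 * q2 + 3 * q3 + 4 * q4 + 5 * rest
    return FrequencyCounts(mode=mode, n=n, s_obs=s_obs,
                           q1=q1, q2=q2, q3=q3, q4=q4,
                           T=T if mode == "incidence" else None)


def surveyed_incidence(seed: int, regions=("A",), **world_kwargs):
    """Generate a world, run both surveys, and build per-region incidence."""
    cfg = tr.WorldConfig(regions=list(regions), seed=seed, **world_kwargs)
    world = tr.generate_world(cfg)
    frames = [tr.sample_abundance_survey(world), tr.sample_occurrence_survey(world)]
    records = pd.concat([f for f in frames if not f.empty], ignore_index=True)
    records, _ = assign_cells(records)
    incs = {r: build_incidence(records, r) for r in regions}
    return world, records, incs


@pytest.fixture(scope="session")
def small_world():
    """One deterministic single-region world with its surveys."""
    return surveyed_incidence(seed=42)


@pytest.fixture(scope="session")
def toy_incidence():
    """5 units, 6 species, mixed frequencies (exact enumeration tractable)."""
    return incidence_from_cells([
        {"a", "b", "c"},
        {"a", "b", "d"},
        {"a", "e"},
        {"a", "b"},
        {"f"},
    ])
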