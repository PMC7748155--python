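"""Shared fixtures: hand-built micro landscapes and a session-scoped
synthetic environment."""

from __future__ import annotations

import numpy as np
import pytest

from emdisc.landscape import Landscape, Occupancy, WaterSource
from emdisc.rules import DecisionContext, FactorConfig
from emdisc.synth import SyntheticEnvSpec, generate_synthetic_environment


def make_landscape(
    quality,
    zone=None,
    water_body=None,
    yield_table=None,
    water_sources=None,
    target=None,
    start_year=800,
):
    """Build a small Landscape from a quality grid and optional layers."""
    quality = np.asarray(quality, dtype=float)
    h, w = quality.shape
    zone = np.zeros((h, w), dtype=int) if zone is None else np.asarray(zone)
    water_body = (
        np.zeros((h, w), dtype=bool) if water_body is None else np.asarray(water_body, dtype=bool)
    )
    if target is None:
        target = [1, 1, 1]
    n_years = len(target)
    n_zones = int(zone.max()) + 1
    if yield_table is None:
        yield_table = np.full((n_zones, n_years), 800.0)
    if water_sources is None:
        water_sources = [WaterSource(0, 0, start_year, start_year + n_years - 1)]
    return Landscape(
        width=w,
        height=h,
        quality=quality,
        zone=zone,
        water_body=water_body,
        yield_table=np.asarray(yield_table, dtype=float),
        water_sources=water_sources,
        target_series=np.asarray(target),
        start_year=start_year,
        end_year=start_year + n_years - 1,
    )


def make_context(
    landscape,
    candidates,
    ref_farm=(0, 0),
    ref_dwelling=(0, 0),
    ref_zone=None,
    ref_age=10.0,
    ref_stock=100.0,
    decider_id=None,
    households=(),
    config=None,
    year=None,
    last_yield=None,
    available=None,
):
    """Build a DecisionContext from plain data.

    ``households`` is a sequence of (id, (x, y), age, stock) tuples.
    """
    hh = list(households)
    ids = np.array([h[0] for h in hh], dtype=np.int64)
    dwellings = np.array([h[1] for h in hh], dtype=np.int64).reshape(-1, 2)
    ages = np.array([h[2] for h in hh], dtype=float)
    stocks = np.array([h[3] for h in hh], dtype=float)
    if available is None:
        available = ~landscape.water_body
    return DecisionContext(
        landscape=landscape,
        year=landscape.start_year if year is None else year,
        ref_farm=tuple(ref_farm),
        ref_dwelling=tuple(ref_dwelling),
        ref_zone=(
            int(landscape.zone[ref_farm[1], ref_farm[0]]) if ref_zone is None else ref_zone
        ),
        ref_age=ref_age,
        ref_stock=ref_stock,
        decider_id=decider_id,
        hh_ids=ids,
        hh_dwellings=dwellings,
        hh_ages=ages,
        hh_stocks=stocks,
        family_ids=frozenset(),
        available=np.asarray(available, dtype=bool),
        last_yield=last_yield,
        candidates=np.asarray(candidates, dtype=np.int64).reshape(-1, 2),
        config=config or FactorConfig(),
    )


def random_context(rng, n_households=None, size=6):
    """A small fuzzed decision context for oracle-equivalence tests."""
    quality = rng.random((size, size))
    zone = rng.integers(0, 3, size=(size, size))
    water_body = rng.random((size, size)) < 0.1
    n_years = 3
    yields = rng.uniform(100, 1000, size=(3, n_years))
    sources = [
        WaterSource(int(rng.integers(size)), int(rng.integers(size)), 800, 802)
        for _ in range(rng.integers(1, 4))
    ]
    ls = make_landscape(
        quality, zone=zone, water_body=water_body, yield_table=yields,
        water_sources=sources, target=[1] * n_years,
    )
    free = np.argwhere(~water_body)  # rows of (y, x)
    if len(free) == 0:
        water_body[0, 0] = False
        free = np.array([[0, 0]])
    k = int(rng.integers(1, min(len(free), 12) + 1))
    pick = rng.choice(len(free), size=k, replace=False)
    candidates = free[pick][:, ::-1]  # -> (x, y)

    m = int(rng.integers(0, 6)) if n_households is None else n_households
    households = [
        (i, (int(rng.integers(size)), int(rng.integers(size))),
         float(rng.uniform(0, 40)), float(rng.uniform(0, 500)))
        for i in range(m)
    ]
    fx, fy = int(rng.integers(size)), int(rng.integers(size))
    last_yield = rng.uniform(0, 600, size=(size, size)) * (rng.random((size, size)) < 0.5)
    return make_context(
        ls,
        candidates,
        ref_farm=(fx, fy),
        ref_dwelling=(fx, fy),
        ref_age=float(rng.uniform(0, 40)),
        ref_stock=float(rng.uniform(0, 500)),
        decider_id=0 if (m and rng.random() < 0.5) else None,
        households=households,
        year=800 + int(rng.integers(n_years)),
        last_yield=last_yield,
    )


@pytest.fixture(scope="session")
def small_env():
    """Default-condition synthetic environment planted with argmax(F_Qual)."""
    return generate_synthetic_environment(SyntheticEnvSpec(seed=1))


@pytest.fixture(scope="session")
def small_env_spec():
    return SyntheticEnvSpec(seed=1)
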