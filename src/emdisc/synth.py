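"""Synthetic environment generator.

The historical valley inputs (terrain quality, drought-adjusted yields, water
sources, excavated household counts) are not bundled with this package, so
experiments run on generated stand-ins that reproduce their structure: a
multi-zone grid with a spatially autocorrelated quality field and water-body
blobs, per-zone year-varying baseline yields, sparse water sources with
active year ranges, and a target household-count series that is *planted* —
it is the trajectory of one seeded simulation run under a known generating
rule, so rule-recovery experiments have a ground truth.

Generation is a pure function of the spec (seed included); the same spec
yields byte-identical environment files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .abm import InitConfig, SimulationParams, SimulationResult, run_simulation
from .landscape import Landscape, WaterSource
from .rules import FactorConfig, RuleTree, parse_rule

__all__ = [
    "SyntheticEnvSpec",
    "DegenerateEnvironmentError",
    "generate_synthetic_environment",
    "replay_planted_run",
]


class DegenerateEnvironmentError(ValueError):
    """The planted run collapsed too early to yield a usable target series."""


@dataclass(frozen=True)
class SyntheticEnvSpec:
    """Specification of a synthetic environment.

    Defaults are the package's desk-scale study conditions: a 20x20 grid with
    four zones over a 40-year span and ten founding households. Yields
    average 500 kg/cell/yr, which with the default harvest adjustment makes
    plots below roughly median quality unable to cover a household's annual
    need, and the quality field decorrelates over ~2 cells — together these
    make the farm-selection rule consequential (a household's growth depends
    on the land it picks, and good land is not simply whatever lies nearest).

    quality_corr_length
        Gaussian smoothing length (cells) of the soil-quality random field.
    yield_mean, zone_yield_sd
        Mean baseline yield and the between-zone spread of zone means.
    yield_temporal_sd
        Year-to-year (per-zone, independent) yield fluctuation.
    yield_drift
        Linear trend in yields (kg/cell/yr per year); 0 keeps the climate
        stationary.
    water_source_density
        Expected water sources per cell. One source is always active for the
        whole span so the valley never becomes uninhabitable by construction.
    planted_rule
        Canonical rule string whose seeded run produces the target series.
    """

    width: int = 20
    height: int = 20
    n_zones: int = 4
    quality_corr_length: float = 2.0
    water_body_frac: float = 0.06
    yield_mean: float = 500.0
    zone_yield_sd: float = 40.0
    yield_temporal_sd: float = 50.0
    yield_drift: float = 0.0
    water_source_density: float = 0.015
    start_year: int = 800
    n_years: int = 40
    init_households: int = 10
    planted_rule: str = "argmax[S_All](F_Qual)"
    params: SimulationParams = field(default_factory=SimulationParams)
    factor_config: FactorConfig = field(default_factory=FactorConfig)
    seed: int = 0

    def __post_init__(self):
        for name in ("quality_corr_length", "water_body_frac", "zone_yield_sd",
                     "yield_temporal_sd", "water_source_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def end_year(self) -> int:
        return self.start_year + self.n_years - 1

    def planted_run_seed(self) -> list[int]:
        """Seed of the planted target-generating simulation run."""
        return [self.seed, 0x5EED]

    def rule(self) -> RuleTree:
        return parse_rule(self.planted_rule)


def _terrain(spec: SyntheticEnvSpec, rng: np.random.Generator):
    shape = (spec.height, spec.width)

    def smooth_field() -> np.ndarray:
        noise = rng.normal(size=shape)
        f = ndimage.gaussian_filter(noise, sigma=spec.quality_corr_length, mode="nearest")
        lo, hi = f.min(), f.max()
        return (f - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)

    quality = smooth_field()
    wet = smooth_field()
    if spec.water_body_frac > 0:
        thr = np.quantile(wet, spec.water_body_frac)
        water_body = wet <= thr
    else:
        water_body = np.zeros(shape, dtype=bool)

    # Contiguous vertical bands of roughly equal width.
    xs = np.arange(spec.width)
    zone_row = (xs * spec.n_zones) // spec.width
    zone = np.tile(zone_row, (spec.height, 1)).astype(np.int64)
    return quality, water_body, zone


def _yields(spec: SyntheticEnvSpec, rng: np.random.Generator) -> np.ndarray:
    zone_means = rng.normal(spec.yield_mean, spec.zone_yield_sd, size=spec.n_zones)
    t = np.arange(spec.n_years)
    noise = rng.normal(0.0, spec.yield_temporal_sd, size=(spec.n_zones, spec.n_years))
    table = zone_means[:, None] + spec.yield_drift * t[None, :] + noise
    return np.clip(table, 0.0, None)


def _water_sources(spec: SyntheticEnvSpec, rng: np.random.Generator) -> list[WaterSource]:
    n = max(1, round(spec.water_source_density * spec.width * spec.height))
    sources = []
    for i in range(n):
        x = int(rng.integers(0, spec.width))
        y = int(rng.integers(0, spec.height))
        if i == 0 or rng.random() < 0.5:
            start, end = spec.start_year, spec.end_year
        else:
            a, b = sorted(rng.integers(spec.start_year, spec.end_year + 1, size=2))
            start, end = int(a), int(b)
        sources.append(WaterSource(x, y, start, end))
    # Canonical order, matching the file writer.
    return sorted(sources, key=lambda s: (s.x, s.y, s.start_year))


def generate_synthetic_environment(spec: SyntheticEnvSpec) -> Landscape:
    """Generate a landscape whose target series comes from the planted rule.

    The target household-count trajectory is produced by one simulation run
    of the planted rule, seeded by ``spec.planted_run_seed()`` with
    ``spec.params``; re-running :func:`emdisc.abm.run_simulation` with the
    same rule, params and seed on the result therefore scores RMSE 0 (see
    :func:`replay_planted_run`).

    Raises :class:`DegenerateEnvironmentError` if the planted population
    collapses to zero before 10% of the span has elapsed.
    """
    rng = np.random.default_rng([spec.seed, 0xE4])
    quality, water_body, zone = _terrain(spec, rng)
    yield_table = _yields(spec, rng)
    sources = _water_sources(spec, rng)

    # Provisional target: constant placeholder while the planted run executes.
    landscape = Landscape(
        width=spec.width,
        height=spec.height,
        quality=quality,
        zone=zone,
        water_body=water_body,
        yield_table=yield_table,
        water_sources=sources,
        target_series=np.full(spec.n_years, spec.init_households, dtype=np.int64),
        start_year=spec.start_year,
        end_year=spec.end_year,
    )
    result = run_simulation(
        landscape,
        spec.params,
        spec.rule(),
        init=InitConfig(count=spec.init_households),
        rng=np.random.default_rng(spec.planted_run_seed()),
        factor_config=spec.factor_config,
    )
    counts = np.array([result.counts[y] for y in landscape.years], dtype=np.int64)
    zero_years = np.nonzero(counts == 0)[0]
    if zero_years.size and zero_years[0] < 0.1 * spec.n_years:
        raise DegenerateEnvironmentError(
            f"planted population collapsed in year {int(landscape.years[zero_years[0]])}, "
            f"before 10% of the {spec.n_years}-year span"
        )
    landscape.target_series = counts
    landscape.meta = {"planted_rule": spec.planted_rule, "seed": spec.seed}
    return landscape


def replay_planted_run(spec: SyntheticEnvSpec, landscape: Landscape) -> SimulationResult:
    """Re-run the planted simulation on a generated landscape.

    By construction the replayed trajectory equals the target series exactly,
    so the returned result has RMSE 0.
    """
    return run_simulation(
        landscape,
        spec.params,
        spec.rule(),
        init=InitConfig(count=spec.init_households),
        rng=np.random.default_rng(spec.planted_run_seed()),
        factor_config=spec.factor_config,
    )
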