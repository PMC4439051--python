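"""Synthetic matched case-control spatial datasets.

Real geocoded case-control registry data are confidential, so the package
ships a generator with the same structure the analyses assume:

* an inhomogeneous at-risk population drawn from a Gaussian-mixture intensity
  truncated to the study window (emulating regions dominated by a few urban
  centers);
* case labels assigned uniformly under the null hypothesis of spatially
  constant risk, or with a multiplicative relative risk inside an injected
  circular cluster;
* matching strata (region, year of birth, sex) assigned independently of
  location, with a fixed number of same-stratum controls per case (default 6,
  the matched design of the emulated registries);
* an optional privacy jitter that replaces the trailing digits of each
  projected coordinate with a uniform random number, as registry custodians
  do before releasing point data.
"""

from __future__ import annotations

import dataclasses
import math
import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dstat import CaseControlPattern
from .geometry import StudyWindow

__all__ = [
    "PopulationCenter",
    "InjectedCluster",
    "StrataSpec",
    "SyntheticScenario",
    "JitterSpec",
    "StratumExhaustedError",
    "sample_population",
    "assign_cases",
    "jitter_coordinates",
    "generate_dataset",
    "northeast_like_scenario",
]


class StratumExhaustedError(RuntimeError):
    """Raised when a matching stratum has too few non-case locations."""


@dataclasses.dataclass(frozen=True)
class PopulationCenter:
    """One Gaussian component of the population intensity."""

    center: tuple[float, float]
    spread: float  # isotropic standard deviation, meters
    weight: float = 1.0

    def __post_init__(self):
        if self.spread <= 0 or self.weight <= 0:
            raise ValueError("spread and weight must be positive")


@dataclasses.dataclass(frozen=True)
class InjectedCluster:
    """Circular excess-risk region used by non-null scenarios."""

    center: tuple[float, float]
    radius: float
    relative_risk: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.relative_risk < 1:
            raise ValueError("relative_risk must be >= 1")


@dataclasses.dataclass(frozen=True)
class StrataSpec:
    """Distribution of the matching variables, independent of location."""

    birth_year_range: tuple[int, int] = (1996, 2011)
    sex_ratio_male: float = 0.512
    region_weights: tuple[tuple[str, float], ...] = (
        ("CAT", 0.62),
        ("PV", 0.18),
        ("ARA", 0.11),
        ("NAV", 0.09),
    )

    def __post_init__(self):
        lo, hi = self.birth_year_range
        if hi < lo:
            raise ValueError("birth_year_range must be (low, high)")
        if not 0 < self.sex_ratio_male < 1:
            raise ValueError("sex_ratio_male must be in (0, 1)")
        if any(w <= 0 for _, w in self.region_weights):
            raise ValueError("region weights must be positive")

    @property
    def n_strata(self) -> int:
        lo, hi = self.birth_year_range
        return (hi - lo + 1) * len(self.region_weights) * 2

    @property
    def min_stratum_prob(self) -> float:
        """Probability of the rarest (region, year, sex) stratum."""
        lo, hi = self.birth_year_range
        w = np.array([x for _, x in self.region_weights], dtype=float)
        sex_min = min(self.sex_ratio_male, 1.0 - self.sex_ratio_male)
        return float(w.min() / w.sum() / (hi - lo + 1) * sex_min)

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        lo, hi = self.birth_year_range
        regions = [r for r, _ in self.region_weights]
        w = np.array([w for _, w in self.region_weights], dtype=float)
        return pd.DataFrame(
            {
                "region": rng.choice(regions, size=n, p=w / w.sum()),
                "birth_year": rng.integers(lo, hi + 1, size=n),
                "sex": np.where(rng.random(n) < self.sex_ratio_male, "M", "F"),
            }
        )


@dataclasses.dataclass(frozen=True)
class SyntheticScenario:
    """Generative description of one matched case-control dataset.

    ``n_locations`` is the size of the at-risk location pool the labels are
    assigned over. It defaults to twice the final dataset size
    ``n_cases * (1 + matching_ratio)`` plus a margin inversely proportional to
    the rarest stratum's probability, so that stratum-matched control sampling
    does not exhaust any stratum under typical multinomial fluctuations (the
    emulated birth-registry pool is effectively unlimited relative to the
    case series).
    """

    window: StudyWindow
    population_centers: tuple[PopulationCenter, ...]
    n_cases: int
    matching_ratio: int = 6
    strata: StrataSpec = dataclasses.field(default_factory=StrataSpec)
    injected_cluster: Optional[InjectedCluster] = None
    n_locations: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.matching_ratio < 1:
            raise ValueError("matching_ratio must be >= 1")
        if not self.population_centers:
            raise ValueError("need at least one population center")

    @property
    def pool_size(self) -> int:
        if self.n_locations is not None:
            return self.n_locations
        margin = math.ceil(4 * self.matching_ratio / self.strata.min_stratum_prob)
        return 2 * self.n_cases * (1 + self.matching_ratio) + margin

    def to_json(self) -> str:
        d = {
            "window_wkt": self.window.boundary.wkt,
            "crs_tag": self.window.crs_tag,
            "population_centers": [
                {"center": list(c.center), "spread": c.spread, "weight": c.weight}
                for c in self.population_centers
            ],
            "n_cases": self.n_cases,
            "matching_ratio": self.matching_ratio,
            "strata": {
                "birth_year_range": list(self.strata.birth_year_range),
                "sex_ratio_male": self.strata.sex_ratio_male,
                "region_weights": [list(x) for x in self.strata.region_weights],
            },
            "injected_cluster": (
                None
                if self.injected_cluster is None
                else {
                    "center": list(self.injected_cluster.center),
                    "radius": self.injected_cluster.radius,
                    "relative_risk": self.injected_cluster.relative_risk,
                }
            ),
            "n_locations": self.n_locations,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticScenario":
        d = json.loads(text)
        strata = d.get("strata") or {}
        return cls(
            window=StudyWindow.from_wkt(d["window_wkt"], crs_tag=d.get("crs_tag", "")),
            population_centers=tuple(
                PopulationCenter(tuple(c["center"]), c["spread"], c.get("weight", 1.0))
                for c in d["population_centers"]
            ),
            n_cases=d["n_cases"],
            matching_ratio=d.get("matching_ratio", 6),
            strata=StrataSpec(
                birth_year_range=tuple(strata.get("birth_year_range", (1996, 2011))),
                sex_ratio_male=strata.get("sex_ratio_male", 0.512),
                region_weights=tuple(
                    tuple(x) for x in strata.get(
                        "region_weights",
                        (("CAT", 0.62), ("PV", 0.18), ("ARA", 0.11), ("NAV", 0.09)),
                    )
                ),
            ),
            injected_cluster=(
                None
                if d.get("injected_cluster") is None
                else InjectedCluster(
                    tuple(d["injected_cluster"]["center"]),
                    d["injected_cluster"]["radius"],
                    d["injected_cluster"]["relative_risk"],
                )
            ),
            n_locations=d.get("n_locations"),
            seed=d.get("seed"),
        )


@dataclasses.dataclass(frozen=True)
class JitterSpec:
    """Privacy jitter: replace the last ``digits`` integer digits of x and y."""

    digits: int = 1
    seed: Optional[int] = None

    def __post_init__(self):
        if self.digits < 1:
            raise ValueError("digits must be >= 1")


def sample_population(
    scenario: SyntheticScenario,
    n: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    max_tries: int = 1000,
) -> np.ndarray:
    """Draw at-risk locations from the mixture intensity truncated to the window.

    Rejection sampling: mixture proposals falling outside the window are
    discarded. Raises if fewer than ``n`` points are accepted after
    ``max_tries`` batches (window and mixture effectively disjoint).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    if n is None:
        n = scenario.pool_size
    centers = scenario.population_centers
    w = np.array([c.weight for c in centers], dtype=float)
    w /= w.sum()
    mu = np.array([c.center for c in centers], dtype=float)
    sd = np.array([c.spread for c in centers], dtype=float)

    out = np.empty((n, 2))
    got = 0
    for _ in range(max_tries):
        m = max(n - got, 16)
        comp = rng.choice(len(centers), size=m, p=w)
        pts = mu[comp] + rng.standard_normal((m, 2)) * sd[comp, None]
        keep = scenario.window.contains(pts)
        pts = pts[keep]
        take = min(len(pts), n - got)
        out[got : got + take] = pts[:take]
        got += take
        if got == n:
            return out
    raise RuntimeError(
        "rejection sampling failed: population mixture places almost no mass "
        "inside the study window"
    )


def _case_weights(
    locations: np.ndarray, cluster: Optional[InjectedCluster]
) -> np.ndarray:
    w = np.ones(len(locations))
    if cluster is not None:
        d = np.hypot(
            locations[:, 0] - cluster.center[0], locations[:, 1] - cluster.center[1]
        )
        w[d <= cluster.radius] *= cluster.relative_risk
    return w


def assign_cases(
    locations: np.ndarray,
    scenario: SyntheticScenario,
    rng: Optional[np.random.Generator] = None,
) -> CaseControlPattern:
    """Label a location pool into cases and stratum-matched controls.

    Case locations are sampled without replacement with probability
    proportional to 1 (null) or to the relative risk inside the injected
    cluster. Strata are assigned independently per location. Every case then
    receives ``matching_ratio`` controls drawn without replacement from the
    same-stratum non-case locations; the leftover pool is discarded. The
    output pattern carries a ``match_id`` column linking each control to its
    case.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    locations = np.asarray(locations, dtype=float)
    n = len(locations)
    need = scenario.n_cases * (1 + scenario.matching_ratio)
    if n < need:
        raise ValueError(f"need at least {need} locations, got {n}")

    w = _case_weights(locations, scenario.injected_cluster)
    case_idx = rng.choice(n, size=scenario.n_cases, replace=False, p=w / w.sum())
    is_case_pool = np.zeros(n, dtype=bool)
    is_case_pool[case_idx] = True

    strata = scenario.strata.sample(n, rng)
    codes = pd.MultiIndex.from_frame(strata).factorize()[0]

    selected = list(case_idx)
    match_ids = list(range(scenario.n_cases))
    ctrl_indices: list[int] = []
    ctrl_match: list[int] = []
    for code in np.unique(codes[case_idx]):
        stratum_cases = np.flatnonzero(is_case_pool & (codes == code))
        pool = np.flatnonzero(~is_case_pool & (codes == code))
        need_k = len(stratum_cases) * scenario.matching_ratio
        if len(pool) < need_k:
            key = tuple(strata.iloc[stratum_cases[0]][["region", "birth_year", "sex"]])
            raise StratumExhaustedError(
                f"stratum {key}: need {need_k} controls, only {len(pool)} available"
            )
        chosen = rng.choice(pool, size=need_k, replace=False)
        for j, ci in enumerate(stratum_cases):
            block = chosen[j * scenario.matching_ratio : (j + 1) * scenario.matching_ratio]
            mid = int(np.flatnonzero(case_idx == ci)[0])
            ctrl_indices.extend(int(b) for b in block)
            ctrl_match.extend([mid] * scenario.matching_ratio)

    selected.extend(ctrl_indices)
    match_ids.extend(ctrl_match)
    sel = np.asarray(selected, dtype=int)
    is_case = np.zeros(len(sel), dtype=bool)
    is_case[: scenario.n_cases] = True
    out_strata = strata.iloc[sel].reset_index(drop=True)
    out_strata["match_id"] = match_ids
    return CaseControlPattern(
        coords=locations[sel],
        is_case=is_case,
        window=scenario.window,
        strata=out_strata,
    )


def jitter_coordinates(data, spec: JitterSpec):
    """Replace the last ``spec.digits`` integer digits of every coordinate.

    For each coordinate, x' = floor(x / 10^d) * 10^d + u with u uniform on
    {0, ..., 10^d - 1}, independently per coordinate, so |x' - x| < 10^d.
    Jittered points that would leave the study window are redrawn (up to 100
    times), then left unchanged, preserving the pattern invariants. Accepts a
    CaseControlPattern or a bare (n, 2) coordinate array.
    """
    rng = np.random.default_rng(spec.seed)
    base = 10 ** spec.digits

    if isinstance(data, CaseControlPattern):
        coords = data.coords
    else:
        coords = np.asarray(data, dtype=float)
    if coords.size and coords.min() < 0:
        raise ValueError("privacy jitter expects nonnegative projected coordinates")

    def draw(c):
        return np.floor(c / base) * base + rng.integers(0, base, size=c.shape)

    new = draw(coords)
    if isinstance(data, CaseControlPattern):
        bad = ~data.window.contains(new)
        tries = 0
        while bad.any() and tries < 100:
            new[bad] = draw(coords[bad])
            bad = ~data.window.contains(new)
            tries += 1
        new[bad] = coords[bad]
        return CaseControlPattern(
            coords=new, is_case=data.is_case, window=data.window, strata=data.strata
        )
    return new


def generate_dataset(
    scenario: SyntheticScenario, jitter: Optional[JitterSpec] = None
) -> CaseControlPattern:
    """Sample a full matched dataset from the scenario (one RNG from its seed)."""
    rng = np.random.default_rng(scenario.seed)
    locations = sample_population(scenario, rng=rng)
    data = assign_cases(locations, scenario, rng=rng)
    if jitter is not None:
        data = jitter_coordinates(data, jitter)
    return data


def northeast_like_scenario(
    n_cases: int = 638,
    seed: Optional[int] = None,
    injected_cluster: Optional[InjectedCluster] = None,
) -> SyntheticScenario:
    """Default scenario sized like the largest regional stratum of the emulated
    registries (638 cases, 3828 matched controls): a ~300 x 300 km region whose
    population concentrates in a few urban centers of very different size."""
    window = StudyWindow.rectangle(0.0, 0.0, 300_000.0, 300_000.0, crs_tag="synthetic")
    centers = (
        PopulationCenter((230_000.0, 120_000.0), 15_000.0, weight=0.55),  # dominant metro
        PopulationCenter((60_000.0, 230_000.0), 9_000.0, weight=0.20),
        PopulationCenter((150_000.0, 180_000.0), 7_000.0, weight=0.15),
        PopulationCenter((110_000.0, 60_000.0), 20_000.0, weight=0.10),  # diffuse rural
    )
    return SyntheticScenario(
        window=window,
        population_centers=centers,
        n_cases=n_cases,
        seed=seed,
        injected_cluster=injected_cluster,
    )
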