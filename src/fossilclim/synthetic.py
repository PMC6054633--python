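"""Synthetic calibration sets and fossil sequences with known climate truth.

The generator emulates the statistical structure that pollen-climate transfer
functions assume: each taxon has a unimodal (Gaussian) response surface over
the two climate variables (mean July and January air temperature), modern
calibration samples are drawn along a correlated bivariate-normal climate
gradient, and counts are multinomial at a fixed pollen sum. Fossil sequences
follow a depth-indexed climate trajectory with decoupled seasonal trends
(summer temperature declining up-core, winter temperature rising) and
superimposed abrupt cooling events of prescribed magnitude, mimicking an
interglacial sequence punctuated by short-lived coolings.

Winter temperature is deliberately the harder target: taxon tolerances are
broad for January and the calibration climate variables are correlated
(default r = 0.7), so January reconstructions are realistically confounded
with the (stronger) July signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import TERRESTRIAL, AssemblageTable, ClimateTable


@dataclass(frozen=True)
class TaxonResponse:
    """Bivariate Gaussian response of one taxon.

    Expected relative abundance at climate (x_jul, x_jan) is proportional to
    ``h * exp(-(x_jul-u_jul)^2 / 2 t_jul^2) * exp(-(x_jan-u_jan)^2 / 2 t_jan^2)``.
    """

    name: str
    optimum_jul: float
    tolerance_jul: float
    optimum_jan: float
    tolerance_jan: float
    max_abundance: float = 1.0

    def __post_init__(self):
        if self.tolerance_jul <= 0 or self.tolerance_jan <= 0:
            raise ValueError("tolerances must be > 0")
        if self.max_abundance <= 0:
            raise ValueError("max_abundance must be > 0")


@dataclass(frozen=True)
class AbruptEvent:
    """Boxcar cooling event on the depth axis (depth_lo < depth_hi, metres)."""

    name: str
    depth_lo: float
    depth_hi: float
    delta_t_jul: float

    def __post_init__(self):
        if not self.depth_lo < self.depth_hi:
            raise ValueError(f"event {self.name!r}: depth_lo must be < depth_hi")

    @property
    def window(self) -> tuple[float, float]:
        return (self.depth_lo, self.depth_hi)


@dataclass
class ClimateTrajectory:
    """Depth-indexed true climate, the ground truth of a fossil simulation."""

    depths: np.ndarray
    t_jul: np.ndarray
    t_jan: np.ndarray
    events: list[AbruptEvent] = field(default_factory=list)

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.t_jul = np.asarray(self.t_jul, dtype=float)
        self.t_jan = np.asarray(self.t_jan, dtype=float)
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depth grid must be strictly increasing")
        if not (len(self.depths) == len(self.t_jul) == len(self.t_jan)):
            raise ValueError("depths, t_jul, t_jan must have equal length")

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth_m": self.depths, "t_jul": self.t_jul, "t_jan": self.t_jan}
        )


@dataclass
class TrajectoryParams:
    """Defaults emulate a ~10 m interglacial lake sequence: July temperature
    declining by 3 degC from bottom (oldest) to top, January temperature rising
    by 5 degC over the same span, and two abrupt July coolings of 2.7 and
    1.8 degC (a broad mid-sequence event and a short late-sequence spike)."""

    depth_top: float = 16.0
    depth_bottom: float = 26.0
    n_samples: int = 200
    t_jul_base: float = 14.5       # degC at the bottom (oldest sample)
    t_jul_decline: float = 3.0     # total bottom-to-top decline, degC
    t_jan_base: float = -10.0      # degC at the bottom
    t_jan_rise: float = 5.0        # total bottom-to-top rise, degC
    events: tuple[AbruptEvent, ...] = (
        AbruptEvent("tunturi", 22.51, 23.40, 2.7),
        AbruptEvent("varrio", 17.30, 17.45, 1.8),
    )


def eemian_like_trajectory(params: TrajectoryParams | None = None) -> ClimateTrajectory:
    """Build the truth trajectory: linear decoupled seasonal trends plus
    boxcar cooling events subtracted from July temperature (sharp onset by
    construction: the full magnitude applies to every in-window sample)."""
    p = params or TrajectoryParams()
    if p.depth_top >= p.depth_bottom:
        raise ValueError("depth_top must be above (smaller than) depth_bottom")
    depths = np.linspace(p.depth_top, p.depth_bottom, p.n_samples)
    span = p.depth_bottom - p.depth_top
    frac_up = (p.depth_bottom - depths) / span  # 0 at bottom, 1 at top
    t_jul = p.t_jul_base - p.t_jul_decline * frac_up
    t_jan = p.t_jan_base + p.t_jan_rise * frac_up

    events = sorted(p.events, key=lambda e: e.depth_lo)
    for a, b in zip(events, events[1:]):
        if a.depth_hi > b.depth_lo:
            raise ValueError(f"overlapping event windows: {a.name!r} and {b.name!r}")
    for ev in events:
        if ev.depth_lo < depths[0] or ev.depth_hi > depths[-1]:
            raise ValueError(f"event {ev.name!r} outside the depth grid")
        mask = (depths >= ev.depth_lo) & (depths <= ev.depth_hi)
        if mask.sum() < 1:
            raise ValueError(f"event {ev.name!r} window contains no grid samples")
        t_jul = t_jul - ev.delta_t_jul * mask
    return ClimateTrajectory(depths, t_jul, t_jan, list(events))


@dataclass
class BivariateNormalClimate:
    """Correlated (T_jul, T_jan) sampler for modern calibration climates.

    Defaults sketch a European lake-surface-sample gradient from subarctic to
    temperate sites; the positive correlation makes winter and summer signals
    partly confounded, as in real calibration sets. Draws violating
    ``t_jan <= t_jul`` are rejected and redrawn.
    """

    mean_jul: float = 13.0
    sd_jul: float = 3.0
    mean_jan: float = -6.0
    sd_jan: float = 5.0
    corr: float = 0.7

    def __call__(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        cov = np.array(
            [
                [self.sd_jul**2, self.corr * self.sd_jul * self.sd_jan],
                [self.corr * self.sd_jul * self.sd_jan, self.sd_jan**2],
            ]
        )
        mean = np.array([self.mean_jul, self.mean_jan])
        out = np.empty((n, 2))
        filled = 0
        while filled < n:
            draw = rng.multivariate_normal(mean, cov, size=n - filled)
            ok = draw[:, 1] <= draw[:, 0]
            k = int(ok.sum())
            out[filled : filled + k] = draw[ok]
            filled += k
        return out[:, 0], out[:, 1]


def default_responses(n_taxa: int = 25, seed: int = 0) -> list[TaxonResponse]:
    """A reproducible community of unimodal taxa spanning the gradient.

    July optima are spread over 6-20 degC with moderate tolerances (1.5-3.5),
    January optima track July optima (warm-summer taxa also tolerate milder
    winters) with broad tolerances (5-9) so the winter signal is weak.
    """
    rng = np.random.default_rng(seed)
    opt_jul = np.linspace(6.0, 20.0, n_taxa) + rng.uniform(-0.5, 0.5, n_taxa)
    tol_jul = rng.uniform(1.5, 3.5, n_taxa)
    opt_jan = -6.0 + 1.2 * (opt_jul - 13.0) + rng.normal(0.0, 2.0, n_taxa)
    tol_jan = rng.uniform(5.0, 9.0, n_taxa)
    h = rng.uniform(0.5, 1.5, n_taxa)
    return [
        TaxonResponse(f"taxon_{i + 1:02d}", opt_jul[i], tol_jul[i], opt_jan[i],
                      tol_jan[i], h[i])
        for i in range(n_taxa)
    ]


def expected_proportions(t_jul, t_jan, responses) -> np.ndarray:
    """Expected taxon proportions at each climate point (rows sum to 1)."""
    t_jul = np.atleast_1d(np.asarray(t_jul, dtype=float))
    t_jan = np.atleast_1d(np.asarray(t_jan, dtype=float))
    U = np.array([r.optimum_jul for r in responses])
    T = np.array([r.tolerance_jul for r in responses])
    Uj = np.array([r.optimum_jan for r in responses])
    Tj = np.array([r.tolerance_jan for r in responses])
    H = np.array([r.max_abundance for r in responses])
    lam = H * np.exp(
        -((t_jul[:, None] - U) ** 2) / (2 * T**2)
        - ((t_jan[:, None] - Uj) ** 2) / (2 * Tj**2)
    )
    total = lam.sum(axis=1)
    if np.any(total <= 0):
        raise FloatingPointError("all expected proportions zero at some climate")
    return lam / total[:, None]


def _draw_counts(rng, probs, pollen_sum, overdispersion):
    counts = np.empty_like(probs)
    for i, p in enumerate(probs):
        q = p
        if overdispersion is not None:
            q = rng.dirichlet(np.maximum(p * overdispersion, 1e-12))
        counts[i] = rng.multinomial(int(pollen_sum), q / q.sum())
    return counts


def generate_calibration(
    n_samples: int = 300,
    responses=None,
    climate_sampler=None,
    pollen_sum: int = 400,
    seed: int | None = None,
    overdispersion: float | None = None,
) -> tuple[AssemblageTable, ClimateTable]:
    """Draw a modern calibration set: counts table plus climate/coordinates.

    Counts are multinomial at ``pollen_sum`` around the Gaussian-response
    expected proportions; optional Dirichlet-multinomial overdispersion via a
    precision parameter (larger = closer to plain multinomial). Coordinates
    are a smooth map of climate (colder summers further north, milder winters
    further west) with jitter, enough for analogue-geography summaries.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if pollen_sum < 1:
        raise ValueError("pollen_sum must be >= 1")
    rng = np.random.default_rng(seed)
    responses = responses or default_responses()
    sampler = climate_sampler or BivariateNormalClimate()

    t_jul, t_jan = sampler(rng, n_samples)
    for _ in range(100):
        try:
            probs = expected_proportions(t_jul, t_jan, responses)
            break
        except FloatingPointError:
            warnings.warn("resampling climates with zero expected pollen", stacklevel=2)
            t_jul, t_jan = sampler(rng, n_samples)
    else:  # pragma: no cover - pathological response set
        raise RuntimeError("could not sample climates with non-zero expected pollen")

    counts = _draw_counts(rng, probs, pollen_sum, overdispersion)
    ids = [f"cal_{i + 1:04d}" for i in range(n_samples)]
    table = AssemblageTable(
        pd.DataFrame(counts, index=ids, columns=[r.name for r in responses]),
        groups={r.name: TERRESTRIAL for r in responses},
    )
    lat = 68.0 - 1.1 * (t_jul - 13.0) + rng.normal(0.0, 0.8, n_samples)
    lon = 20.0 + 1.2 * (t_jan + 6.0) + rng.normal(0.0, 2.0, n_samples)
    climate = ClimateTable(
        pd.DataFrame({"t_jul": t_jul, "t_jan": t_jan, "lat": lat, "lon": lon}, index=ids)
    )
    return table, climate


def generate_fossil(
    trajectory: ClimateTrajectory,
    responses=None,
    pollen_sum: int = 400,
    seed: int | None = None,
    overdispersion: float | None = None,
) -> AssemblageTable:
    """Draw a depth-ordered fossil sequence along a climate trajectory."""
    if pollen_sum < 1:
        raise ValueError("pollen_sum must be >= 1")
    rng = np.random.default_rng(seed)
    responses = responses or default_responses()
    probs = expected_proportions(trajectory.t_jul, trajectory.t_jan, responses)
    counts = _draw_counts(rng, probs, pollen_sum, overdispersion)
    ids = [f"fs_{i + 1:04d}" for i in range(len(trajectory.depths))]
    return AssemblageTable(
        pd.DataFrame(counts, index=ids, columns=[r.name for r in responses]),
        groups={r.name: TERRESTRIAL for r in responses},
        depths=trajectory.depths,
    )


@dataclass
class SyntheticScenario:
    """A complete simulated study: calibration set, fossil sequence, truth."""

    calibration: AssemblageTable
    climate: ClimateTable
    fossil: AssemblageTable
    trajectory: ClimateTrajectory
    responses: list[TaxonResponse]
    pollen_sum: int
    seed: int


def default_scenario(
    seed: int = 0,
    n_calibration: int = 300,
    n_taxa: int = 25,
    pollen_sum: int = 400,
    trajectory_params: TrajectoryParams | None = None,
) -> SyntheticScenario:
    """The standard study conditions: 300 calibration samples, 25 taxa,
    pollen sum 400, and a 200-sample fossil sequence with two abrupt events."""
    ss = np.random.SeedSequence(seed)
    s_resp, s_cal, s_fos = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    responses = default_responses(n_taxa, seed=s_resp)
    calibration, climate = generate_calibration(
        n_calibration, responses, pollen_sum=pollen_sum, seed=s_cal
    )
    trajectory = eemian_like_trajectory(trajectory_params)
    fossil = generate_fossil(trajectory, responses, pollen_sum=pollen_sum, seed=s_fos)
    return SyntheticScenario(calibration, climate, fossil, trajectory, responses,
                             pollen_sum, seed)
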