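"""Poisson-process age-depth modelling with dated tie points.

Sediment deposition is treated as a Poisson process with event rate
``k_rate`` per centimetre: between two dated tie points the waiting times of
successive depth increments are gamma distributed with shape proportional to
the increment thickness, so the normalised within-segment age allocation is a
Dirichlet bridge. Each Monte-Carlo draw samples the tie-point ages from their
normal priors (rejecting stratigraphic inversions) and allocates the time
span across the depth increments, yielding strictly monotone age-depth
functions whose spread grows away from the tie points. Smaller ``k_rate``
means coarser depositional events and therefore larger interior uncertainty.

Ages are in ka before present; depth increases downward (and age with it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass(frozen=True)
class TiePoint:
    """A dated depth: age prior is Normal(age_ka, (age_2sigma_ka / 2)^2)."""

    depth_m: float
    age_ka: float
    age_2sigma_ka: float

    def __post_init__(self):
        if self.age_2sigma_ka <= 0:
            raise ValueError("age_2sigma_ka must be > 0")


@dataclass
class AgeDepthPosterior:
    """Monte-Carlo ensemble of monotone depth -> age functions."""

    depths: np.ndarray            # (n_depths,) metres, increasing
    draws: np.ndarray             # (n_draws, n_depths) ka
    k_rate: float                 # events per cm
    tie_points: list[TiePoint]
    tie_age_draws: np.ndarray     # (n_draws, n_ties) ka
    extrapolated: np.ndarray | None = None  # bool mask over depths

    def median_ages(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.draws, q, axis=0)

    def interpolate(self, depths) -> np.ndarray:
        """Per-draw linear interpolation of ages at arbitrary depths."""
        depths = np.asarray(depths, dtype=float)
        out = np.empty((self.draws.shape[0], len(depths)))
        for i, row in enumerate(self.draws):
            out[i] = np.interp(depths, self.depths, row)
        return out

    def summary(self) -> pd.DataFrame:
        lo, hi = self.quantile(0.022750131948179195), self.quantile(0.9772498680518208)
        return pd.DataFrame(
            {
                "depth_m": self.depths,
                "age_median_ka": self.median_ages(),
                "age_lo_2sigma_ka": lo,
                "age_hi_2sigma_ka": hi,
                "two_sigma_ka": 0.5 * (hi - lo),
            }
        )


def _sample_tie_ages(rng, ties, n_draws, max_iter=1000) -> np.ndarray:
    mu = np.array([t.age_ka for t in ties])
    sd = np.array([t.age_2sigma_ka / 2.0 for t in ties])
    ages = rng.normal(mu, sd, size=(n_draws, len(ties)))
    for _ in range(max_iter):
        bad = np.any(np.diff(ages, axis=1) <= 0, axis=1)
        if not bad.any():
            return ages
        ages[bad] = rng.normal(mu, sd, size=(int(bad.sum()), len(ties)))
    raise RuntimeError("could not sample tie-point ages without inversions")


def fit_psequence(
    tie_points,
    depth_grid,
    k_rate: float = 1.0,
    n_draws: int = 1000,
    seed=None,
    extrapolate: bool = False,
) -> AgeDepthPosterior:
    """Monte-Carlo P-sequence-style age model on a depth grid.

    ``k_rate`` is the Poisson event rate in events per centimetre; the time
    increment over a depth step of d cm has a Gamma(k_rate * d) allocation
    weight. Depths outside the tie-point span raise an error unless
    ``extrapolate`` is set, in which case ages continue at the adjacent
    segment's per-draw mean accumulation rate and are flagged.
    """
    ties = sorted(tie_points, key=lambda t: t.depth_m)
    if len(ties) < 2:
        raise ValueError("need at least 2 tie points")
    if k_rate <= 0:
        raise ValueError("k_rate must be > 0")
    for a, b in zip(ties, ties[1:]):
        if b.depth_m <= a.depth_m:
            raise ValueError("tie points must have distinct, increasing depths")
        # probability that the deeper tie is dated younger than the shallower
        sd = np.hypot(a.age_2sigma_ka / 2.0, b.age_2sigma_ka / 2.0)
        p_inv = float(norm.cdf((a.age_ka - b.age_ka) / sd))
        if p_inv > 0.5:
            raise ValueError(
                f"tie points at {a.depth_m} m and {b.depth_m} m imply an age "
                f"inversion with probability {p_inv:.2f}"
            )

    depths = np.sort(np.asarray(depth_grid, dtype=float))
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depth grid must have distinct values")
    d_lo, d_hi = ties[0].depth_m, ties[-1].depth_m
    tol = 1e-9 * max(1.0, abs(d_hi))
    near = (depths >= d_lo - tol) & (depths <= d_hi + tol)
    depths = np.where(near, np.clip(depths, d_lo, d_hi), depths)
    outside = (depths < d_lo) | (depths > d_hi)
    if outside.any() and not extrapolate:
        raise ValueError(
            "depth grid extends outside the tie-point span; pass "
            "extrapolate=True or model the section with fixed_duration_section"
        )

    rng = np.random.default_rng(seed)
    tie_ages = _sample_tie_ages(rng, ties, n_draws)
    ages = np.empty((n_draws, len(depths)))

    for s in range(len(ties) - 1):
        t0, t1 = ties[s], ties[s + 1]
        inseg = (depths >= t0.depth_m) & (depths <= t1.depth_m)
        knots = np.unique(np.concatenate([[t0.depth_m], depths[inseg], [t1.depth_m]]))
        shapes = k_rate * np.diff(knots) * 100.0  # depth steps in cm
        g = np.maximum(rng.gamma(np.maximum(shapes, 1e-9), 1.0, size=(n_draws, len(shapes))),
                       1e-12)
        frac = np.cumsum(g, axis=1) / g.sum(axis=1, keepdims=True)
        frac = np.column_stack([np.zeros(n_draws), frac])
        span = (tie_ages[:, s + 1] - tie_ages[:, s])[:, None]
        knot_ages = tie_ages[:, s][:, None] + span * frac
        pos = np.searchsorted(knots, depths[inseg])
        ages[:, inseg] = knot_ages[:, pos]

    if outside.any():
        below = depths < d_lo
        above = depths > d_hi
        if below.any():
            rate = (tie_ages[:, 1] - tie_ages[:, 0]) / (ties[1].depth_m - ties[0].depth_m)
            ages[:, below] = tie_ages[:, 0][:, None] - rate[:, None] * (d_lo - depths[below])
        if above.any():
            rate = (tie_ages[:, -1] - tie_ages[:, -2]) / (
                ties[-1].depth_m - ties[-2].depth_m
            )
            ages[:, above] = tie_ages[:, -1][:, None] + rate[:, None] * (depths[above] - d_hi)

    return AgeDepthPosterior(depths, ages, k_rate, ties, tie_ages,
                             extrapolated=outside if outside.any() else None)


def fixed_duration_section(posterior: AgeDepthPosterior, section_depths,
                           duration_ka: float) -> AgeDepthPosterior:
    """Append a section of prescribed total duration outside the tie span.

    The section (e.g. rapidly deposited glacio-lacustrine beds) is mapped
    linearly onto ``duration_ka`` anchored at the adjacent tie point's age
    draw: deeper-than-span sections extend back in time, shallower ones
    forward.
    """
    section = np.sort(np.asarray(section_depths, dtype=float))
    d_lo = posterior.tie_points[0].depth_m
    d_hi = posterior.tie_points[-1].depth_m
    if np.any((section >= d_lo) & (section <= d_hi)):
        raise ValueError("section overlaps the modelled tie-point span")
    if duration_ka < 0:
        raise ValueError("duration_ka must be >= 0")
    # the section's samples are spaced linearly over [0, duration] measured
    # from the adjacent tie age; the sample nearest the tie sits at the tie age
    ptp = section.max() - section.min()
    deeper = section > d_hi
    if deeper.all():
        anchor = posterior.tie_age_draws[:, -1][:, None]
        frac = (section - section.min()) / ptp if ptp > 0 else np.ones_like(section)
        sec_ages = anchor + duration_ka * frac[None, :]
    elif (~deeper).all() and (section < d_lo).all():
        anchor = posterior.tie_age_draws[:, 0][:, None]
        frac = (section.max() - section) / ptp if ptp > 0 else np.ones_like(section)
        sec_ages = anchor - duration_ka * frac[None, :]
    else:
        raise ValueError("section must lie entirely on one side of the tie span")

    depths = np.concatenate([posterior.depths, section])
    draws = np.concatenate([posterior.draws, sec_ages], axis=1)
    order = np.argsort(depths)
    flags = np.concatenate(
        [
            posterior.extrapolated
            if posterior.extrapolated is not None
            else np.zeros(len(posterior.depths), dtype=bool),
            np.ones(len(section), dtype=bool),
        ]
    )
    return AgeDepthPosterior(depths[order], draws[:, order], posterior.k_rate,
                             posterior.tie_points, posterior.tie_age_draws,
                             extrapolated=flags[order])


def uncertainty_profile(posterior: AgeDepthPosterior) -> pd.DataFrame:
    """Per-depth 2-sigma age uncertainty (half-width of the central 95.45%
    interval, plus the full width)."""
    s = posterior.summary()
    return pd.DataFrame(
        {
            "depth_m": s["depth_m"],
            "two_sigma_ka": s["two_sigma_ka"],
            "full_width_ka": s["age_hi_2sigma_ka"] - s["age_lo_2sigma_ka"],
        }
    )
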