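"""Reconstruction significance via the random-transfer-function RDA test.

A reconstruction is deemed significant when it explains more variance in the
fossil assemblage data than reconstructions produced by transfer functions
trained on random environmental variables. The statistic is the fraction of
variance explained (VE) by a single-variable redundancy analysis: species
columns are centred and projected on the (centred) reconstruction. Null
reconstructions are obtained by retraining the same calibration method on
variables drawn uniformly over the observed climate range; the Monte-Carlo
p-value is ``(1 + #{VE_null >= VE_obs}) / (1 + n_perm)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .calibration import make_model, prepare_matrices
from .io import AssemblageTable, ClimateTable


def rda_ve(Y, constraint) -> float:
    """Variance of (centred) species data explained by one constraint.

    Equivalent to the variance-weighted mean per-taxon regression R^2:
    VE = SS(fitted) / SS(total) under per-taxon least squares on the
    centred constraint.
    """
    Y = np.asarray(Y, dtype=float)
    c = np.asarray(constraint, dtype=float)
    if Y.ndim != 2 or len(c) != Y.shape[0]:
        raise ValueError("constraint length must match species rows")
    if Y.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    cc = c - c.mean()
    denom = float(cc @ cc)
    if denom <= 1e-24 * max(1.0, float(np.abs(c).max()) ** 2):
        warnings.warn("constant constraint; VE = 0", stacklevel=2)
        return 0.0
    Yc = Y - Y.mean(axis=0)
    total = float((Yc**2).sum())
    if total <= 0:
        return 0.0
    b = (Yc.T @ cc) / denom
    fitted = np.outer(cc, b)
    return float((fitted**2).sum()) / total


def permutation_pvalue(ve_obs: float, ve_null) -> float:
    """Monte-Carlo p-value (1 + #{null >= obs}) / (1 + n_null)."""
    ve_null = np.asarray(ve_null, dtype=float)
    return float((1 + int((ve_null >= ve_obs - 1e-15).sum())) / (1 + len(ve_null)))


@dataclass
class SignificanceResult:
    ve_obs: float
    ve_null: np.ndarray
    p: float
    n_perm: int
    method: str
    climate_var: str
    subset: np.ndarray | None = None  # row indices of the fossil subset used

    def null_quantiles(self, qs=(0.5, 0.9, 0.95, 0.99)) -> dict[float, float]:
        return {q: float(np.quantile(self.ve_null, q)) for q in qs}


def _resolve_subset(depths, n, subset):
    if subset is None:
        return np.arange(n)
    if isinstance(subset, tuple) and len(subset) == 2:
        if depths is None:
            raise ValueError("depth-range subset requires a depth-indexed fossil table")
        lo, hi = sorted(subset)
        idx = np.where((depths >= lo) & (depths <= hi))[0]
    else:
        idx = np.asarray(subset)
        if idx.dtype == bool:
            idx = np.where(idx)[0]
    if len(idx) < 3:
        raise ValueError("subset must contain at least 3 fossil samples")
    return idx


def random_tf_test(
    calibration: AssemblageTable,
    climate_table: ClimateTable,
    fossil: AssemblageTable,
    method: str = "MAT",
    climate_var: str = "t_jul",
    n_perm: int = 99,
    subset=None,
    seed=None,
    sqrt_species: bool = False,
    model_params: dict | None = None,
) -> SignificanceResult:
    """Significance of a reconstruction against random-variable null models.

    ``subset`` restricts the test to part of the sequence (a (depth_lo,
    depth_hi) tuple or row indices); species data are re-centred within the
    subset. The null climate variables are uniform over the observed range of
    the real variable. Deterministic under ``seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Xc, Xf, depths = prepare_matrices(calibration, fossil)
    y = climate_table.variable(climate_var)
    idx = _resolve_subset(depths, Xf.shape[0], subset)
    Yf = np.sqrt(Xf[idx]) if sqrt_species else Xf[idx]

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    def reconstruct(env, child_seed):
        model = make_model(method, seed=child_seed, **(model_params or {}))
        model.fit(Xc, env)
        return model.predict(Xf[idx])

    obs_seed = int(ss.generate_state(1)[0] % 2**31)
    ve_obs = rda_ve(Yf, reconstruct(y, obs_seed))
    lo, hi = float(y.min()), float(y.max())
    ve_null = np.empty(n_perm)
    for b in range(n_perm):
        env = rng.uniform(lo, hi, size=len(y))
        try:
            ve_null[b] = rda_ve(Yf, reconstruct(env, obs_seed + b + 1))
        except Exception as err:
            raise RuntimeError(f"null draw {b + 1} failed: {err}") from err
    p = permutation_pvalue(ve_obs, ve_null)
    return SignificanceResult(ve_obs, ve_null, p, n_perm, method, climate_var, idx)
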