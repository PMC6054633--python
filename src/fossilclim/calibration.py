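"""Pollen-climate calibration models, cross-validation and the ensemble.

Six transfer-function estimators share the sklearn fit/predict contract
(``X`` = samples x taxa percentage matrix on the 0-100 scale, ``y`` = climate
variable in degC):

* :class:`WARegressor` - weighted averaging with inverse or classical
  deshrinking;
* :class:`WAPLSRegressor` - weighted-averaging partial least squares
  (component extraction on weighted residuals, final weighted regression);
* :class:`MATRegressor` - modern analogue technique, k nearest neighbours
  under squared chord distance;
* :class:`MLRCRegressor` - maximum-likelihood response curves (per-taxon
  Gaussian-logit regression, grid-search likelihood maximisation);
* :class:`BRTRegressor` / :class:`RFRegressor` - boosted and bagged
  regression-tree ensembles (thin wrappers around scikit-learn).

:func:`reconstruct_ensemble` fits all six to a calibration set, predicts the
fossil sequence, and summarises the stack as a pointwise median with a robust
LOESS smoother (tricube local quadratic, one robustifying iteration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .io import AssemblageTable, ClimateTable, chord_distance_matrix, harmonise_taxa, percentages

DEFAULT_METHODS = ("WA", "WAPLS", "MAT", "MLRC", "BRT", "RF")


def _row_proportions(X: np.ndarray) -> np.ndarray:
    rowsum = X.sum(axis=1)
    if np.any(rowsum <= 0):
        raise ValueError("samples with all-zero composition")
    return X / rowsum[:, None]


# ---------------------------------------------------------------------------
# Weighted averaging
# ---------------------------------------------------------------------------

class WARegressor(RegressorMixin, BaseEstimator):
    """Weighted-averaging transfer function.

    Taxon optimum u_k is the abundance-weighted mean of the climate variable;
    the raw estimate for a sample is the abundance-weighted mean of the
    optima of the taxa present. The variance shrinkage of the double
    averaging is corrected by linear deshrinking: ``inverse`` regresses the
    observed climate on the raw estimates, ``classical`` regresses the raw
    estimates on observed climate and inverts.
    """

    def __init__(self, deshrinking: str = "inverse"):
        self.deshrinking = deshrinking

    def fit(self, X, y):
        if self.deshrinking not in ("inverse", "classical"):
            raise ValueError(f"unknown deshrinking {self.deshrinking!r}")
        X, y = check_X_y(X, y)
        colsum = X.sum(axis=0)
        keep = colsum > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} taxa with zero total abundance",
                          stacklevel=2)
        if not keep.any():
            raise ValueError("no taxa with positive abundance")
        self.keep_ = keep
        Xk = X[:, keep]
        self.optima_ = (Xk.T @ y) / colsum[keep]
        raw = self._raw(Xk)
        if np.var(raw) < 1e-12 or np.var(y) < 1e-12:
            # degenerate: constant raw estimates or constant target
            self.slope_, self.intercept_ = 0.0, float(np.mean(y))
            self._constant = True
        else:
            self._constant = False
            if self.deshrinking == "inverse":
                b, a = np.polyfit(raw, y, 1)
                self.slope_, self.intercept_ = float(b), float(a)
            else:
                b, a = np.polyfit(y, raw, 1)  # raw = a + b*y  ->  y = (raw - a)/b
                self.slope_, self.intercept_ = 1.0 / float(b), -float(a) / float(b)
        self.n_features_in_ = X.shape[1]
        return self

    def _raw(self, Xk: np.ndarray) -> np.ndarray:
        rowsum = Xk.sum(axis=1)
        if np.any(rowsum <= 0):
            raise ValueError("sample with zero abundance over retained taxa")
        return (Xk @ self.optima_) / rowsum

    def predict(self, X):
        check_is_fitted(self, "optima_")
        X = check_array(X)
        raw = self._raw(X[:, self.keep_])
        if self._constant:
            return np.full(len(raw), self.intercept_)
        return self.intercept_ + self.slope_ * raw


# ---------------------------------------------------------------------------
# WA-PLS
# ---------------------------------------------------------------------------

class WAPLSRegressor(RegressorMixin, BaseEstimator):
    """Weighted-averaging partial least squares.

    Components are extracted iteratively: taxon scores are abundance-weighted
    averages of the current climate residuals, sample scores are
    abundance-weighted averages of taxon scores, and the climate variable is
    re-regressed on all components so far (weighted by sample pollen totals).
    With one component this reproduces weighted averaging with inverse
    deshrinking. When ``n_components`` is None it is chosen by
    leave-one-out RMSEP over ``1..max_components``.
    """

    def __init__(self, n_components=None, max_components: int = 5):
        self.n_components = n_components
        self.max_components = max_components

    def _fit_core(self, X, y, n_comp):
        r = X.sum(axis=1)
        c = X.sum(axis=0)
        if np.any(r <= 0):
            raise ValueError("samples with all-zero composition")
        total = r.sum()
        xbar = float(r @ y) / total
        e = y - xbar
        U = np.empty((X.shape[1], n_comp))
        S = np.empty((len(y), 0))
        coef = np.array([xbar])
        safe_c = np.where(c > 0, c, 1.0)
        for a in range(n_comp):
            u = (X.T @ e) / safe_c
            u[c <= 0] = 0.0
            U[:, a] = u
            s = (X @ u) / r
            S = np.column_stack([S, s])
            design = np.column_stack([np.ones(len(y)), S])
            w = np.sqrt(r)
            coef, *_ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
            e = y - design @ coef
        self.taxon_scores_ = U
        self.coef_ = coef
        return self

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        rank_bound = min(X.shape[0] - 1, X.shape[1])
        if self.n_components is not None:
            if not 1 <= self.n_components <= rank_bound:
                raise ValueError(
                    f"n_components={self.n_components} outside feasible range "
                    f"1..{rank_bound}"
                )
            n_comp = self.n_components
        else:
            n_comp = self._select_components(X, y, min(self.max_components, rank_bound))
        self.n_components_ = n_comp
        self._fit_core(X, y, n_comp)
        self.n_features_in_ = X.shape[1]
        return self

    def _select_components(self, X, y, max_comp) -> int:
        n = len(y)
        preds = np.zeros((n, max_comp))
        helper = WAPLSRegressor(n_components=max_comp)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            helper._fit_core(X[mask], y[mask], max_comp)
            for a in range(max_comp):
                preds[i, a] = helper._predict_components(X[i : i + 1], a + 1)[0]
        rmsep = np.sqrt(((preds - y[:, None]) ** 2).mean(axis=0))
        return int(rmsep.argmin()) + 1

    def _predict_components(self, X, n_comp) -> np.ndarray:
        r = X.sum(axis=1)
        S = (X @ self.taxon_scores_[:, :n_comp]) / r[:, None]
        design = np.column_stack([np.ones(len(r)), S])
        return design @ self.coef_[: n_comp + 1]

    def predict(self, X):
        check_is_fitted(self, "taxon_scores_")
        X = check_array(X)
        return self._predict_components(X, self.n_components_)


# ---------------------------------------------------------------------------
# Modern analogue technique
# ---------------------------------------------------------------------------

class MATRegressor(RegressorMixin, BaseEstimator):
    """k-nearest-neighbour prediction under squared chord distance.

    The prediction is the (inverse-distance-weighted) mean climate of the k
    most compositionally similar calibration samples; ties at the k-th
    distance are all included, and exact matches (zero distance) receive all
    the weight.
    """

    def __init__(self, k: int = 5, weighting: str = "inverse_distance"):
        self.k = k
        self.weighting = weighting

    def fit(self, X, y):
        if self.weighting not in ("none", "inverse_distance"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        X, y = check_X_y(X, y)
        if not 1 <= self.k <= X.shape[0]:
            raise ValueError(f"k={self.k} outside 1..{X.shape[0]}")
        self.library_ = _row_proportions(X)
        self.y_ = np.asarray(y, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def _distances(self, X) -> np.ndarray:
        P = _row_proportions(check_array(X))
        return chord_distance_matrix(P, self.library_)

    def kneighbors(self, X):
        """(distances, index lists) of the k nearest analogues (ties included)."""
        check_is_fitted(self, "y_")
        D = self._distances(X)
        idx, dst = [], []
        for row in D:
            kth = np.partition(row, self.k - 1)[self.k - 1]
            sel = np.where(row <= kth + 1e-12)[0]
            sel = sel[np.argsort(row[sel], kind="stable")]
            idx.append(sel)
            dst.append(row[sel])
        return dst, idx

    def predict(self, X, return_min_distance: bool = False):
        dst, idx = self.kneighbors(X)
        out = np.empty(len(idx))
        dmin = np.empty(len(idx))
        for i, (d, j) in enumerate(zip(dst, idx)):
            dmin[i] = d.min()
            if self.weighting == "none":
                w = np.ones_like(d)
            else:
                exact = d <= 1e-12
                w = np.where(exact, 1.0, 0.0) if exact.any() else 1.0 / d
            out[i] = float(np.average(self.y_[j], weights=w))
        if return_min_distance:
            return out, dmin
        return out


# ---------------------------------------------------------------------------
# Maximum likelihood response curves
# ---------------------------------------------------------------------------

class MLRCRegressor(RegressorMixin, BaseEstimator):
    """Maximum-likelihood calibration with Gaussian-logit response curves.

    Each taxon's probability of occurrence along the climate gradient is
    modelled as ``logit p = b0 + b1 x + b2 x^2`` fitted by binomial GLM on
    the observed proportions. A fossil sample's climate estimate maximises
    the summed Bernoulli log-likelihood of its taxon proportions over a
    regular grid spanning the calibration climate range. Curves with
    ``b2 >= 0`` are kept but flagged monotone (``monotone_`` mask); taxa whose
    GLM fails to converge are excluded (``fitted_`` mask).
    """

    def __init__(self, grid_points: int = 501, clip: float = 1e-6):
        self.grid_points = grid_points
        self.clip = clip

    def fit(self, X, y):
        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import DomainWarning, PerfectSeparationError

        X, y = check_X_y(X, y)
        P = _row_proportions(X)
        design = np.column_stack([np.ones(len(y)), y, y**2])
        m = X.shape[1]
        self.coefs_ = np.full((m, 3), np.nan)
        self.fitted_ = np.zeros(m, dtype=bool)
        self.monotone_ = np.zeros(m, dtype=bool)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k in range(m):
                pk = np.clip(P[:, k], 0.0, 1.0)
                if pk.max() <= 0:
                    continue
                try:
                    res = sm.GLM(pk, design, family=sm.families.Binomial()).fit(maxiter=100)
                    if not np.all(np.isfinite(res.params)):
                        continue
                except (PerfectSeparationError, ValueError, np.linalg.LinAlgError):
                    continue
                self.coefs_[k] = res.params
                self.fitted_[k] = True
                self.monotone_[k] = res.params[2] >= 0
        if not self.fitted_.any():
            raise ValueError("no taxon with a defined response curve")
        self.grid_ = np.linspace(y.min(), y.max(), self.grid_points)
        G = np.column_stack([np.ones_like(self.grid_), self.grid_, self.grid_**2])
        eta = self.coefs_[self.fitted_] @ G.T  # (m_fit, grid)
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, self.clip, 1.0 - self.clip)
        self._logp = np.log(p)
        self._log1mp = np.log1p(-p)
        self.n_features_in_ = X.shape[1]
        return self

    def log_likelihood(self, X) -> np.ndarray:
        """(n_samples, n_grid) summed Bernoulli log-likelihood surface."""
        check_is_fitted(self, "grid_")
        P = _row_proportions(check_array(X))[:, self.fitted_]
        return P @ self._logp + (1.0 - P) @ self._log1mp

    def predict(self, X):
        ll = self.log_likelihood(X)
        return self.grid_[np.argmax(ll, axis=1)]


# ---------------------------------------------------------------------------
# Tree ensembles
# ---------------------------------------------------------------------------

class BRTRegressor(RegressorMixin, BaseEstimator):
    """Boosted regression trees (gradient boosting on taxon percentages).

    Slow learning (rate 0.01), interaction depth 3 and a 0.75 bag fraction;
    the number of trees is chosen by validation-loss early stopping. A
    degenerate constant target yields a constant prediction with a warning.
    """

    def __init__(self, learning_rate=0.01, max_depth=3, subsample=0.75,
                 max_estimators=2000, n_iter_no_change=20,
                 validation_fraction=0.2, random_state=None):
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.subsample = subsample
        self.max_estimators = max_estimators
        self.n_iter_no_change = n_iter_no_change
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if np.ptp(y) < 1e-12:
            warnings.warn("constant target; predicting the constant", stacklevel=2)
            self.constant_ = float(y[0])
            self.model_ = None
            return self
        self.constant_ = None
        self.model_ = GradientBoostingRegressor(
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            subsample=self.subsample,
            n_estimators=self.max_estimators,
            n_iter_no_change=self.n_iter_no_change,
            validation_fraction=self.validation_fraction,
            random_state=self.random_state,
        ).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        if self.model_ is None:
            return np.full(X.shape[0], self.constant_)
        return self.model_.predict(X)


class RFRegressor(RegressorMixin, BaseEstimator):
    """Random forest on taxon percentages (500 trees, mtry = p/3)."""

    def __init__(self, n_estimators=500, max_features=1 / 3, random_state=None):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if np.ptp(y) < 1e-12:
            warnings.warn("constant target; predicting the constant", stacklevel=2)
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            random_state=self.random_state,
        ).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(check_array(X))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Held-out prediction skill: RMSEP, R^2 and maximum bias (the largest
    absolute mean residual over 10 equal-width intervals of the climate
    variable)."""

    rmsep: float
    r2: float
    max_bias: float
    predictions: np.ndarray
    scheme: str


def cross_validate(model, X, y, scheme: str = "loo", n_folds: int = 10,
                   seed=None) -> CVResult:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    preds = np.empty(n)
    if scheme == "loo":
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            m = clone(model).fit(X[mask], y[mask])
            preds[i] = m.predict(X[i : i + 1])[0]
    elif scheme == "kfold":
        for train, test in KFold(n_splits=n_folds, shuffle=True,
                                 random_state=seed).split(X):
            m = clone(model).fit(X[train], y[train])
            preds[test] = m.predict(X[test])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    resid = preds - y
    rmsep = float(np.sqrt((resid**2).mean()))
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0
    edges = np.linspace(y.min(), y.max(), 11)
    max_bias = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (y >= lo) & (y <= hi) if hi == edges[-1] else (y >= lo) & (y < hi)
        if sel.any():
            max_bias = max(max_bias, abs(float(resid[sel].mean())))
    return CVResult(rmsep, r2, max_bias, preds, scheme)


# ---------------------------------------------------------------------------
# Robust LOESS
# ---------------------------------------------------------------------------

def robust_loess(x, y, span: float = 0.03, degree: int = 2,
                 robustifying_iterations: int = 1) -> np.ndarray:
    """Locally weighted polynomial smoother with tricube weights and
    bisquare robustifying iterations (the classic LOESS recipe).

    ``span`` is the fraction of points in each local window (at least
    ``degree + 2`` points are always used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    window = max(degree + 2, int(np.ceil(span * n)))
    window = min(window, n)
    robust_w = np.ones(n)
    fitted = y.copy()
    for it in range(robustifying_iterations + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            sel = np.argpartition(d, window - 1)[:window]
            dmax = d[sel].max()
            if dmax <= 0:
                fitted[i] = np.average(y[sel], weights=robust_w[sel])
                continue
            w = (1 - (d[sel] / dmax) ** 3) ** 3
            w = np.clip(w, 0.0, None) * robust_w[sel]
            if w.sum() <= 0:
                w = np.ones_like(w)
            deg = min(degree, len(sel) - 1)
            with warnings.catch_warnings():
                # robust weights may zero out most of a window
                warnings.simplefilter("ignore", np.exceptions.RankWarning)
                coef = np.polyfit(x[sel] - x[i], y[sel], deg, w=np.sqrt(w))
            fitted[i] = coef[-1]
        if it == robustifying_iterations:
            break
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = np.clip(resid / (6.0 * s), -1.0, 1.0)
        robust_w = (1 - u**2) ** 2
    return fitted


# ---------------------------------------------------------------------------
# Ensemble reconstruction
# ---------------------------------------------------------------------------

@dataclass
class Reconstruction:
    """One method's predicted climate along the fossil sequence."""

    method: str
    depths: np.ndarray
    estimates: np.ndarray
    analogue_distances: np.ndarray | None = None


@dataclass
class EnsembleReconstruction:
    """The six-method stack with pointwise median and LOESS smoother."""

    climate_var: str
    depths: np.ndarray
    members: dict[str, Reconstruction]
    median: np.ndarray
    smoothed: np.ndarray
    cv_stats: dict[str, CVResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (depth, method, estimate) plus median/smoothed rows."""
        rows = []
        for name, rec in self.members.items():
            for d, v in zip(rec.depths, rec.estimates):
                rows.append((d, name, v))
        for d, v in zip(self.depths, self.median):
            rows.append((d, "median", v))
        for d, v in zip(self.depths, self.smoothed):
            rows.append((d, "loess", v))
        return pd.DataFrame(rows, columns=["depth_m", "method", "estimate"])


def make_model(method: str, seed=None, **params):
    """Instantiate a calibration model by name with the package defaults."""
    method = method.upper().replace("-", "")
    if method == "WA":
        return WARegressor(**params)
    if method == "WAPLS":
        return WAPLSRegressor(**params)
    if method == "MAT":
        return MATRegressor(**params)
    if method == "MLRC":
        return MLRCRegressor(**params)
    if method == "BRT":
        return BRTRegressor(random_state=seed, **params)
    if method == "RF":
        return RFRegressor(random_state=seed, **params)
    raise ValueError(f"unknown calibration method {method!r}")


#: cross-validation scheme per method: LOO where refits are cheap, seeded
#: 10-fold where a fit is expensive.
DEFAULT_CV_SCHEMES = {
    "WA": "loo", "WAPLS": "loo", "MAT": "loo",
    "MLRC": "kfold", "BRT": "kfold", "RF": "kfold",
}


def prepare_matrices(calibration: AssemblageTable, fossil: AssemblageTable):
    """Harmonise taxa and return percent matrices (X_cal, X_fossil, depths)."""
    if calibration.unit != "percent":
        calibration = percentages(calibration)
    if fossil.unit != "percent":
        fossil = percentages(fossil)
    fossil = harmonise_taxa(fossil, calibration)
    Xc = calibration.pollen_matrix().to_numpy()
    Xf = fossil.pollen_matrix().to_numpy()
    return Xc, Xf, fossil.depths


def reconstruct_ensemble(
    calibration: AssemblageTable,
    climate_table: ClimateTable,
    fossil: AssemblageTable,
    climate_var: str = "t_jul",
    methods=DEFAULT_METHODS,
    seed=None,
    compute_cv: bool = True,
    loess_span: float = 0.03,
    model_params: dict | None = None,
    cv_schemes: dict | None = None,
) -> EnsembleReconstruction:
    """Fit every method, reconstruct the fossil sequence, and summarise.

    Any single model failure aborts with an error naming the method. The
    pointwise median of the member reconstructions is smoothed along the
    depth axis by robust LOESS (span ``loess_span``, one robustifying
    iteration).
    """
    Xc, Xf, depths = prepare_matrices(calibration, fossil)
    if depths is None:
        depths = np.arange(len(Xf), dtype=float)
    y = climate_table.variable(climate_var)
    model_params = model_params or {}
    schemes = dict(DEFAULT_CV_SCHEMES, **(cv_schemes or {}))
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(methods))

    members: dict[str, Reconstruction] = {}
    cv_stats: dict[str, CVResult] = {}
    for i, method in enumerate(methods):
        mseed = int(children[2 * i].generate_state(1)[0] % 2**31)
        model = make_model(method, seed=mseed, **model_params.get(method, {}))
        try:
            model.fit(Xc, y)
            if isinstance(model, MATRegressor):
                est, dmin = model.predict(Xf, return_min_distance=True)
                members[method] = Reconstruction(method, depths, est, dmin)
            else:
                members[method] = Reconstruction(method, depths, model.predict(Xf))
            if compute_cv:
                cvseed = int(children[2 * i + 1].generate_state(1)[0] % 2**31)
                cv_stats[method] = cross_validate(
                    model, Xc, y, scheme=schemes.get(method, "kfold"), seed=cvseed
                )
        except Exception as err:
            raise RuntimeError(f"calibration model {method!r} failed: {err}") from err

    stack = np.vstack([members[m].estimates for m in methods])
    median = np.median(stack, axis=0)
    smoothed = robust_loess(depths, median, span=loess_span)
    return EnsembleReconstruction(climate_var, np.asarray(depths, dtype=float),
                                  members, median, smoothed, cv_stats)


# -- spec-style functional wrappers ----------------------------------------

def fit_wa(calibration, climate_var="t_jul", deshrinking="inverse", *, climate_table):
    Xc = percentages(calibration).pollen_matrix().to_numpy() \
        if calibration.unit != "percent" else calibration.pollen_matrix().to_numpy()
    return WARegressor(deshrinking=deshrinking).fit(Xc, climate_table.variable(climate_var))


def fit_wapls(calibration, climate_var="t_jul", n_components=None, *, climate_table):
    Xc = percentages(calibration).pollen_matrix().to_numpy() \
        if calibration.unit != "percent" else calibration.pollen_matrix().to_numpy()
    return WAPLSRegressor(n_components=n_components).fit(Xc, climate_table.variable(climate_var))


def fit_mat(calibration, climate_var="t_jul", k=5, weighting="inverse_distance", *, climate_table):
    Xc = percentages(calibration).pollen_matrix().to_numpy() \
        if calibration.unit != "percent" else calibration.pollen_matrix().to_numpy()
    return MATRegressor(k=k, weighting=weighting).fit(Xc, climate_table.variable(climate_var))


def fit_mlrc(calibration, climate_var="t_jul", grid_points=501, *, climate_table):
    Xc = percentages(calibration).pollen_matrix().to_numpy() \
        if calibration.unit != "percent" else calibration.pollen_matrix().to_numpy()
    return MLRCRegressor(grid_points=grid_points).fit(Xc, climate_table.variable(climate_var))


def fit_brt(calibration, climate_var="t_jul", seed=None, *, climate_table, **hyper):
    Xc = percentages(calibration).pollen_matrix().to_numpy() \
        if calibration.unit != "percent" else calibration.pollen_matrix().to_numpy()
    return BRTRegressor(random_state=seed, **hyper).fit(Xc, climate_table.variable(climate_var))


def fit_rf(calibration, climate_var="t_jul", seed=None, *, climate_table, **hyper):
    Xc = percentages(calibration).pollen_matrix().to_numpy() \
        if calibration.unit != "percent" else calibration.pollen_matrix().to_numpy()
    return RFRegressor(random_state=seed, **hyper).fit(Xc, climate_table.variable(climate_var))
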