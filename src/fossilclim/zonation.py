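"""Stratigraphic zonation by a multivariate regression tree.

With core depth as the sole predictor and the taxon percentage matrix as a
multivariate response, a regression tree's splits are depth thresholds, so
the leaves form contiguous stratigraphic zones. Splits are found by best-first
greedy search: at each step the split (over all current zones and all
between-sample boundaries) that most reduces the total within-zone sum of
squares is taken. Tree size is chosen by repeated k-fold cross-validation and
the 1-SE rule: the smallest tree whose CV relative error is within one
standard error of the minimum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import AssemblageTable


def _segment_ss(c1: np.ndarray, c2: np.ndarray, a: int, b: int) -> float:
    """Within-segment sum of squares over all taxa for rows [a, b).

    ``c1``/``c2`` are (n+1, k) cumulative sums of Y and Y**2.
    """
    n = b - a
    s1 = c1[b] - c1[a]
    s2 = c2[b] - c2[a]
    return float((s2 - s1**2 / n).sum())


def _grow_greedy(depths: np.ndarray, Y: np.ndarray, max_zones: int,
                 min_segment: int = 1):
    """Best-first greedy segmentation. Returns the ordered split sequence as
    (cut_index, depth_midpoint, ss_reduction) triples; cut_index i splits
    rows [.., i) / [i, ..). Ties in SS reduction go to the shallowest depth."""
    n, _ = Y.shape
    c1 = np.vstack([np.zeros(Y.shape[1]), np.cumsum(Y, axis=0)])
    c2 = np.vstack([np.zeros(Y.shape[1]), np.cumsum(Y**2, axis=0)])
    segments = [(0, n)]
    splits = []
    while len(segments) < max_zones:
        best = None  # (reduction, cut_index, seg_pos)
        for pos, (a, b) in enumerate(segments):
            if b - a < 2 * min_segment:
                continue
            parent = _segment_ss(c1, c2, a, b)
            for c in range(a + min_segment, b - min_segment + 1):
                red = parent - _segment_ss(c1, c2, a, c) - _segment_ss(c1, c2, c, b)
                # strict > keeps the shallowest cut on exact ties
                if best is None or red > best[0] + 1e-12:
                    best = (red, c, pos)
        if best is None or best[0] <= 1e-10:
            break
        red, c, pos = best
        a, b = segments[pos]
        segments[pos : pos + 1] = [(a, c), (c, b)]
        splits.append((c, 0.5 * (depths[c - 1] + depths[c]), red))
    return splits, c1, c2


def _predict_ss(train_depths, train_Y, cuts, test_depths, test_Y) -> float:
    """Held-out SS of a segmentation of the training rows, applied to test rows."""
    bounds = sorted(0.5 * (train_depths[c - 1] + train_depths[c]) for c in cuts)
    edges = np.array([-np.inf] + bounds + [np.inf])
    ss = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        tr = (train_depths > lo) & (train_depths <= hi)
        te = (test_depths > lo) & (test_depths <= hi)
        if not te.any():
            continue
        mean = train_Y[tr].mean(axis=0) if tr.any() else train_Y.mean(axis=0)
        ss += float(((test_Y[te] - mean) ** 2).sum())
    return ss


def choose_size_1se(cv_table: pd.DataFrame) -> int:
    """Smallest size with CV error <= min(CV error) + SE at the argmin."""
    if len(cv_table) == 0:
        raise ValueError("empty CV table")
    t = cv_table.sort_values("size")
    i = int(t["cv_error"].to_numpy().argmin())
    threshold = t["cv_error"].iloc[i] + t["se"].iloc[i]
    ok = t[t["cv_error"] <= threshold]
    return int(ok["size"].iloc[0])


class MultivariateRegressionTree(BaseEstimator):
    """Greedy multivariate regression tree on the depth axis.

    Parameters
    ----------
    max_zones : int
        Upper bound on the number of zones (leaves) grown.
    cv_folds, n_cv_reps : int
        Repeated k-fold cross-validation used to populate the CV table; the
        standard error of the CV relative error is taken across repetitions.
    random_state : int or None
        Seed for the CV fold shuffling.
    sqrt_transform : bool
        Apply a square-root transform to the response before fitting.
    run_cv : bool
        Skip cross-validation (and 1-SE pruning) when False; the full grown
        tree is then kept.

    Fitted attributes: ``split_sequence_`` (ordered split depths of the full
    tree), ``split_depths_`` (splits of the chosen tree), ``size_``,
    ``cv_table_`` (size / cv_error / se), ``tss_``, ``node_ss_``.
    """

    def __init__(self, max_zones=10, cv_folds=10, n_cv_reps=50, min_segment=1,
                 random_state=None, sqrt_transform=False, run_cv=True):
        self.max_zones = max_zones
        self.cv_folds = cv_folds
        self.n_cv_reps = n_cv_reps
        self.min_segment = min_segment
        self.random_state = random_state
        self.sqrt_transform = sqrt_transform
        self.run_cv = run_cv

    def fit(self, depths, Y):
        depths = np.asarray(depths, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n = len(depths)
        if n < 2:
            raise ValueError("need at least 2 samples")
        if Y.shape[0] != n:
            raise ValueError("depths and response must have equal length")
        if self.max_zones > n:
            raise ValueError(f"max_zones={self.max_zones} exceeds n_samples={n}")
        order = np.argsort(depths)
        depths, Y = depths[order], Y[order]
        if np.any(np.diff(depths) <= 0):
            raise ValueError("duplicate depths are not supported")
        if self.sqrt_transform:
            Y = np.sqrt(Y)

        self.depths_ = depths
        self.Y_ = Y
        splits, c1, c2 = _grow_greedy(depths, Y, self.max_zones, self.min_segment)
        self.split_sequence_ = [s[1] for s in splits]
        self._cut_sequence = [s[0] for s in splits]
        self.ss_reductions_ = [s[2] for s in splits]
        self.tss_ = _segment_ss(c1, c2, 0, n)

        if self.run_cv:
            self.cv_table_ = self._cross_validate(depths, Y, len(splits) + 1)
            self.size_ = choose_size_1se(self.cv_table_)
        else:
            self.cv_table_ = None
            self.size_ = len(splits) + 1
        self._apply_size()
        return self

    def _apply_size(self):
        cuts = sorted(self._cut_sequence[: self.size_ - 1])
        self.split_depths_ = sorted(self.split_sequence_[: self.size_ - 1])
        edges = [0] + cuts + [len(self.depths_)]
        self.node_ss_ = []
        self.node_means_ = []
        for a, b in zip(edges[:-1], edges[1:]):
            block = self.Y_[a:b]
            self.node_means_.append(block.mean(axis=0))
            self.node_ss_.append(float(((block - block.mean(axis=0)) ** 2).sum()))

    def _cross_validate(self, depths, Y, max_size) -> pd.DataFrame:
        if max_size < 1:
            raise ValueError("nothing to cross-validate")
        rng = np.random.default_rng(self.random_state)
        n = len(depths)
        folds = min(self.cv_folds, n)
        errors = np.zeros((self.n_cv_reps, max_size))
        for rep in range(self.n_cv_reps):
            assignment = rng.permutation(np.arange(n) % folds)
            ss = np.zeros(max_size)
            for f in range(folds):
                test = assignment == f
                tr_d, tr_Y = depths[~test], Y[~test]
                te_d, te_Y = depths[test], Y[test]
                tr_splits, _, _ = _grow_greedy(tr_d, tr_Y, max_size, self.min_segment)
                tr_cuts = [s[0] for s in tr_splits]
                for m in range(1, max_size + 1):
                    cuts = tr_cuts[: m - 1]  # largest available if exhausted
                    ss[m - 1] += _predict_ss(tr_d, tr_Y, cuts, te_d, te_Y)
            errors[rep] = ss / self.tss_ if self.tss_ > 0 else ss
        mean = errors.mean(axis=0)
        se = errors.std(axis=0, ddof=1) / np.sqrt(self.n_cv_reps) if self.n_cv_reps > 1 \
            else np.zeros(max_size)
        return pd.DataFrame(
            {"size": np.arange(1, max_size + 1), "cv_error": mean, "se": se}
        )

    def zones(self, depths) -> np.ndarray:
        """1-based zone number (shallowest zone = 1) for each depth."""
        depths = np.asarray(depths, dtype=float)
        return np.searchsorted(np.asarray(self.split_depths_), depths, side="left") + 1

    def predict(self, depths) -> np.ndarray:
        """Within-zone mean response vector for each depth."""
        z = self.zones(depths) - 1
        return np.vstack([self.node_means_[i] for i in z])


def fit_mrt(percent_table: AssemblageTable, max_zones=10, cv_folds=10,
            n_cv_reps=50, seed=None, sqrt_transform=False,
            run_cv=True) -> MultivariateRegressionTree:
    """Fit the zonation tree to a percentage table (terrestrial pollen +
    spores as response, depth as the sole predictor)."""
    if percent_table.depths is None:
        raise ValueError("zonation needs a depth-indexed table")
    tree = MultivariateRegressionTree(
        max_zones=max_zones, cv_folds=cv_folds, n_cv_reps=n_cv_reps,
        random_state=seed, sqrt_transform=sqrt_transform, run_cv=run_cv,
    )
    return tree.fit(percent_table.depths, percent_table.pollen_matrix().to_numpy())


def prune_1se(tree: MultivariateRegressionTree) -> MultivariateRegressionTree:
    """Re-apply the 1-SE rule from the tree's CV table (in place)."""
    if getattr(tree, "cv_table_", None) is None:
        raise ValueError("CV table not populated; fit with run_cv=True")
    tree.size_ = choose_size_1se(tree.cv_table_)
    tree._apply_size()
    return tree


def zone_table(tree: MultivariateRegressionTree, table: AssemblageTable) -> pd.DataFrame:
    """Zone assignment per sample plus boundary depths (midpoints between the
    adjacent samples straddling each split)."""
    if table.depths is None:
        raise ValueError("zone assignment needs a depth-indexed table")
    z = tree.zones(table.depths)
    out = pd.DataFrame(
        {"depth_m": table.depths, "zone": z}, index=table.sample_ids
    )
    out.attrs["boundaries_m"] = list(tree.split_depths_)
    return out
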