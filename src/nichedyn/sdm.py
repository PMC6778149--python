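"""Reciprocal presence-background distribution modelling (G-space).

A penalized binomial presence-vs-background model on a linear +
quadratic + pairwise-product feature expansion of the climate
predictors plays the role of the maximum-entropy model: the two are
equivalent in functional form (a Gibbs distribution over background
contrasted features), and the analysis of interest here is the
reciprocal calibrate-and-project design, the max-SSS thresholding, and
the percent-correctly-predicted score, not the fitting engine's
internals.

Each model is fitted in ``n_replicates`` bootstrap replicates holding
out a random quarter of the presences for testing; projection into
another region clamps predictors to the training range so the response
is never evaluated on unseen climate ("fade by clamping" is approximated
by plain clamping).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .grids import ClimateStack
from .prep import OccurrenceSet, extract_env


def expand_features(X: np.ndarray) -> np.ndarray:
    """Linear, quadratic, and pairwise-product terms of the predictors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    cols = [X, X**2]
    for i in range(p):
        for j in range(i + 1, p):
            cols.append((X[:, i] * X[:, j])[:, None])
    return np.hstack(cols)


@dataclass
class _Replicate:
    coef: np.ndarray
    intercept: float
    auc_train: float
    auc_test: float


@dataclass
class SDMModel:
    """Presence-background model: one penalized logistic fit per
    bootstrap replicate plus the shared feature scaling and the training
    climate ranges used for clamping."""

    variables: list[str]
    clamp_min: np.ndarray          # training min per predictor
    clamp_max: np.ndarray          # training max per predictor
    feat_center: np.ndarray
    feat_scale: np.ndarray
    replicates: list = field(default_factory=list)
    reg_weight: float = 1.0
    test_fraction: float = 0.25
    seed: int = 0

    @property
    def auc_train(self) -> float:
        return float(np.mean([r.auc_train for r in self.replicates]))

    @property
    def auc_test(self) -> float:
        return float(np.mean([r.auc_test for r in self.replicates]))

    @property
    def auc_test_sd(self) -> float:
        return float(np.std([r.auc_test for r in self.replicates], ddof=1)) \
            if len(self.replicates) > 1 else 0.0

    def predict(self, climate: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Replicate-mean suitability in [0, 1] for climate vectors."""
        X = np.atleast_2d(np.asarray(climate, dtype=float))
        if X.shape[1] != len(self.variables):
            raise ValueError("climate matrix does not match model predictors")
        if clamp:
            X = np.clip(X, self.clamp_min, self.clamp_max)
        F = (expand_features(X) - self.feat_center) / self.feat_scale
        preds = np.empty((len(self.replicates), X.shape[0]))
        for i, r in enumerate(self.replicates):
            eta = F @ r.coef + r.intercept
            preds[i] = 1.0 / (1.0 + np.exp(-eta))
        return preds.mean(axis=0)


def fit_model(presence_env: np.ndarray, background_env: np.ndarray,
              variables: list[str] | None = None, n_replicates: int = 20,
              test_fraction: float = 0.25, reg_weight: float = 1.0,
              seed: int = 0) -> SDMModel:
    """Fit the presence-background model with bootstrap replication.

    Per replicate a random ``test_fraction`` of the presences is held
    out, the remainder is bootstrap-resampled (with replacement), and an
    L2-penalized logistic fit contrasts presences against the background
    sample.  AUC is reported on the held-out presences vs the background.
    """
    P = np.atleast_2d(np.asarray(presence_env, dtype=float))
    B = np.atleast_2d(np.asarray(background_env, dtype=float))
    if P.shape[0] < 10:
        raise ValueError("need at least 10 presences")
    if B.shape[0] < P.shape[0]:
        raise ValueError("background must be at least as large as the presences")
    if variables is None:
        variables = [f"x{i}" for i in range(P.shape[1])]
    allX = np.vstack([P, B])
    clamp_min, clamp_max = allX.min(axis=0), allX.max(axis=0)
    F_all = expand_features(allX)
    feat_center = F_all.mean(axis=0)
    feat_scale = F_all.std(axis=0)
    feat_scale[feat_scale == 0] = 1.0
    model = SDMModel(
        variables=list(variables), clamp_min=clamp_min, clamp_max=clamp_max,
        feat_center=feat_center, feat_scale=feat_scale,
        reg_weight=reg_weight, test_fraction=test_fraction, seed=seed,
    )
    FB = (expand_features(B) - feat_center) / feat_scale
    rng = np.random.default_rng(seed)
    n = P.shape[0]
    n_test = max(1, int(round(test_fraction * n)))
    for _rep in range(n_replicates):
        perm = rng.permutation(n)
        test_idx, train_pool = perm[:n_test], perm[n_test:]
        boot = train_pool[rng.integers(0, len(train_pool), size=len(train_pool))]
        FP = (expand_features(P[boot]) - feat_center) / feat_scale
        X = np.vstack([FP, FB])
        y = np.r_[np.ones(len(FP)), np.zeros(len(FB))]
        # default sklearn penalty is ridge (L2); C is its inverse strength
        clf = LogisticRegression(C=1.0 / max(reg_weight, 1e-12), max_iter=2000)
        clf.fit(X, y)
        coef = clf.coef_.ravel()
        if not np.isfinite(coef).all():
            warnings.warn("non-finite coefficients; refitting with stronger penalty")
            clf = LogisticRegression(C=0.1, max_iter=2000)
            clf.fit(X, y)
            coef = clf.coef_.ravel()
        rep = _Replicate(coef=coef, intercept=float(clf.intercept_[0]),
                         auc_train=0.0, auc_test=0.0)
        s_train = 1 / (1 + np.exp(-(FP @ coef + rep.intercept)))
        FT = (expand_features(P[test_idx]) - feat_center) / feat_scale
        s_test = 1 / (1 + np.exp(-(FT @ coef + rep.intercept)))
        s_bkg = 1 / (1 + np.exp(-(FB @ coef + rep.intercept)))
        rep.auc_train = float(roc_auc_score(
            np.r_[np.ones(len(s_train)), np.zeros(len(s_bkg))],
            np.r_[s_train, s_bkg]))
        rep.auc_test = float(roc_auc_score(
            np.r_[np.ones(len(s_test)), np.zeros(len(s_bkg))],
            np.r_[s_test, s_bkg]))
        model.replicates.append(rep)
    return model


@dataclass
class SuitabilityMap:
    """Continuous and thresholded projection of one model onto one
    region."""

    region: str
    continuous: np.ndarray     # (ny, nx) in [0, 1], NaN on NoData
    threshold: float
    west: float
    north: float
    cell_size: float
    auc_train: float = np.nan
    auc_test: float = np.nan

    @property
    def binary(self) -> np.ndarray:
        """Suitable (1) / unsuitable (0) / NoData (NaN)."""
        out = np.where(self.continuous >= self.threshold, 1.0, 0.0)
        out[np.isnan(self.continuous)] = np.nan
        return out


def project(model: SDMModel, target: ClimateStack, clamp: bool = True
            ) -> np.ndarray:
    """Continuous suitability raster of the model over a target region."""
    missing = [v for v in model.variables if v not in target.variables]
    if missing:
        raise ValueError(f"target stack lacks predictors {missing}")
    order = [target.variables.index(v) for v in model.variables]
    mask = target.land_mask()
    clim = target.data[order][:, mask].T
    out = np.full(target.shape, np.nan)
    out[mask] = model.predict(clim, clamp=clamp)
    return out


def max_sss_threshold(scores_presence: np.ndarray,
                      scores_background: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the observed scores; sensitivity is the fraction of
    presences at or above the threshold, specificity the fraction of
    background below it.  Ties are broken toward the lowest threshold.
    """
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    cand = np.unique(np.r_[sp, sb])
    if cand.size == 1:
        warnings.warn("all scores identical; threshold equals that score")
        return float(cand[0])
    sens = (sp[None, :] >= cand[:, None]).mean(axis=1)
    spec = (sb[None, :] < cand[:, None]).mean(axis=1)
    total = sens + spec
    return float(cand[np.argmax(total)])  # argmax returns the first (lowest)


def percent_correctly_predicted(suit: SuitabilityMap, occ: OccurrenceSet
                                ) -> float:
    """Percentage of a range's occurrences falling on suitable cells of a
    thresholded projection.

    Occurrences on NoData cells (or outside the raster) are excluded from
    the denominator.
    """
    binary = suit.binary
    ny, nx = binary.shape
    col = np.floor((occ.lon - suit.west) / suit.cell_size).astype(int)
    row = np.floor((suit.north - occ.lat) / suit.cell_size).astype(int)
    inside = (col >= 0) & (col < nx) & (row >= 0) & (row < ny)
    vals = np.full(len(occ), np.nan)
    vals[inside] = binary[row[inside], col[inside]]
    valid = ~np.isnan(vals)
    if not valid.any():
        raise ValueError("no occurrence falls on a valid cell of the projection")
    return float(100.0 * np.nansum(vals[valid]) / valid.sum())


def sample_background_cells(stack: ClimateStack, n: int = 10_000,
                            seed: int = 0) -> np.ndarray:
    """Climate vectors of ``n`` random valid cells (with replacement if
    the region has fewer cells)."""
    mask = stack.land_mask()
    rows, cols = np.nonzero(mask)
    rng = np.random.default_rng(seed)
    replace = len(rows) < n
    idx = rng.choice(len(rows), size=n, replace=replace)
    return stack.data[:, rows[idx], cols[idx]].T


def reciprocal_matrix(stacks: dict[str, ClimateStack],
                      occs: dict[str, OccurrenceSet],
                      n_replicates: int = 20, n_background: int = 10_000,
                      reg_weight: float = 1.0, seed: int = 0,
                      clamp: bool = True) -> pd.DataFrame:
    """Fit one model per calibration range and project it into every
    range (including itself).

    Returns a long-format table with one row per (calibration,
    projection) pair: mean and sd of the replicate test AUCs, the max-SSS
    threshold (from calibration presences vs calibration background on
    the replicate-mean predictor), and the percentage of the projection
    range's occurrences on suitable cells.
    """
    labels = list(stacks)
    if len(labels) < 2:
        raise ValueError("need at least two ranges")
    rows = []
    for ci, cal in enumerate(labels):
        stack = stacks[cal]
        pres = extract_env(occs[cal], stack).values
        bkg = sample_background_cells(stack, n_background, seed=seed + 31 * ci)
        model = fit_model(pres, bkg, variables=stack.variables,
                          n_replicates=n_replicates, reg_weight=reg_weight,
                          seed=seed + 101 * ci)
        thr = max_sss_threshold(model.predict(pres, clamp=clamp),
                                model.predict(bkg, clamp=clamp))
        for proj in labels:
            cont = project(model, stacks[proj], clamp=clamp)
            smap = SuitabilityMap(
                region=proj, continuous=cont, threshold=thr,
                west=stacks[proj].west, north=stacks[proj].north,
                cell_size=stacks[proj].cell_size,
                auc_train=model.auc_train, auc_test=model.auc_test,
            )
            pct = percent_correctly_predicted(smap, occs[proj])
            rows.append({
                "calibration": cal, "projection": proj,
                "auc_mean": model.auc_test, "auc_sd": model.auc_test_sd,
                "threshold": thr, "pct_predicted": pct,
            })
    return pd.DataFrame(rows)


__all__ = [
    "SDMModel", "SuitabilityMap", "expand_features", "fit_model", "project",
    "max_sss_threshold", "percent_correctly_predicted",
    "sample_background_cells", "reciprocal_matrix",
]
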