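"""Occurrence filtering, climate extraction, and predictor selection.

Implements the data-preparation stage of a multi-range niche comparison:
spatial thinning of occurrence records, extraction of climate values at
point locations, grouping of collinear predictors by pairwise Pearson
correlation, and variance-inflation-factor (VIF) screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import KM_PER_DEGREE, ClimateStack


@dataclass
class OccurrenceSet:
    """Labelled wild-occurrence records for one distribution range.

    ``lon``/``lat`` are WGS84 decimal degrees.  ``thinned``/``min_sep``
    record thinning provenance.
    """

    range_label: str
    lon: np.ndarray
    lat: np.ndarray
    ids: list[str] = field(default_factory=list)
    thinned: bool = False
    min_sep: float = 0.0

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.lon.shape != self.lat.shape:
            raise ValueError("lon and lat must have equal length")
        if not self.ids:
            self.ids = [f"{self.range_label}_{i}" for i in range(len(self.lon))]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("occurrence ids must be unique")

    def __len__(self) -> int:
        return len(self.lon)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "range": self.range_label, "lon": self.lon, "lat": self.lat}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, range_label: str | None = None) -> "OccurrenceSet":
        if range_label is not None:
            df = df[df["range"] == range_label]
        else:
            labels = df["range"].unique()
            if len(labels) != 1:
                raise ValueError("frame holds multiple ranges; pass range_label")
            range_label = labels[0]
        return cls(
            range_label=str(range_label),
            lon=df["lon"].to_numpy(float),
            lat=df["lat"].to_numpy(float),
            ids=[str(i) for i in df["id"]],
        )

    @classmethod
    def read_csv(cls, path: str | Path, range_label: str | None = None) -> "OccurrenceSet":
        return cls.from_frame(pd.read_csv(path), range_label)


@dataclass
class EnvTable:
    """Per-point climate values; rows and ``dropped`` partition the input."""

    variables: list[str]
    ids: list[str]
    values: np.ndarray  # (n_points, n_variables)
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.variables):
            raise ValueError("values must be (n_points, n_variables)")
        if np.isnan(self.values).any():
            raise ValueError("retained rows may not contain NoData")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variables)
        df.insert(0, "id", self.ids)
        return df


def _pairwise_dist(lon: np.ndarray, lat: np.ndarray, metric: str) -> str:
    return metric


def _dist_to(lon0: float, lat0: float, lon: np.ndarray, lat: np.ndarray,
             metric: str) -> np.ndarray:
    if metric == "euclidean":
        return np.hypot(lon - lon0, lat - lat0)
    if metric == "greatcircle":
        # haversine, returned in degrees of arc for comparability with
        # a degree-valued min_sep
        la0, la = np.radians(lat0), np.radians(lat)
        dlo = np.radians(lon - lon0)
        dla = la - la0
        a = np.sin(dla / 2) ** 2 + np.cos(la0) * np.cos(la) * np.sin(dlo / 2) ** 2
        return np.degrees(2 * np.arcsin(np.sqrt(np.clip(a, 0, 1))))
    raise ValueError(f"unknown metric {metric!r}")


def thin_occurrences(occ: OccurrenceSet, min_sep: float, *,
                     metric: str = "euclidean",
                     shuffle_seed: int | None = None) -> OccurrenceSet:
    """Greedy spatial thinning: keep a point iff it is at least ``min_sep``
    from every previously kept point.

    The scan runs in input order (first point always kept); pass
    ``shuffle_seed`` to randomize the order reproducibly.  ``min_sep`` is
    in decimal degrees; the default metric is planar Euclidean in degrees.
    """
    if min_sep < 0:
        raise ValueError("min_sep must be non-negative")
    n = len(occ)
    order = np.arange(n)
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(n)
    kept: list[int] = []
    for i in order:
        if not kept:
            kept.append(i)
            continue
        d = _dist_to(occ.lon[i], occ.lat[i],
                     occ.lon[np.array(kept)], occ.lat[np.array(kept)], metric)
        if (d >= min_sep).all():
            kept.append(i)
    idx = np.array(kept, dtype=int)
    return OccurrenceSet(
        range_label=occ.range_label,
        lon=occ.lon[idx] if n else occ.lon,
        lat=occ.lat[idx] if n else occ.lat,
        ids=[occ.ids[i] for i in idx],
        thinned=True,
        min_sep=min_sep,
    )


def extract_env(occ: OccurrenceSet, stack: ClimateStack) -> EnvTable:
    """Climate values at the cell containing each point.

    Cell assignment uses half-open cell intervals (deterministic on
    boundaries).  Points on NoData cells or outside the raster extent are
    listed in ``dropped``.
    """
    if stack.data.size == 0:
        raise ValueError("empty climate stack")
    vals = stack.values_at(occ.lon, occ.lat)
    bad = np.isnan(vals).any(axis=1)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} point(s) of range {occ.range_label!r} fall on "
            "NoData or outside the raster and were dropped"
        )
    return EnvTable(
        variables=list(stack.variables),
        ids=[occ.ids[i] for i in np.flatnonzero(~bad)],
        values=vals[~bad],
        dropped=[occ.ids[i] for i in np.flatnonzero(bad)],
    )


def correlation_groups(env: EnvTable, threshold: float = 0.5) -> list[list[str]]:
    """Partition predictors into groups of mutually reachable high
    correlation.

    Predictors are nodes; an edge joins two when ``|Pearson r| >=
    threshold``; the returned groups are the connected components (in
    input variable order).  Picking one representative per group is left
    to the caller.  A constant predictor has undefined r and is reported
    as a singleton with a warning.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if len(env) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    X = env.values
    p = X.shape[1]
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        names = [v for v, c in zip(env.variables, constant) if c]
        warnings.warn(f"constant predictor(s) {names}: correlation undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    adj = np.abs(corr) >= threshold
    adj[constant, :] = adj[:, constant] = False
    # union-find over the adjacency graph
    parent = list(range(p))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(p):
        for j in range(i + 1, p):
            if adj[i, j]:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, name in enumerate(env.variables):
        groups.setdefault(find(i), []).append(name)
    return sorted(groups.values(), key=lambda g: env.variables.index(g[0]))


def vif(env: EnvTable, cutoff: float = 5.0) -> pd.DataFrame:
    """Variance inflation factors, VIF_j = 1 / (1 - R²_j).

    R²_j comes from the ordinary least-squares regression of predictor j
    (with intercept) on all other predictors.  Exact collinearity yields
    ``inf``.  The returned frame carries a ``retained`` flag for the
    multicollinearity screen (default cutoff 5).
    """
    X = env.values
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more rows than predictors + 1")
    out = np.empty(p)
    for j in range(p):
        y = X[:, j]
        A = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        tss = np.sum((y - y.mean()) ** 2)
        if tss == 0:
            out[j] = np.inf
            continue
        r2 = 1 - resid @ resid / tss
        out[j] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.DataFrame(
        {"variable": env.variables, "vif": out, "retained": out < cutoff}
    )


def select_predictors(env: EnvTable, *, r_threshold: float = 0.5,
                      vif_cutoff: float = 5.0,
                      representatives: dict[int, str] | None = None
                      ) -> tuple[list[str], pd.DataFrame, list[list[str]]]:
    """Correlation grouping followed by VIF screening.

    One representative per correlation group is taken (by default the
    first member, standing in for an expert choice; override per group
    index via ``representatives``), then VIF is computed on the chosen
    set and predictors above ``vif_cutoff`` are excluded.
    Returns (selected names, VIF table, correlation groups).
    """
    groups = correlation_groups(env, r_threshold)
    reps = []
    for gi, group in enumerate(groups):
        name = (representatives or {}).get(gi, group[0])
        if name not in group:
            raise ValueError(f"{name!r} is not in group {group}")
        reps.append(name)
    cols = [env.variables.index(v) for v in reps]
    sub = EnvTable(variables=reps, ids=env.ids, values=env.values[:, cols])
    table = vif(sub, vif_cutoff)
    selected = [v for v, keep in zip(table["variable"], table["retained"]) if keep]
    return selected, table, groups


def occurrence_cells(occ: OccurrenceSet, stack: ClimateStack) -> np.ndarray:
    """Unique valid (row, col) cells occupied by a range; used by the
    geographic-space scoring."""
    row, col = stack.index_of(occ.lon, occ.lat)
    ok = row >= 0
    cells = np.unique(np.stack([row[ok], col[ok]], axis=1), axis=0)
    return cells


__all__ = [
    "OccurrenceSet", "EnvTable", "thin_occurrences", "extract_env",
    "correlation_groups", "vif", "select_predictors", "occurrence_cells",
    "KM_PER_DEGREE",
]
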