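"""Isolation by distance / by environment: distance matrices and Mantel
tests at the population level.

Inputs are pre-extracted per-population environmental tables (e.g. soil
bulk density, pH, organic carbon, cation exchange capacity, bioclim
variables) plus decimal-degree coordinates.  Geographic distance is
great-circle (haversine) in km; environmental distance is Mahalanobis
using the covariance across populations (pseudo-inverse when singular);
highly collinear variable sets can first be reduced by standardised PCA.

The simple Mantel statistic is the Pearson correlation of the off-diagonal
upper triangles of two distance matrices; significance is one-tailed
(upper) by jointly permuting rows and columns of one matrix, with the
(n_greater + 1)/(n_perm + 1) estimator, or by exhaustive enumeration of
all n! relabellings for small n.  The partial Mantel correlation of d1
and d2 given a control matrix is the first-order partial correlation
computed from the three pairwise Mantel r's; its null distribution
permutes d2 while d1 and the control stay fixed.

Genetic distance for these tests is normally the pairwise F_ST matrix
(optionally linearised as F_ST / (1 - F_ST)).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("hybkit")

EARTH_RADIUS_KM = 6371.0088


@dataclass
class EnvTable:
    """Per-population environmental variables and coordinates."""

    data: pd.DataFrame           # index: population; numeric variables
    latitudes: pd.Series
    longitudes: pd.Series

    @property
    def populations(self) -> list[str]:
        return list(self.data.index)

    @staticmethod
    def from_csv(path) -> "EnvTable":
        """CSV with columns population, latitude, longitude, then numeric
        environmental variables."""
        df = pd.read_csv(path)
        for col in ("population", "latitude", "longitude"):
            if col not in df.columns:
                raise ValueError(f"environment table lacks column {col!r}")
        df = df.set_index("population")
        lat = df.pop("latitude").astype(float)
        lon = df.pop("longitude").astype(float)
        return EnvTable(df.astype(float), lat, lon)


def geo_distance(env: EnvTable) -> pd.DataFrame:
    """Great-circle distance matrix (km) between population coordinates."""
    lat = env.latitudes.to_numpy(dtype=float)
    lon = env.longitudes.to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("coordinates out of range (lat +-90, lon +-180)")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = (np.sin(dphi / 2.0) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :]
         * np.sin(dlam / 2.0) ** 2)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=env.populations, columns=env.populations)


def env_distance(env: EnvTable, variables: list[str] | None = None,
                 method: str = "mahalanobis") -> pd.DataFrame:
    """Pairwise Mahalanobis distance over environmental variables.

    Constant variables are dropped with a warning; a singular covariance
    engages the Moore-Penrose pseudo-inverse (rank reported via logging).
    """
    if method != "mahalanobis":
        raise ValueError("only the mahalanobis method is provided")
    X = env.data if variables is None else env.data[list(variables)]
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = sorted(set(X.columns) - set(keep))
    if dropped:
        logger.warning("dropping constant variables: %s", dropped)
    X = X[keep]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 non-constant variables")
    M = X.to_numpy(dtype=float)
    cov = np.cov(M, rowvar=False)
    rank = np.linalg.matrix_rank(cov)
    if rank < cov.shape[0]:
        logger.warning("singular covariance (rank %d of %d); using "
                       "pseudo-inverse", rank, cov.shape[0])
        vi = np.linalg.pinv(cov)
    else:
        vi = np.linalg.inv(cov)
    diff = M[:, None, :] - M[None, :, :]
    d2 = np.einsum("ijk,kl,ijl->ij", diff, vi, diff)
    d = np.sqrt(np.clip(d2, 0.0, None))
    return pd.DataFrame(d, index=env.populations, columns=env.populations)


def env_pca_reduce(env: EnvTable, variables: list[str] | None = None,
                   retain: int | float = 0.955) -> tuple[EnvTable, np.ndarray]:
    """Standardised-variable PCA of the environmental table.

    ``retain``: an int keeps that many components; a fraction in (0, 1)
    keeps the smallest k whose cumulative explained variance reaches it.
    Returns (score table, explained-variance fractions of kept components).
    """
    X = env.data if variables is None else env.data[list(variables)]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 variables for PCA")
    M = X.to_numpy(dtype=float)
    M = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    U, S, _ = np.linalg.svd(M, full_matrices=False)
    var = S ** 2
    frac = var / var.sum()
    rank = int(np.sum(S > S[0] * 1e-12))
    if isinstance(retain, float) and 0.0 < retain < 1.0:
        k = int(np.searchsorted(np.cumsum(frac), retain) + 1)
    else:
        k = int(retain)
    if k > rank:
        raise ValueError(f"retain={retain} exceeds data rank {rank}")
    scores = U[:, :k] * S[:k]
    out = pd.DataFrame(scores, index=env.populations,
                       columns=[f"PC{i + 1}" for i in range(k)])
    return EnvTable(out, env.latitudes, env.longitudes), frac[:k]


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def _upper(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def _check_pair(d1: pd.DataFrame, d2: pd.DataFrame) -> tuple[np.ndarray,
                                                             np.ndarray]:
    if list(d1.index) != list(d2.index):
        raise ValueError("distance matrices have mismatched labels")
    a = d1.to_numpy(dtype=float)
    b = d2.to_numpy(dtype=float)
    if a.shape[0] < 4:
        raise ValueError("Mantel tests need at least 4 populations")
    for m in (a, b):
        if np.ptp(_upper(m)) == 0.0:
            raise ValueError("constant distance matrix: r undefined")
    return a, b


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    return float((x @ y) / np.sqrt((x @ x) * (y @ y)))


def mantel(d1: pd.DataFrame, d2: pd.DataFrame, n_perm: int = 9999,
           seed: int = 0, exhaustive: bool = False) -> tuple[float, float]:
    """Simple Mantel test; returns (r, one-tailed upper p)."""
    a, b = _check_pair(d1, d2)
    r_obs = _pearson(_upper(a), _upper(b))
    n = a.shape[0]
    ua = _upper(a)
    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.asarray(perm)
            r = _pearson(ua, _upper(b[np.ix_(idx, idx)]))
            count += r >= r_obs - 1e-12
            total += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        r = _pearson(ua, _upper(b[np.ix_(idx, idx)]))
        if r >= r_obs - 1e-12:
            ge += 1
    return r_obs, (ge + 1) / (n_perm + 1)


def _partial_r(r12: float, r13: float, r23: float) -> float:
    num = r12 - r13 * r23
    denom = math.sqrt(max((1.0 - r13 ** 2) * (1.0 - r23 ** 2), 0.0))
    if denom < 1e-12:
        # d2 == control: numerator vanishes too and the limit is 0
        if abs(num) < 1e-9:
            return 0.0
        raise ValueError("degenerate partial correlation: a matrix is "
                         "perfectly correlated with the control")
    return num / denom


def partial_mantel(d1: pd.DataFrame, d2: pd.DataFrame,
                   control: pd.DataFrame, n_perm: int = 9999,
                   seed: int = 0) -> tuple[float, float]:
    """Partial Mantel test of d1 x d2 given a control matrix.

    The partial r is computed from the three pairwise Mantel correlations;
    the permutation null relabels d2 (rows and columns jointly) while d1
    and the control stay fixed, recomputing r(d1,d2) and r(d2,control)
    each time.  One-tailed upper p.
    """
    a, b = _check_pair(d1, d2)
    _, c = _check_pair(d1, control)
    ua, ub, uc = _upper(a), _upper(b), _upper(c)
    r13 = _pearson(ua, uc)
    if abs(r13) >= 1.0 - 1e-12:
        raise ValueError("d1 and control are perfectly correlated")
    r_obs = _partial_r(_pearson(ua, ub), r13, _pearson(ub, uc))
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    ge = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        bp = b[np.ix_(idx, idx)]
        ubp = _upper(bp)
        r = _partial_r(_pearson(ua, ubp), r13, _pearson(ubp, uc))
        if r >= r_obs - 1e-12:
            ge += 1
    return r_obs, (ge + 1) / (n_perm + 1)


def linearize_fst(fst: pd.DataFrame) -> pd.DataFrame:
    """Rousset's F_ST / (1 - F_ST) transform for distance-based tests."""
    m = fst.to_numpy(dtype=float)
    out = m / (1.0 - m)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=fst.index, columns=fst.columns)
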