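"""Distance-matrix permutation tests linking genetics, geography and phenotype.

Builds great-circle geographic distance matrices and runs Mantel and
partial Mantel permutation tests (Pearson correlation of vectorized
upper triangles, simultaneous row/column permutation of one matrix).
The integrated report reproduces the within-cluster matrix-regression
table: per genetic cluster, genetic distance is tested against dorsal
color, geography, side pattern and ventral pattern, with partial tests
controlling for geography.  Partial Mantel tests are known to inflate
type-I error under spatial autocorrelation, so the report is meant to be
read alongside the plain pairwise tests.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen import DistanceBundle

__all__ = [
    "MantelResult",
    "Table1Report",
    "geographic_distance_matrix",
    "mantel",
    "partial_mantel",
    "table1_analysis",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    matrices_id: tuple
    method: str = "mantel"


def geographic_distance_matrix(latitudes, longitudes) -> np.ndarray:
    """Haversine great-circle distances (km) between coordinate pairs."""
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude out of [-90, 90]")
    if np.any((lon < -180) | (lon > 180)):
        raise ValueError("longitude out of [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _check_distance_matrix(X, name):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError(f"{name} must be square")
    if X.shape[0] < 4:
        raise ValueError(f"{name} must be at least 4x4")
    if not np.allclose(X, X.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(X), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return X


def _triangle(X):
    iu = np.triu_indices(X.shape[0], k=1)
    return X[iu]


def _pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt((a * a).sum()), np.sqrt((b * b).sum())
    if na == 0 or nb == 0:
        raise ValueError("degenerate matrix: zero-variance upper triangle")
    return float((a * b).sum() / (na * nb))


def _permuted_triangles(Y, perms):
    """Upper triangles of Y under a batch of simultaneous row/col permutations."""
    perms = np.asarray(perms)
    Yp = Y[perms[:, :, None], perms[:, None, :]]
    iu = np.triu_indices(Y.shape[0], k=1)
    return Yp[:, iu[0], iu[1]]


def _batch_pearson(a, B):
    """Pearson correlation of vector ``a`` with each row of ``B``."""
    a = a - a.mean()
    B = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((a * a).sum())
    nB = np.sqrt((B * B).sum(axis=1))
    return (B @ a) / (na * nB)


def _tail_count(stats, observed, tail):
    tol = 1e-12
    if tail == "greater":
        return int((stats >= observed - tol).sum())
    if tail == "two-sided":
        return int((np.abs(stats) >= abs(observed) - tol).sum())
    raise ValueError(f"unknown tail {tail!r}")


def mantel(
    X,
    Y,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "greater",
    exhaustive: bool = False,
    labels: tuple = ("X", "Y"),
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    The statistic is the Pearson correlation of the vectorized upper
    triangles; the null distribution permutes rows and columns of Y with a
    shared permutation.  The sampled p-value uses the add-one convention
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm), so p is never 0.  In
    exhaustive mode all n! permutations are enumerated and the p-value is
    the exact fraction of the permutation distribution (the identity
    permutation included) meeting the tail criterion.
    """
    X = _check_distance_matrix(X, "X")
    Y = _check_distance_matrix(Y, "Y")
    if X.shape != Y.shape:
        raise ValueError("X and Y must be conformable")
    xt, yt = _triangle(X), _triangle(Y)
    r_obs = _pearson(xt, yt)
    n = X.shape[0]
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))))
        stats = _batch_pearson(xt, _permuted_triangles(Y, perms))
        p = _tail_count(stats, r_obs, tail) / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        stats = _batch_pearson(xt, _permuted_triangles(Y, perms))
        p = (1 + _tail_count(stats, r_obs, tail)) / (1 + n_perm)
        n_used = n_perm
    return MantelResult(r=r_obs, p=float(p), n_perm=n_used, tail=tail, matrices_id=tuple(labels))


def _residual_matrix(Y, Z):
    """Square symmetric zero-diagonal matrix of Y-triangle residuals on Z."""
    yt, zt = _triangle(Y), _triangle(Z)
    zc = zt - zt.mean()
    denom = (zc * zc).sum()
    slope = (yt - yt.mean()) @ zc / denom
    resid = yt - yt.mean() - slope * zc
    n = Y.shape[0]
    R = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    R[iu] = resid
    return R + R.T


def partial_mantel(
    X,
    Y,
    Z,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "greater",
    labels: tuple = ("X", "Y", "Z"),
) -> MantelResult:
    """Partial Mantel test of X vs Y controlling for Z.

    The observed statistic is the first-order partial Pearson correlation
    r_XY.Z of the upper triangles, which equals the plain correlation of
    the X-on-Z and Y-on-Z triangle residuals.  The null permutes the
    residual matrix of Y on Z (residuals arranged back into square form,
    rows and columns permuted together) and recorrelates with the X
    residuals.
    """
    X = _check_distance_matrix(X, "X")
    Y = _check_distance_matrix(Y, "Y")
    Z = _check_distance_matrix(Z, "Z")
    if not (X.shape == Y.shape == Z.shape):
        raise ValueError("X, Y, Z must be conformable")
    xt, yt, zt = _triangle(X), _triangle(Y), _triangle(Z)
    rxy, rxz, ryz = _pearson(xt, yt), _pearson(xt, zt), _pearson(yt, zt)
    if abs(abs(rxz) - 1) < 1e-12 or abs(abs(ryz) - 1) < 1e-12:
        raise ValueError("Z collinear with X or Y")
    r_obs = (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))
    RX = _residual_matrix(X, Z)
    RY = _residual_matrix(Y, Z)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    stats = _batch_pearson(_triangle(RX), _permuted_triangles(RY, perms))
    p = (1 + _tail_count(stats, r_obs, tail)) / (1 + n_perm)
    return MantelResult(
        r=r_obs, p=float(p), n_perm=n_perm, tail=tail, matrices_id=tuple(labels), method="partial_mantel"
    )


PHENOTYPE_MATRICES = ("dorsal_color", "geographic", "side_pattern", "ventral_pattern")


@dataclass
class Table1Report:
    rows: pd.DataFrame
    n_individuals: int
    skipped_groups: list


def table1_analysis(
    bundle: DistanceBundle,
    grouping: dict,
    photo_ok: dict | None = None,
    n_perm: int = 999,
    seed: int = 0,
    min_group_size: int = 4,
) -> Table1Report:
    """Within-cluster Mantel regression report.

    For each group (genetic cluster), genetic distance is tested against
    dorsal color, geographic, side-pattern and ventral-pattern distance;
    partial Mantel tests control for geography.  Individuals with
    ``photo_ok`` False are excluded before any test; groups smaller than
    ``min_group_size`` are skipped with a warning.  The variable with the
    highest Mantel r in each group is flagged.
    """
    usable = [
        i
        for i, ind in enumerate(bundle.individuals)
        if (photo_ok is None or photo_ok.get(ind, True)) and ind in grouping
    ]
    sub = bundle.subset(usable)
    groups: dict[str, list] = {}
    for i, ind in enumerate(sub.individuals):
        groups.setdefault(str(grouping[ind]), []).append(i)
    rows, skipped = [], []
    rng = np.random.default_rng(seed)
    for group in sorted(groups):
        idx = groups[group]
        if len(idx) < min_group_size:
            warnings.warn(f"group {group!r} has fewer than {min_group_size} individuals; skipped")
            skipped.append(group)
            continue
        gsub = sub.subset(idx)
        gen = gsub.matrices["genetic"]
        geo = gsub.matrices["geographic"]
        group_rows = []
        for name in PHENOTYPE_MATRICES:
            X = gsub.matrices[name]
            res = mantel(
                gen, X, n_perm=n_perm, seed=int(rng.integers(2**31)), labels=("genetic", name)
            )
            row = {
                "group": group,
                "x_matrix": name,
                "n": len(idx),
                "mantel_r": res.r,
                "p": res.p,
            }
            if name != "geographic":
                pres = partial_mantel(
                    gen, X, geo, n_perm=n_perm, seed=int(rng.integers(2**31)),
                    labels=("genetic", name, "geographic"),
                )
                row["partial_r_given_geography"] = pres.r
                row["partial_p_given_geography"] = pres.p
            else:
                row["partial_r_given_geography"] = np.nan
                row["partial_p_given_geography"] = np.nan
            group_rows.append(row)
        best = max(group_rows, key=lambda r: r["mantel_r"])
        for row in group_rows:
            row["max_r_variable"] = row is best
        rows.extend(group_rows)
    return Table1Report(
        rows=pd.DataFrame(rows), n_individuals=len(sub.individuals), skipped_groups=skipped
    )
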