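"""Genotype-likelihood population genomics.

At 1.8-13.9x coverage, hard genotype calls are unreliable, so every
analysis here works from per-site genotype likelihoods: maximum-likelihood
minor-allele frequencies with a likelihood-ratio SNP test, HWE-prior
genotype posteriors, PCA of the posterior-genotype covariance matrix,
expected-mismatch genetic distances, Hudson pairwise FST from
posterior-mean allele frequencies, an admixture EM (individual ancestry
proportions Q and cluster allele frequencies F under HWE), and the Evanno
delta-K rule for choosing the number of clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "GenotypeLikelihoodMatrix",
    "SnpCallResult",
    "AdmixtureFit",
    "DistanceBundle",
    "compute_gl",
    "estimate_maf_and_call_snps",
    "pca_posterior_covariance",
    "genetic_distance_matrix",
    "pairwise_fst",
    "admixture_em",
    "evanno_best_k",
    "assign_admixed_population",
    "match_cluster_labels",
    "write_nexus_distance",
]


@dataclass
class GenotypeLikelihoodMatrix:
    """Per-site, per-individual biallelic genotype log-likelihoods.

    ``log_gl`` has shape (n_individuals, n_sites, 3) for g in {0, 1, 2}
    copies of the minor allele; sites with zero depth carry a flat
    (uninformative) likelihood.
    """

    log_gl: np.ndarray
    depth: np.ndarray
    individuals: list = field(default_factory=list)

    @property
    def n_individuals(self):
        return self.log_gl.shape[0]

    @property
    def n_sites(self):
        return self.log_gl.shape[1]

    def likelihoods(self) -> np.ndarray:
        """Per-site-normalized likelihoods (max scaled to 1)."""
        return np.exp(self.log_gl - self.log_gl.max(axis=2, keepdims=True))


def compute_gl(
    major_counts, minor_counts, error_rate: float, other_counts=None, individuals=None
) -> GenotypeLikelihoodMatrix:
    """Genotype log-likelihoods under a uniform per-read error model.

    With g minor-allele copies, a read reports the major allele with
    probability (1-g/2)(1-e) + (g/2)(e/3) and the minor allele with the
    complementary-allele term; reads showing a third base contribute a
    genotype-independent factor e/3 each (kept for completeness).
    """
    if not 0 < error_rate < 0.25:
        raise ValueError("error_rate must lie in (0, 0.25)")
    nm = np.asarray(major_counts, dtype=float)
    nn = np.asarray(minor_counts, dtype=float)
    no = np.zeros_like(nm) if other_counts is None else np.asarray(other_counts, dtype=float)
    e = error_rate
    g = np.array([0.0, 1.0, 2.0])
    p_major = (1 - g / 2) * (1 - e) + (g / 2) * (e / 3)  # shape (3,)
    p_minor = (g / 2) * (1 - e) + (1 - g / 2) * (e / 3)
    log_gl = (
        nm[..., None] * np.log(p_major)
        + nn[..., None] * np.log(p_minor)
        + no[..., None] * math.log(e / 3)
    )
    depth = (nm + nn + no).astype(int)
    return GenotypeLikelihoodMatrix(
        log_gl=log_gl, depth=depth, individuals=list(individuals or [])
    )


@dataclass
class SnpCallResult:
    maf: np.ndarray  # ML minor-allele frequency per site
    lrt_pvalues: np.ndarray
    is_called: np.ndarray  # passes LRT and coverage thresholds
    posteriors: np.ndarray  # (n_ind, n_sites, 3) HWE-prior genotype posteriors
    expected_genotypes: np.ndarray  # posterior mean minor-allele dosage
    hard_calls: np.ndarray  # argmax genotype where max posterior > threshold, else -1


def _site_maf_em(lik, max_iter=200, tol=1e-10):
    """Per-site ML minor-allele frequency by 1-D EM over genotype likelihoods."""
    n, S, _ = lik.shape
    p = np.full(S, 0.1)
    for _ in range(max_iter):
        prior = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)  # (S, 3)
        post = lik * prior[None, :, :]
        post /= post.sum(axis=2, keepdims=True)
        p_new = (post[:, :, 1].sum(axis=0) + 2 * post[:, :, 2].sum(axis=0)) / (2 * n)
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            break
        p = p_new
    return p


def _loglik_at(lik, p):
    prior = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)
    return np.log((lik * prior[None, :, :]).sum(axis=2)).sum(axis=0)


def estimate_maf_and_call_snps(
    gl: GenotypeLikelihoodMatrix,
    lrt_alpha: float = 1e-6,
    post_threshold: float = 0.95,
    min_cov_frac: float = 0.80,
    min_depth: int = 3,
) -> SnpCallResult:
    """ML minor-allele frequencies, LRT SNP calling, and genotype posteriors.

    The per-site statistic 2(l(p_hat) - l(0)) is referred to a chi-square
    with 1 d.f.; a site is called variable when p < ``lrt_alpha`` and at
    least ``min_cov_frac`` of individuals have depth >= ``min_depth``.
    Genotype posteriors use the HWE prior at p_hat; hard calls are made
    only where the maximum posterior exceeds ``post_threshold``.
    """
    lik = gl.likelihoods()
    p_hat = _site_maf_em(lik)
    ll_hat = _loglik_at(lik, p_hat)
    ll_0 = np.log(lik[:, :, 0]).sum(axis=0)
    stat = np.maximum(0.0, 2 * (ll_hat - ll_0))
    pvals = chi2.sf(stat, df=1)
    coverage_ok = (gl.depth >= min_depth).mean(axis=0) >= min_cov_frac
    is_called = (pvals < lrt_alpha) & coverage_ok
    prior = np.stack([(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2], axis=-1)
    post = lik * prior[None, :, :]
    post /= post.sum(axis=2, keepdims=True)
    expected = post[:, :, 1] + 2 * post[:, :, 2]
    maxpost = post.max(axis=2)
    hard = np.where(maxpost > post_threshold, post.argmax(axis=2), -1)
    return SnpCallResult(
        maf=p_hat,
        lrt_pvalues=pvals,
        is_called=is_called,
        posteriors=post,
        expected_genotypes=expected,
        hard_calls=hard,
    )


@dataclass
class PCAResult:
    covariance: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray  # columns are eigenvectors, sorted by eigenvalue desc

    def scores(self, k: int = 2) -> np.ndarray:
        return self.components[:, :k] * np.sqrt(np.maximum(self.eigenvalues[:k], 0.0))


def pca_posterior_covariance(expected_genotypes, maf) -> PCAResult:
    """PCA of the covariance of posterior-mean genotypes.

    C_ij = (1/S') sum_s (E[g_is] - 2 p_s)(E[g_js] - 2 p_s) / (2 p_s (1 - p_s)),
    over sites with p_s strictly inside (0, 1); eigenpairs returned in
    descending eigenvalue order.
    """
    eg = np.asarray(expected_genotypes, dtype=float)
    p = np.asarray(maf, dtype=float)
    usable = (p > 0) & (p < 1)
    if usable.sum() < 2:
        raise ValueError("need at least two polymorphic sites")
    eg = eg[:, usable]
    p = p[usable]
    centered = (eg - 2 * p) / np.sqrt(2 * p * (1 - p))
    cov = centered @ centered.T / centered.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return PCAResult(covariance=cov, eigenvalues=vals[order], components=vecs[:, order])


def genetic_distance_matrix(posteriors, depth=None):
    """Expected pairwise mismatch distance from genotype posteriors.

    D_ij = (1/S') sum_s sum_{g,g'} P(g_is) P(g'_js) |g - g'| / 2 over the
    sites where both individuals have data (depth > 0); a pair sharing no
    sites gets NaN and is reported.
    """
    post = np.asarray(posteriors, dtype=float)
    n, S, _ = post.shape
    has_data = np.ones((n, S), dtype=bool) if depth is None else np.asarray(depth) > 0
    M = np.abs(np.arange(3)[:, None] - np.arange(3)[None, :]) / 2.0
    num = np.zeros((n, n))
    for g in range(3):
        for gp in range(3):
            if M[g, gp] == 0:
                continue
            num += (post[:, :, g] * has_data) @ (post[:, :, gp] * has_data).T * M[g, gp]
    shared = has_data.astype(float) @ has_data.T.astype(float)
    missing = []
    with np.errstate(invalid="ignore", divide="ignore"):
        D = num / shared
    for i in range(n):
        for j in range(n):
            if shared[i, j] == 0:
                missing.append((i, j))
    return D, missing


def pairwise_fst(expected_genotypes, populations, depth=None) -> pd.DataFrame:
    """Hudson pairwise FST (ratio of averages) from posterior-mean frequencies.

    Per site, with sample frequencies p1, p2 and haploid sample sizes
    n1, n2 (= 2 x individuals with data):
    N_s = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D_s = p1(1-p2) + p2(1-p1), and FST = sum N_s / sum D_s.
    """
    eg = np.asarray(expected_genotypes, dtype=float)
    populations = np.asarray(populations)
    pops = list(dict.fromkeys(populations))
    n, S = eg.shape
    has_data = np.ones((n, S), dtype=bool) if depth is None else np.asarray(depth) > 0
    freq, nhap = {}, {}
    for pop in pops:
        sel = populations == pop
        cnt = has_data[sel].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[pop] = (eg[sel] * has_data[sel]).sum(axis=0) / (2 * cnt)
        nhap[pop] = 2 * cnt
    out = pd.DataFrame(np.zeros((len(pops), len(pops))), index=pops, columns=pops)
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1 :]:
            f1, f2, n1, n2 = freq[p1], freq[p2], nhap[p1], nhap[p2]
            ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(f1) & np.isfinite(f2)
            if not ok.any():
                out.loc[p1, p2] = out.loc[p2, p1] = np.nan
                continue
            a, b, m1, m2 = f1[ok], f2[ok], n1[ok], n2[ok]
            num = (a - b) ** 2 - a * (1 - a) / (m1 - 1) - b * (1 - b) / (m2 - 1)
            den = a * (1 - b) + b * (1 - a)
            out.loc[p1, p2] = out.loc[p2, p1] = float(num.sum() / den.sum())
    return out


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # (n_individuals, K), rows sum to 1
    F: np.ndarray  # (K, n_sites) cluster minor-allele frequencies
    loglik: float
    seed: int
    n_iter: int
    loglik_path: np.ndarray


def admixture_em(
    gl: GenotypeLikelihoodMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 400,
    tol: float = 1e-6,
    freq_floor: float = 1e-5,
) -> AdmixtureFit:
    """EM estimation of admixture proportions from genotype likelihoods.

    Maximizes sum_{i,s} log sum_g L(g_is) P(g_is | Q_i, F_.s) where the
    genotype prior is HWE at the individual allele frequency
    h_is = sum_k Q_ik F_ks.  Each read-level allele copy is fractionally
    assigned to clusters in the E-step; the log-likelihood is checked to be
    non-decreasing at every iteration.  K=1 reduces to the per-site
    minor-allele-frequency model.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    lik = gl.likelihoods()  # (n, S, 3)
    n, S, _ = lik.shape
    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    if K == 1:
        Q = np.ones((n, 1))
    F = rng.uniform(0.05, 0.95, size=(K, S))
    gvals = np.arange(3.0)
    prev_ll = -np.inf
    path = []
    for it in range(1, max_iter + 1):
        H = Q @ F  # (n, S) individual minor-allele frequencies
        H = np.clip(H, freq_floor, 1 - freq_floor)
        prior = np.stack([(1 - H) ** 2, 2 * H * (1 - H), H**2], axis=-1)
        joint = lik * prior
        denom = joint.sum(axis=2, keepdims=True)
        ll = float(np.log(denom).sum() + gl.log_gl.max(axis=2).sum())
        post = joint / denom
        m = post @ gvals  # expected minor-allele dosage (n, S)
        # fractional cluster assignment of minor (a) and major (b) allele copies
        a = Q[:, :, None] * F[None, :, :] / H[:, None, :]  # (n, K, S)
        b = Q[:, :, None] * (1 - F)[None, :, :] / (1 - H)[:, None, :]
        minor_k = m[:, None, :] * a
        major_k = (2 - m)[:, None, :] * b
        F = minor_k.sum(axis=0) / (minor_k.sum(axis=0) + major_k.sum(axis=0))
        F = np.clip(F, freq_floor, 1 - freq_floor)
        if K > 1:
            Q = (minor_k + major_k).sum(axis=2) / (2 * S)
            Q /= Q.sum(axis=1, keepdims=True)
        path.append(ll)
        if ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
            raise RuntimeError(
                f"log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}"
            )
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * abs(ll):
            prev_ll = ll
            break
        prev_ll = ll
    if not np.isfinite(prev_ll):
        raise RuntimeError("non-finite log-likelihood in admixture EM")
    return AdmixtureFit(
        K=K, Q=Q, F=F, loglik=prev_ll, seed=seed, n_iter=len(path), loglik_path=np.array(path)
    )


def evanno_best_k(logliks: dict) -> tuple[int, pd.DataFrame]:
    """Evanno delta-K selection of the number of clusters.

    ``logliks`` maps K to a list of replicate log-likelihoods over a
    contiguous K range.  For interior K,
    dK = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd(L(K));
    the selected K maximizes dK (ties broken toward the smallest K).  The
    method is undefined at the endpoints, so K=1 (and the largest K) can
    never be selected; degenerate replicates (sd exactly 0) raise.
    """
    ks = sorted(logliks)
    if len(ks) < 4:
        raise ValueError("need a contiguous range of at least 4 K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K range must be contiguous")
    reps = {k: np.asarray(logliks[k], dtype=float) for k in ks}
    n_rep = {k: len(v) for k, v in reps.items()}
    if min(n_rep.values()) < 2:
        raise ValueError("need at least 2 replicates per K")
    rows = []
    for k in ks[1:-1]:
        r = min(n_rep[k - 1], n_rep[k], n_rep[k + 1])
        second = np.abs(reps[k + 1][:r] - 2 * reps[k][:r] + reps[k - 1][:r])
        sd = reps[k].std(ddof=1)
        if sd == 0:
            raise ValueError("replicates degenerate; jitter seeds")
        rows.append(
            {
                "K": k,
                "mean_loglik": reps[k].mean(),
                "sd_loglik": sd,
                "delta_k": float(second.mean() / sd),
            }
        )
    table = pd.DataFrame(rows)
    top = table[np.isclose(table.delta_k, table.delta_k.max())]  # tie: smallest K
    return int(top.K.min()), table


def assign_admixed_population(Q, individuals, population_map) -> dict:
    """Assign each population to the cluster holding >50% of its mean ancestry.

    Populations without a majority cluster are labeled ``"unassigned"``.
    """
    Q = np.asarray(Q, dtype=float)
    pops: dict[str, list] = {}
    for i, ind in enumerate(individuals):
        pops.setdefault(population_map[ind], []).append(i)
    out = {}
    for pop, idx in pops.items():
        mean_q = Q[idx].mean(axis=0)
        k = int(np.argmax(mean_q))
        out[pop] = k if mean_q[k] > 0.5 else "unassigned"
    return out


def match_cluster_labels(Q, Q_ref) -> np.ndarray:
    """Permutation of columns of Q best matching Q_ref (Hungarian on L1 cost)."""
    from scipy.optimize import linear_sum_assignment

    Q = np.asarray(Q, dtype=float)
    Q_ref = np.asarray(Q_ref, dtype=float)
    cost = np.array(
        [[np.abs(Q[:, i] - Q_ref[:, j]).sum() for j in range(Q_ref.shape[1])] for i in range(Q.shape[1])]
    )
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(Q.shape[1], dtype=int)
    perm[cols] = rows
    return perm


@dataclass
class DistanceBundle:
    """Aligned square distance matrices over one individual ordering."""

    individuals: list
    matrices: dict  # name -> (n, n) ndarray

    def __post_init__(self):
        n = len(self.individuals)
        for name, m in self.matrices.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"matrix {name!r} shape mismatch")
            if not np.allclose(m, m.T, equal_nan=True):
                raise ValueError(f"matrix {name!r} not symmetric")
            if not np.allclose(np.diag(m), 0.0):
                raise ValueError(f"matrix {name!r} has nonzero diagonal")
            self.matrices[name] = m

    def subset(self, indices) -> "DistanceBundle":
        idx = np.asarray(indices)
        return DistanceBundle(
            individuals=[self.individuals[i] for i in idx],
            matrices={k: v[np.ix_(idx, idx)] for k, v in self.matrices.items()},
        )


def write_nexus_distance(ids, D, path):
    """Export a distance matrix as a NEXUS distances block (for network viewers)."""
    D = np.asarray(D, dtype=float)
    n = len(ids)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={n};\nTAXLABELS\n")
        for i, ident in enumerate(ids, 1):
            fh.write(f"[{i}] '{ident}'\n")
        fh.write(";\nEND;\n\nBEGIN Distances;\n")
        fh.write(f"DIMENSIONS ntax={n};\nFORMAT labels=left diagonal triangle=both;\nMATRIX\n")
        for i, ident in enumerate(ids):
            row = " ".join(f"{D[i, j]:.6f}" for j in range(n))
            fh.write(f"'{ident}' {row}\n")
        fh.write(";\nEND;\n")
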