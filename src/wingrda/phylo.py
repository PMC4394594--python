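"""Phylogenetic covariance, joint Pagel's lambda estimation, and PGLS whitening.

The whitening operator is the symmetric inverse square root of the
lambda-scaled covariance; pre-multiplying both the response and explanatory
matrices by it embeds C^-1 in every cross-product downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import linalg, optimize, stats


@dataclass
class PhyloCovariance:
    """Tree-derived covariance C and its lambda-scaled variant."""

    taxa: list[str]
    C: np.ndarray
    lam: float = 1.0
    C_lam: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if not np.allclose(self.C, self.C.T, atol=1e-10):
            raise ValueError("covariance matrix is not symmetric")
        self.C_lam = lambda_scale(self.C, self.lam)

    def whitener(self) -> np.ndarray:
        """Symmetric C_lam^(-1/2) from eigendecomposition."""
        return inverse_sqrt(self.C_lam)

    def with_lambda(self, lam: float) -> "PhyloCovariance":
        return PhyloCovariance(self.taxa, self.C, lam)


@dataclass
class LambdaEstimate:
    lam: float
    loglik: float
    loglik_0: float
    loglik_1: float
    lr_vs_0: float
    lr_vs_1: float
    p_vs_0: float
    p_vs_1: float
    sigma2: np.ndarray  # profiled per-variable rates at lam


@dataclass
class CenteredData:
    """Per-variable GLS root estimates, ranging scales, and transformed data."""

    taxa: list[str]
    roots: np.ndarray        # (p,) ancestral (root) estimates
    scales: np.ndarray       # (p,) ranging divisors (1.0 where not ranged)
    centered: np.ndarray     # (n, p) centered (and ranged) data
    ranged: np.ndarray       # (p,) bool, which variables were ranged
    whitened: np.ndarray | None = None


def phylo_covariance(tree: dendropy.Tree,
                     taxa: list[str] | None = None) -> PhyloCovariance:
    """C[i, j] = shared root-to-MRCA path length; diagonal = root-to-tip depth."""
    if tree.seed_node is None or len(tree.seed_node.child_nodes()) == 0:
        raise ValueError("tree has no structure")
    if not tree.is_rooted:
        raise ValueError("tree must be rooted")
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if taxa is None:
        taxa = sorted(labels)
    index = {}
    for t in taxa:
        if t in labels:
            index[t] = labels.index(t)
        elif t.replace(" ", "_") in labels:
            index[t] = labels.index(t.replace(" ", "_"))
        else:
            raise ValueError(f"taxon {t!r} not a tip of the tree")
    n = len(taxa)
    # depth of every node; C via postorder accumulation of tip sets
    depth: dict[int, float] = {}
    for nd in tree.preorder_node_iter():
        el = nd.edge.length or 0.0
        depth[id(nd)] = (depth[id(nd.parent_node)] + el) if nd.parent_node else 0.0
    C = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    pos = {labels[index[t]]: k for k, t in enumerate(taxa)}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = ([pos[nd.taxon.label]]
                             if nd.taxon.label in pos else [])
            continue
        kids = [below.pop(id(ch)) for ch in nd.child_nodes()]
        d = depth[id(nd)]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    C[i, kids[b]] = d
                    C[kids[b], i] = d
        below[id(nd)] = [i for kk in kids for i in kk]
    for t in taxa:
        C[pos[labels[index[t]]], pos[labels[index[t]]]] = depth[id(leaves[index[t]])]
    return PhyloCovariance(list(taxa), C, 1.0)


def lambda_scale(C: np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal entries by lambda; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = np.asarray(C, dtype=float)
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def inverse_sqrt(M: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition; M must be SPD."""
    evals, evecs = np.linalg.eigh(np.asarray(M, float))
    if evals[0] <= 0:
        raise ValueError(f"matrix not positive definite "
                         f"(smallest eigenvalue {evals[0]:.3e})")
    return (evecs * (1.0 / np.sqrt(evals))) @ evecs.T


def _profile_loglik(data: np.ndarray, C: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Sum over variables of the BM Gaussian log-likelihood with root mean and
    rate profiled out analytically; returns (logL, sigma2 per variable)."""
    n, p = data.shape
    C_lam = lambda_scale(C, lam)
    try:
        cho = linalg.cho_factor(C_lam, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(f"singular C_lambda at lambda={lam}") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cho, ones)
    denom = ones @ Ci1
    CiX = linalg.cho_solve(cho, data)
    roots = (ones @ CiX) / denom
    resid = data - roots
    sigma2 = np.einsum("ij,ij->j", resid, linalg.cho_solve(cho, resid)) / n
    if np.any(sigma2 <= 0):
        raise ValueError("non-positive profiled variance (constant variable?)")
    ll = -0.5 * np.sum(n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return float(ll), sigma2


def joint_lambda_ml(data: np.ndarray, cov: PhyloCovariance) -> LambdaEstimate:
    """Jointly estimate one lambda for all variables by summing per-variable
    profiled BM log-likelihoods; bounded scalar search on [0, 1]."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    n, p = data.shape
    if n < 4:
        raise ValueError("need at least 4 taxa")
    keep = np.std(data, axis=0) > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} constant variable(s) "
                      "from lambda estimation", stacklevel=2)
        data = data[:, keep]
        if data.shape[1] == 0:
            raise ValueError("all variables constant")
    C = cov.C

    def neg(lam: float) -> float:
        return -_profile_loglik(data, C, lam)[0]

    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    cands = [(float(res.x), -float(res.fun))]
    ll0 = _profile_loglik(data, C, 0.0)[0]
    ll1 = _profile_loglik(data, C, 1.0)[0]
    cands += [(0.0, ll0), (1.0, ll1)]
    lam_hat, ll_hat = max(cands, key=lambda t: t[1])
    _, sigma2 = _profile_loglik(data, C, lam_hat)
    lr0 = 2.0 * (ll_hat - ll0)
    lr1 = 2.0 * (ll_hat - ll1)
    return LambdaEstimate(
        lam=lam_hat, loglik=ll_hat, loglik_0=ll0, loglik_1=ll1,
        lr_vs_0=lr0, lr_vs_1=lr1,
        p_vs_0=float(stats.chi2.sf(max(lr0, 0.0), df=1)),
        p_vs_1=float(stats.chi2.sf(max(lr1, 0.0), df=1)),
        sigma2=sigma2,
    )


def lambda_lr_test(est: LambdaEstimate, tol: float = 1e-6) -> tuple[float, float]:
    """Likelihood-ratio chi-squared (df=1) p-values vs lambda=0 and lambda=1."""
    for lr in (est.lr_vs_0, est.lr_vs_1):
        if lr < -tol:
            raise ValueError(f"negative LR statistic {lr}: optimizer failure")
    p0 = float(stats.chi2.sf(max(est.lr_vs_0, 0.0), df=1))
    p1 = float(stats.chi2.sf(max(est.lr_vs_1, 0.0), df=1))
    return p0, p1


def gls_root(x: np.ndarray, C_lam: np.ndarray) -> float:
    """GLS estimate of the ancestral (root) state of a single variable."""
    cho = linalg.cho_factor(C_lam, lower=True)
    ones = np.ones(len(x))
    Ci1 = linalg.cho_solve(cho, ones)
    return float((Ci1 @ x) / (ones @ Ci1))


def center_and_range(data: np.ndarray, C_lam: np.ndarray,
                     range_flags: np.ndarray | list[bool],
                     taxa: list[str] | None = None) -> CenteredData:
    """Center each variable by its GLS root estimate; divide flagged variables
    by their post-centering max absolute value so they span [-1, 1]."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    n, p = data.shape
    flags = np.asarray(range_flags, dtype=bool)
    if flags.shape != (p,):
        raise ValueError("range_flags length does not match variable count")
    cho = linalg.cho_factor(np.asarray(C_lam, float), lower=True)
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cho, ones)
    denom = ones @ Ci1
    roots = (Ci1 @ data) / denom
    centered = data - roots
    scales = np.ones(p)
    for j in np.flatnonzero(flags):
        m = float(np.max(np.abs(centered[:, j])))
        if m == 0:
            raise ValueError(f"variable {j} has zero range after centering")
        scales[j] = m
    centered = centered / scales
    return CenteredData(taxa=list(taxa) if taxa else [f"t{i}" for i in range(n)],
                        roots=roots, scales=scales, centered=centered,
                        ranged=flags)


def pgls_whiten(centered: CenteredData, C_lam: np.ndarray) -> np.ndarray:
    """Pre-multiply centered data by the symmetric C_lam^(-1/2)."""
    W = inverse_sqrt(C_lam)
    centered.whitened = W @ centered.centered
    return centered.whitened
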