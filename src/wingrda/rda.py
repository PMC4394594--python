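"""Redundancy analysis, variation partitioning, and passive taxon placement.

All inputs are assumed pre-centered (no intercept is fitted) and, for the
phylogenetic analysis, pre-whitened by C_lambda^(-1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import CenteredData

_TOL = 1e-10


@dataclass
class RdaResult:
    canonical_eigenvalues: np.ndarray
    residual_eigenvalues: np.ndarray
    relative_eigenvalues: np.ndarray       # canonical then residual, / total
    canonical_axes: np.ndarray             # (p, k) eigenvectors in Y-space
    residual_axes: np.ndarray
    taxon_scores: np.ndarray               # (n, k) = Yw @ canonical_axes
    fitted_scores: np.ndarray              # (n, k) = Yhat @ canonical_axes
    response_loadings: np.ndarray          # corr(Yw cols, taxon scores)
    explanatory_loadings: np.ndarray       # corr(Xw cols, taxon scores)
    coefficients: np.ndarray               # (m, p) regression of Yw on Xw
    r2: float
    total_variance: float
    axis_p_values: np.ndarray | None = None
    loading_p_values: np.ndarray | None = None

    @property
    def n_canonical(self) -> int:
        return len(self.canonical_eigenvalues)

    def eigenvalue_table(self) -> pd.DataFrame:
        names = ([f"canonical_{k + 1}" for k in range(self.n_canonical)]
                 + [f"non_canonical_{k + 1}"
                    for k in range(len(self.residual_eigenvalues))])
        eig = np.concatenate([self.canonical_eigenvalues,
                              self.residual_eigenvalues])
        return pd.DataFrame({"eigenvalue": eig,
                             "relative_eigenvalue": eig / self.total_variance},
                            index=names)


@dataclass
class VarpartResult:
    adj_r2_a: float          # AR alone
    adj_r2_b: float          # M alone
    adj_r2_ab: float         # AR + M
    n: int
    p_values: dict = field(default_factory=dict)

    @property
    def a_given_b(self) -> float:
        return self.adj_r2_ab - self.adj_r2_b

    @property
    def b_given_a(self) -> float:
        return self.adj_r2_ab - self.adj_r2_a

    @property
    def intersection(self) -> float:
        return self.adj_r2_a + self.adj_r2_b - self.adj_r2_ab

    @property
    def residual(self) -> float:
        return 1.0 - self.adj_r2_ab

    def fractions(self) -> dict[str, float]:
        return {"AR": self.adj_r2_a, "M": self.adj_r2_b,
                "AR+M": self.adj_r2_ab, "AR|M": self.a_given_b,
                "M|AR": self.b_given_a, "AR^M": self.intersection,
                "residual": self.residual}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"adjusted_R2": self.fractions()})
        df["p_value"] = [self.p_values.get(k, np.nan) for k in df.index]
        return df


def _check_xy(Yw: np.ndarray, Xw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Yw = np.atleast_2d(np.asarray(Yw, float))
    Xw = np.asarray(Xw, float)
    if Xw.ndim == 1:
        Xw = Xw[:, None]
    if Yw.shape[0] != Xw.shape[0]:
        raise ValueError("Yw and Xw have different numbers of rows")
    if Yw.shape[0] <= Xw.shape[1]:
        raise ValueError("need more observations than predictors")
    if np.linalg.matrix_rank(Xw) < Xw.shape[1]:
        raise ValueError("explanatory matrix is rank deficient")
    return Yw, Xw


def _safe_corr(cols: np.ndarray, scores: np.ndarray) -> np.ndarray:
    a = cols - cols.mean(axis=0)
    b = scores - scores.mean(axis=0)
    sa = np.sqrt((a ** 2).sum(axis=0))
    sb = np.sqrt((b ** 2).sum(axis=0))
    num = a.T @ b
    den = np.outer(sa, sb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r


def rda(Yw: np.ndarray, Xw: np.ndarray) -> RdaResult:
    """Constrained ordination: PCA of fitted values of a no-intercept
    multivariate regression of Yw on Xw; residual PCA on the remainder."""
    Yw, Xw = _check_xy(Yw, Xw)
    n, p = Yw.shape
    m = Xw.shape[1]
    coef, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    Yhat = Xw @ coef
    resid = Yw - Yhat
    S_can = Yhat.T @ Yhat / (n - 1)
    S_res = resid.T @ resid / (n - 1)
    ev_c, U_c = np.linalg.eigh(S_can)
    ev_c, U_c = ev_c[::-1], U_c[:, ::-1]
    k = min(m, p)
    ev_c, U_c = ev_c[:k], U_c[:, :k]
    ev_r, U_r = np.linalg.eigh(S_res)
    ev_r, U_r = ev_r[::-1], U_r[:, ::-1]
    n_res = int((ev_r > _TOL * max(1.0, abs(ev_r[0]))).sum())
    ev_r, U_r = ev_r[:n_res], U_r[:, :n_res]
    total = float(np.trace(Yw.T @ Yw)) / (n - 1)
    scores = Yw @ U_c
    fitted_scores = Yhat @ U_c
    # orient axes deterministically: largest-|.| fitted score positive
    for j in range(U_c.shape[1]):
        i = int(np.argmax(np.abs(fitted_scores[:, j])))
        if fitted_scores[i, j] < 0:
            U_c[:, j] *= -1
            scores[:, j] *= -1
            fitted_scores[:, j] *= -1
    rel = np.concatenate([ev_c, ev_r]) / total
    r2 = float(np.trace(Yhat.T @ Yhat) / np.trace(Yw.T @ Yw))
    return RdaResult(
        canonical_eigenvalues=ev_c,
        residual_eigenvalues=ev_r,
        relative_eigenvalues=rel,
        canonical_axes=U_c,
        residual_axes=U_r,
        taxon_scores=scores,
        fitted_scores=fitted_scores,
        response_loadings=_safe_corr(Yw, scores),
        explanatory_loadings=_safe_corr(Xw, scores),
        coefficients=coef,
        r2=r2,
        total_variance=total,
    )


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R2)(n - 1)/(n - m - 1)."""
    if not 0.0 <= r2 <= 1.0 + 1e-12:
        raise ValueError(f"R2 out of range: {r2}")
    if n - m - 1 <= 0:
        raise ValueError(f"too few observations (n={n}) for {m} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _model_r2(Yw: np.ndarray, Xw: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    Yhat = Xw @ coef
    return float(np.trace(Yhat.T @ Yhat) / np.trace(Yw.T @ Yw))


def varpart(Yw: np.ndarray, ar_w: np.ndarray, m_w: np.ndarray,
            n_perm: int = 0, seed: int | None = None) -> VarpartResult:
    """Partition adjusted R2 of Yw between AR, M, their intersection, and a
    residual.  Permutation p-values (rows of Yw permuted) are attached for
    the marginal and joint models when ``n_perm > 0``."""
    ar_w = np.asarray(ar_w, float).reshape(-1, 1)
    m_w = np.asarray(m_w, float).reshape(-1, 1)
    Yw = np.atleast_2d(np.asarray(Yw, float))
    n = Yw.shape[0]
    X_ab = np.hstack([ar_w, m_w])
    r2_a = _model_r2(Yw, ar_w)
    r2_b = _model_r2(Yw, m_w)
    r2_ab = _model_r2(Yw, X_ab)
    res = VarpartResult(
        adj_r2_a=adjusted_r2(r2_a, n, 1),
        adj_r2_b=adjusted_r2(r2_b, n, 1),
        adj_r2_ab=adjusted_r2(r2_ab, n, 2),
        n=n,
    )
    if n_perm:
        if seed is None:
            raise ValueError("seed required for permutation tests")
        rng = np.random.default_rng(seed)
        hits = {"AR": 0, "M": 0, "AR+M": 0}
        obs = {"AR": r2_a, "M": r2_b, "AR+M": r2_ab}
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Yp = Yw[perm]
            if _model_r2(Yp, ar_w) >= obs["AR"]:
                hits["AR"] += 1
            if _model_r2(Yp, m_w) >= obs["M"]:
                hits["M"] += 1
            if _model_r2(Yp, X_ab) >= obs["AR+M"]:
                hits["AR+M"] += 1
        res.p_values = {k: (1 + v) / (1 + n_perm) for k, v in hits.items()}
    return res


def permutation_tests(Yw: np.ndarray, Xw: np.ndarray, n_perm: int = 999,
                      seed: int | None = None) -> dict[str, np.ndarray]:
    """Permute rows of Yw; recompute per-axis canonical eigenvalues and
    per-variable |loading| on each axis; p = (1 + #(perm >= obs))/(1 + n_perm)."""
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if seed is None:
        raise ValueError("seed required for permutation tests")
    Yw, Xw = _check_xy(Yw, Xw)
    if np.allclose(Yw, Yw[0], atol=1e-12):
        raise ValueError("response has no variance across taxa")
    obs = rda(Yw, Xw)
    k = obs.n_canonical
    rng = np.random.default_rng(seed)
    axis_hits = np.zeros(k)
    load_hits = np.zeros_like(obs.explanatory_loadings)
    obs_load = np.abs(obs.explanatory_loadings)
    for _ in range(n_perm):
        perm = rng.permutation(Yw.shape[0])
        r = rda(Yw[perm], Xw)
        axis_hits += r.canonical_eigenvalues >= obs.canonical_eigenvalues
        load_hits += np.abs(r.explanatory_loadings) >= obs_load
    return {
        "axis_p": (1 + axis_hits) / (1 + n_perm),
        "loading_p": (1 + load_hits) / (1 + n_perm),
    }


def place_passive_taxa(scores: np.ndarray, rda_res: RdaResult,
                       centering: CenteredData, ar_index: int = 0,
                       taxa: list[str] | None = None) -> pd.DataFrame:
    """Project supplementary (already centered/transformed) response rows into
    the canonical space and back-predict AR on the natural scale.

    The AR prediction direction is the least-squares fit of the whitened AR
    column onto the extant canonical taxon scores; inversion then unwinds,
    in order, the ranging scale, the GLS root centering, and the log_e
    transform of AR.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.shape[1] != rda_res.canonical_axes.shape[0]:
        raise ValueError("supplementary scores have wrong number of columns")
    z = scores @ rda_res.canonical_axes
    Z = rda_res.taxon_scores
    if centering.whitened is None:
        raise ValueError("centering must carry the whitened explanatory data")
    arw = centering.whitened[:, ar_index]
    g, *_ = np.linalg.lstsq(Z, arw, rcond=None)
    fitted_arw = z @ g
    log_ar = (fitted_arw * centering.scales[ar_index]
              + centering.roots[ar_index])
    idx = taxa if taxa is not None else [f"passive_{i}" for i in range(len(z))]
    out = pd.DataFrame(z, index=idx,
                       columns=[f"RDA{k + 1}" for k in range(z.shape[1])])
    out["fitted_log_AR"] = log_ar
    out["fitted_AR"] = np.exp(log_ar)
    return out


def root_ar(centering: CenteredData, ar_index: int = 0) -> float:
    """Back-transformed GLS root estimate of log AR (natural AR scale)."""
    return float(np.exp(centering.roots[ar_index]))
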