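"""Run the lambda -> whiten -> RDA/VARPART pipeline over a tree set and pick
the representative tree (adjusted R2 terms closest to the ensemble means)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import phylo, rda
from .io import TreeSet

logger = logging.getLogger(__name__)

#: the seven partition terms used for the representativeness distance
TERMS = ("AR", "M", "AR+M", "AR|M", "M|AR", "AR^M", "residual")


@dataclass
class TreeRecord:
    index: int
    lam: float
    loglik: float
    p_vs_0: float
    p_vs_1: float
    fractions: dict[str, float]
    explanatory_loadings: np.ndarray
    rda_result: rda.RdaResult
    centering_x: phylo.CenteredData
    centering_y: phylo.CenteredData
    cov: phylo.PhyloCovariance


@dataclass
class EnsembleResult:
    records: list[TreeRecord]
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def term_matrix(self) -> np.ndarray:
        return np.array([[r.fractions[t] for t in TERMS] for r in self.records])

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([r.lam for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.term_matrix, columns=list(TERMS))
        df.insert(0, "lambda", self.lambdas)
        df.insert(0, "tree", [r.index for r in self.records])
        return df


def run_tree(k: int, tree, taxa: list[str], Y: np.ndarray, X: np.ndarray,
             range_y: bool = False) -> TreeRecord:
    """Full single-tree pipeline: covariance, joint lambda, centering/ranging,
    whitening, RDA and VARPART.  ``Y`` is the retained PCO block and ``X`` the
    (log AR, log M) pair for the same (extant) taxa."""
    cov = phylo.phylo_covariance(tree, taxa=taxa)
    est = phylo.joint_lambda_ml(np.hstack([Y, X]), cov)
    cov_l = cov.with_lambda(est.lam)
    cen_y = phylo.center_and_range(
        Y, cov_l.C_lam, np.full(Y.shape[1], range_y), taxa=taxa)
    cen_x = phylo.center_and_range(
        X, cov_l.C_lam, np.ones(X.shape[1], bool), taxa=taxa)
    Yw = phylo.pgls_whiten(cen_y, cov_l.C_lam)
    Xw = phylo.pgls_whiten(cen_x, cov_l.C_lam)
    res = rda.rda(Yw, Xw)
    vp = rda.varpart(Yw, Xw[:, 0], Xw[:, 1])
    return TreeRecord(
        index=k, lam=est.lam, loglik=est.loglik,
        p_vs_0=est.p_vs_0, p_vs_1=est.p_vs_1,
        fractions=vp.fractions(),
        explanatory_loadings=res.explanatory_loadings,
        rda_result=res, centering_x=cen_x, centering_y=cen_y, cov=cov_l)


def run_ensemble(taxa: list[str], Y: np.ndarray, X: np.ndarray,
                 trees: TreeSet, range_y: bool = False,
                 max_failure_rate: float = 0.05) -> EnsembleResult:
    """One full pipeline run per tree; failures are collected and reported,
    and the run errors out if more than ``max_failure_rate`` of trees fail."""
    records: list[TreeRecord] = []
    failures: list[tuple[int, str]] = []
    for k, tree in enumerate(trees):
        try:
            records.append(run_tree(k, tree, taxa, Y, X, range_y=range_y))
        except Exception as exc:  # noqa: BLE001 - logged and accounted
            logger.warning("tree %d failed: %s", k, exc)
            failures.append((k, str(exc)))
    if len(failures) > max_failure_rate * len(trees):
        raise RuntimeError(
            f"{len(failures)}/{len(trees)} trees failed: {failures[:5]}")
    if not records:
        raise RuntimeError("no trees succeeded")
    return EnsembleResult(records=records, failures=failures)


def select_representative(er: EnsembleResult) -> int:
    """Index (into ``er.records``) of the tree whose partition-term vector is
    closest (Euclidean) to the component-wise means; ties -> lowest index."""
    tm = er.term_matrix
    dist = np.linalg.norm(tm - tm.mean(axis=0), axis=1)
    return int(np.argmin(dist))


def summarize_ensemble(er: EnsembleResult) -> dict:
    """Per-term mean/min/max/representative value, plus lambda and loading
    distributions for histogram / scatter export."""
    tm = er.term_matrix
    rep = select_representative(er)
    terms = {}
    for j, t in enumerate(TERMS):
        terms[t] = {
            "mean": float(tm[:, j].mean()),
            "min": float(tm[:, j].min()),
            "max": float(tm[:, j].max()),
            "representative": float(tm[rep, j]),
        }
    loadings = np.array([r.explanatory_loadings for r in er.records])
    return {
        "n_trees": len(er.records),
        "n_failures": len(er.failures),
        "representative_index": er.records[rep].index,
        "terms": terms,
        "lambda": {
            "mean": float(er.lambdas.mean()),
            "sd": float(er.lambdas.std(ddof=1)) if len(er.records) > 1 else 0.0,
            "values": er.lambdas.tolist(),
        },
        "explanatory_loadings": loadings.tolist(),
    }
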