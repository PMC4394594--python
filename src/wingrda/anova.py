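"""Simulation-based phylogenetic ANOVA with Holm multiple-comparison adjustment.

The null distribution of the F statistic is built by simulating the trait
under Brownian motion on the tree (rate and root from the observed trait's
GLS fit) while holding group membership fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .phylo import PhyloCovariance


@dataclass
class AnovaResult:
    f_observed: float
    group_labels: list
    group_sizes: list[int]
    n_sim: int
    f_null: np.ndarray
    p_value: float
    n_degenerate: int = 0
    p_holm: float | None = None


def anova_f(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way F: between-group mean square over within-group mean square."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    g = len(labels)
    n = len(values)
    if g < 2:
        raise ValueError("need at least 2 groups")
    if n <= g:
        raise ValueError("total n must exceed the number of groups")
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for k in range(g):
        v = values[inv == k]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    if ss_within <= 0:
        raise ValueError("zero within-group variance: F is infinite")
    ms_between = ss_between / (g - 1)
    ms_within = ss_within / (n - g)
    return float(ms_between / ms_within)


def phylogenetic_anova(trait: np.ndarray, groups: np.ndarray,
                       cov: PhyloCovariance, n_sim: int = 1000,
                       seed: int | None = None) -> AnovaResult:
    """Simulation-based phylogenetic ANOVA.

    p = (1 + #(F_sim >= F_obs)) / (1 + n_sim) over ``n_sim`` Brownian-motion
    simulations on the tree; degenerate simulations (zero within-group
    variance) are discarded and counted.
    """
    if seed is None:
        raise ValueError("seed required for simulation")
    trait = np.asarray(trait, float)
    groups = np.asarray(groups)
    n = len(trait)
    if cov.C.shape[0] != n:
        raise ValueError("covariance size does not match trait length")
    f_obs = anova_f(trait, groups)
    # GLS fit of root and BM rate on the same tree
    cho = linalg.cho_factor(cov.C_lam, lower=True)
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cho, ones)
    root = float((Ci1 @ trait) / (ones @ Ci1))
    resid = trait - root
    sigma2 = float(resid @ linalg.cho_solve(cho, resid) / n)
    L = np.linalg.cholesky(cov.C_lam)
    rng = np.random.default_rng(seed)
    sims = root + (L @ rng.standard_normal((n, n_sim))) * np.sqrt(sigma2)
    f_null = []
    n_degen = 0
    for j in range(n_sim):
        try:
            f_null.append(anova_f(sims[:, j], groups))
        except ValueError:
            n_degen += 1
    f_null = np.asarray(f_null)
    n_eff = len(f_null)
    p = (1 + int((f_null >= f_obs).sum())) / (1 + n_eff)
    labels, counts = np.unique(groups, return_counts=True)
    return AnovaResult(
        f_observed=f_obs, group_labels=list(labels),
        group_sizes=[int(c) for c in counts], n_sim=n_eff,
        f_null=f_null, p_value=float(p), n_degenerate=n_degen)


def holm_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Step-down Holm adjustment: sort ascending, multiply p_(k) by
    (m - k), enforce monotonicity, cap at 1."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def binarize_character(scores: np.ndarray) -> np.ndarray:
    """Presence/absence grouping: score > 0 (missing scores not allowed)."""
    scores = np.asarray(scores)
    if np.any(scores < 0):
        raise ValueError("missing scores cannot be binarized")
    return (scores > 0).astype(int)
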