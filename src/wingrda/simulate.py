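"""Synthetic trees, traits and character matrices with known ground truth.

Pure-birth trees provide topology; continuous traits are Brownian draws with
tunable signal (lambda-scaled covariance); ordinal characters come from a
threshold model on a latent liability correlated with the wing-shape trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .io import CHARACTERS, CharacterMatrix, TraitTable, TreeSet
from .phylo import lambda_scale, phylo_covariance


@dataclass
class SimConfig:
    n_taxa: int = 74
    n_extinct: int = 3
    birth_rate: float = 1.0
    lambda_true: float = 0.7
    sigma2_ar: float = 0.2
    sigma2_mass: float = 1.0
    root_log_ar: float = 2.0
    root_log_mass: float = 0.0
    beta: float | list[float] = 1.0
    thresholds: tuple[float, ...] = (-0.5, 0.5)
    n_trees: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValueError("thresholds must be strictly increasing")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def simulate_pure_birth_tree(n: int, birth_rate: float = 1.0,
                             seed: int | None = None,
                             labels: list[str] | None = None) -> dendropy.Tree:
    """Yule tree: exponential waiting times, uniformly chosen splitting
    lineage, tips extended to the final event time (ultrametric)."""
    if n < 2:
        raise ValueError("need at least 2 tips")
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    # active lineages, each recorded with the time its edge started
    first = [tree.seed_node.new_child(), tree.seed_node.new_child()]
    t_now = 0.0
    active: list[tuple[dendropy.Node, float]] = [(nd, 0.0) for nd in first]
    while len(active) < n:
        t_now += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, t0 = active.pop(i)
        node.edge.length = t_now - t0
        active.append((node.new_child(), t_now))
        active.append((node.new_child(), t_now))
    t_now += rng.exponential(1.0 / (birth_rate * len(active)))
    names = labels if labels is not None else [f"t{k + 1}" for k in range(n)]
    if len(names) != n:
        raise ValueError("label count does not match tip count")
    for k, (node, t0) in enumerate(active):
        node.edge.length = t_now - t0
        node.taxon = tns.new_taxon(label=names[k])
    return tree


def simulate_traits(tree: dendropy.Tree, lambda_true: float, sigma2: float,
                    root: float = 0.0, seed: int | None = None,
                    taxa: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Draw one trait per tip from N(root, sigma2 * C_lambda)."""
    if seed is None:
        raise ValueError("seed is mandatory")
    cov = phylo_covariance(tree, taxa=taxa)
    C_lam = lambda_scale(cov.C, lambda_true)
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        return list(cov.taxa), np.full(len(cov.taxa), float(root))
    L = np.linalg.cholesky(C_lam + 1e-12 * np.eye(len(cov.taxa)))
    x = root + np.sqrt(sigma2) * (L @ rng.standard_normal(len(cov.taxa)))
    return list(cov.taxa), x


def simulate_characters(tree: dendropy.Tree, latent: np.ndarray,
                        beta: float | list[float],
                        thresholds: tuple[float, ...] = (-0.5, 0.5),
                        seed: int | None = None,
                        taxa: list[str] | None = None,
                        extinct: np.ndarray | None = None) -> CharacterMatrix:
    """Threshold model: per character, liability = beta * latent + independent
    Brownian noise on the tree; score = number of thresholds below liability."""
    if seed is None:
        raise ValueError("seed is mandatory")
    if list(thresholds) != sorted(set(thresholds)):
        raise ValueError("thresholds must be strictly increasing")
    betas = (np.full(len(CHARACTERS), float(beta))
             if np.isscalar(beta) else np.asarray(beta, float))
    if not np.all(np.isfinite(betas)):
        raise ValueError("beta must be finite")
    cov = phylo_covariance(tree, taxa=taxa)
    names = list(cov.taxa)
    latent = np.asarray(latent, float)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov.C + 1e-12 * np.eye(len(names)))
    scores = np.zeros((len(names), len(CHARACTERS)), dtype=int)
    cuts = np.asarray(thresholds, float)
    for j, ch in enumerate(CHARACTERS):
        noise = L @ rng.standard_normal(len(names))
        liability = betas[j] * latent + noise
        col_cuts = cuts[:1] if ch == "iip1" else cuts  # iip1 is binary
        scores[:, j] = (liability[:, None] > col_cuts[None, :]).sum(axis=1)
    if extinct is None:
        extinct = np.zeros(len(names), bool)
    return CharacterMatrix(names, scores, extinct)


def make_synthetic_study(config: SimConfig) -> tuple[CharacterMatrix, TraitTable, TreeSet]:
    """A full study-shaped dataset: n taxa (last ``n_extinct`` flagged extinct
    with traits masked), six thresholded characters, and a tree set of
    independent pure-birth trees over the extant taxa."""
    rng = np.random.default_rng(config.seed)
    n = config.n_taxa
    names = [f"t{k + 1}" for k in range(n)]
    extinct = np.zeros(n, bool)
    if config.n_extinct:
        extinct[-config.n_extinct:] = True
    base = simulate_pure_birth_tree(n, config.birth_rate,
                                   seed=int(rng.integers(2 ** 31)), labels=names)
    _, log_ar = simulate_traits(base, config.lambda_true, config.sigma2_ar,
                                root=config.root_log_ar,
                                seed=int(rng.integers(2 ** 31)), taxa=names)
    _, log_m = simulate_traits(base, config.lambda_true, config.sigma2_mass,
                               root=config.root_log_mass,
                               seed=int(rng.integers(2 ** 31)), taxa=names)
    cm = simulate_characters(base, log_ar - log_ar.mean(), config.beta,
                             config.thresholds,
                             seed=int(rng.integers(2 ** 31)), taxa=names,
                             extinct=extinct)
    ar = np.exp(log_ar)
    mass = np.exp(log_m)
    ar[extinct] = np.nan
    mass[extinct] = np.nan
    tt = TraitTable(names, ar, mass)
    extant = [t for t, e in zip(names, extinct) if not e]
    tl = dendropy.TreeList()
    for _ in range(config.n_trees):
        tr = simulate_pure_birth_tree(len(extant), config.birth_rate,
                                      seed=int(rng.integers(2 ** 31)),
                                      labels=extant)
        tl.append(dendropy.Tree.get(data=tr.as_string(schema="newick"),
                                    schema="newick", rooting="force-rooted",
                                    taxon_namespace=tl.taxon_namespace))
    return cm, tt, TreeSet(tl)
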