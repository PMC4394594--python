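"""Principal coordinates of Hamming distances with Cailliez correction.

Embeds a categorical character matrix in a Euclidean space so it can feed a
linear constrained ordination; also computes projections of the original
characters onto the retained axes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CHARACTERS, CharacterMatrix

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-10


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("negative distances")
        self.values = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


@dataclass
class PcoResult:
    taxa: list[str]
    eigenvalues: np.ndarray          # all eigenvalues, descending
    relative: np.ndarray             # positive eigenvalues / their sum
    cumulative: np.ndarray
    coordinates: np.ndarray          # (n, n_axes)
    cailliez_constant: float
    n_axes: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCO{k + 1}" for k in range(self.n_axes)]
        return pd.DataFrame(self.coordinates, index=self.taxa, columns=cols)

    def eigenvalue_table(self) -> pd.DataFrame:
        """Relative and cumulative eigenvalues for the retained axes."""
        return pd.DataFrame(
            {"relative_eigenvalue": self.relative[: self.n_axes],
             "cumulative_eigenvalue": self.cumulative[: self.n_axes]},
            index=[f"PCO{k + 1}" for k in range(self.n_axes)])


def hamming_distances(cm: CharacterMatrix) -> DistanceMatrix:
    """Pairwise proportion of mismatching scores over shared non-missing characters.

    A multistate mismatch counts 1 regardless of the score difference.
    """
    if cm.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    s = cm.scores
    present = s != -1
    shared = present[:, None, :] & present[None, :, :]
    n_shared = shared.sum(axis=2)
    if np.any(n_shared == 0):
        i, j = np.argwhere(n_shared == 0)[0]
        raise ValueError(
            f"taxa {cm.taxa[i]!r} and {cm.taxa[j]!r} share no scored characters")
    mism = ((s[:, None, :] != s[None, :, :]) & shared).sum(axis=2)
    d = mism / n_shared
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(cm.taxa), d)


def gower_center(d_squared: np.ndarray) -> np.ndarray:
    """B = -1/2 J D2 J with J = I - 11'/n."""
    n = d_squared.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d_squared @ j


def _min_gower_eigenvalue(d: np.ndarray) -> float:
    return float(np.linalg.eigvalsh(gower_center(d ** 2))[0])


def cailliez_correction(d: DistanceMatrix) -> tuple[DistanceMatrix, float]:
    """Smallest additive constant making off-diagonal distances Euclidean-embeddable.

    The constant is the largest real eigenvalue of the 2n x 2n block matrix
    ``[[0, 2*D1], [-I, -4*D2]]`` where D1 and D2 are the Gower-centered
    squared and plain distance matrices (Cailliez 1983).  Returns ``c = 0``
    when the input is already Euclidean.
    """
    dv = d.values
    if _min_gower_eigenvalue(dv) >= -1e-9:
        return d, 0.0
    n = dv.shape[0]
    d1 = gower_center(dv ** 2)
    d2 = gower_center(dv)
    big = np.block([[np.zeros((n, n)), 2.0 * d1],
                    [-np.eye(n), -4.0 * d2]])
    c = float(np.max(np.linalg.eigvals(big).real))
    corrected = dv + c
    np.fill_diagonal(corrected, 0.0)
    return DistanceMatrix(list(d.taxa), corrected), c


def _orient_axes(coords: np.ndarray) -> np.ndarray:
    """Fix arbitrary axis signs: weight coordinates by taxon order (1..n)
    and flip any axis whose weighted sum is negative."""
    w = np.arange(1, coords.shape[0] + 1, dtype=float)
    signs = np.where(w @ coords < 0, -1.0, 1.0)
    return coords * signs


def principal_coordinates(d: DistanceMatrix, n_axes: int = 12, *,
                          cailliez_constant: float = 0.0,
                          orient: bool = True) -> PcoResult:
    """Metric MDS: eigendecomposition of the Gower-centered squared distances.

    Coordinates are eigenvectors scaled by the square root of their
    eigenvalue; only axes with positive eigenvalues are ever retained.
    Relative eigenvalues are fractions of the positive-eigenvalue sum.
    """
    b = gower_center(d.values ** 2)
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > _EIG_TOL * max(1.0, float(evals[0]))
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        logger.warning("requested %d axes but only %d positive eigenvalues; "
                       "retaining %d", n_axes, n_pos, n_pos)
        warnings.warn(f"retaining {n_pos} axes (only {n_pos} positive eigenvalues)",
                      stacklevel=2)
        n_axes = n_pos
    possum = float(evals[pos].sum())
    relative = np.where(pos, evals / possum, 0.0)
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    if orient:
        coords = _orient_axes(coords)
    return PcoResult(
        taxa=list(d.taxa),
        eigenvalues=evals,
        relative=relative,
        cumulative=np.cumsum(relative),
        coordinates=coords,
        cailliez_constant=cailliez_constant,
        n_axes=n_axes,
    )


def character_projections(cm: CharacterMatrix, pco: PcoResult,
                          scaling: str = "correlation") -> pd.DataFrame:
    """Signed projections of the raw character scores onto the PCO axes.

    ``scaling='correlation'`` gives Pearson correlations (bounded by 1);
    ``scaling='regression'`` gives the slope of each axis regressed on the
    standardized character, which can exceed 1 in magnitude.  Constant
    characters project to 0 with a warning.
    """
    if list(cm.taxa) != list(pco.taxa):
        raise ValueError("character matrix and PCO result cover different taxa")
    if scaling not in ("correlation", "regression"):
        raise ValueError(f"unknown scaling {scaling!r}")
    out = np.zeros((len(CHARACTERS), pco.n_axes))
    coords = pco.coordinates
    cc = coords - coords.mean(axis=0)
    for j, ch in enumerate(CHARACTERS):
        x = cm.scores[:, j].astype(float)
        x[cm.missing[:, j]] = np.nan
        ok = ~np.isnan(x)
        xs = x[ok] - x[ok].mean()
        sx = xs.std(ddof=1)
        if sx == 0:
            warnings.warn(f"character {ch!r} is constant; projections set to 0",
                          stacklevel=2)
            continue
        cov = xs @ cc[ok] / (ok.sum() - 1)
        if scaling == "correlation":
            out[j] = cov / (sx * cc[ok].std(axis=0, ddof=1))
        else:
            # slope of each axis regressed on the standardized character
            out[j] = cov / sx
    return pd.DataFrame(out, index=list(CHARACTERS),
                        columns=[f"PCO{k + 1}" for k in range(pco.n_axes)])
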