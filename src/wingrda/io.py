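"""Readers, writers and validation for character matrices, trait tables and tree sets.

The packaged study dataset (74 taxa scored for six ordinal skeletal
characters, with aspect ratio and body mass for the 71 extant taxa) is
exposed through :func:`load_study_fixture`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical character order used throughout
CHARACTERS = ("drp", "crp", "dpf", "iip1", "iip2", "fp")

#: sentinel for a missing character score (0 is a valid score)
MISSING = -1

_MAX_SCORE = {c: 2 for c in CHARACTERS}
_MAX_SCORE["iip1"] = 1


class ValidationError(ValueError):
    """Raised when an input table or tree violates a structural invariant."""


@dataclass
class CharacterMatrix:
    """Taxa x six ordinal skeletal characters, with missing-value sentinels."""

    taxa: list[str]
    scores: np.ndarray  # (n, 6) int, MISSING where unscored
    extinct: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        self.extinct = np.asarray(self.extinct, dtype=bool)
        if len(self.taxa) != len(set(self.taxa)):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        if len(self.taxa) < 3:
            raise ValidationError("no taxa" if not self.taxa else
                                  f"need at least 3 taxa, got {len(self.taxa)}")
        if self.scores.shape != (len(self.taxa), len(CHARACTERS)):
            raise ValidationError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.taxa)} taxa x {len(CHARACTERS)} characters")
        for j, ch in enumerate(CHARACTERS):
            col = self.scores[:, j]
            bad = (col != MISSING) & ((col < 0) | (col > _MAX_SCORE[ch]))
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"score {col[i]} out of range for character {ch!r} "
                    f"(taxon {self.taxa[i]!r})")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def missing(self) -> np.ndarray:
        return self.scores == MISSING

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, index=self.taxa, columns=list(CHARACTERS))
        df = df.mask(df == MISSING).astype("Int64")
        df["extinct"] = self.extinct.astype(int)
        df.index.name = "taxon"
        return df

    def subset(self, taxa: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return CharacterMatrix(list(taxa), self.scores[idx], self.extinct[idx])


@dataclass
class TraitTable:
    """Per-taxon aspect ratio and mass, stored raw and log_e transformed.

    ``ar_annotation`` carries values that are recorded but must never enter
    the explanatory matrix (fossil aspect-ratio estimates).
    """

    taxa: list[str]
    ar: np.ndarray          # (n,) float, NaN = missing
    mass: np.ndarray        # (n,) float, NaN = missing
    span: np.ndarray | None = None
    area: np.ndarray | None = None
    ar_annotation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ar = np.asarray(self.ar, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if len(self.taxa) != len(set(self.taxa)):
            raise ValidationError("duplicate taxon labels in trait table")
        if self.ar.shape != (len(self.taxa),) or self.mass.shape != (len(self.taxa),):
            raise ValidationError("trait column lengths do not match taxa")
        for name, col in (("AR", self.ar), ("M", self.mass)):
            if np.any(col[~np.isnan(col)] <= 0):
                i = int(np.flatnonzero(np.nan_to_num(col, nan=1.0) <= 0)[0])
                raise ValidationError(
                    f"non-positive {name} for taxon {self.taxa[i]!r}")
        if self.span is not None and self.area is not None:
            b, s = np.asarray(self.span, float), np.asarray(self.area, float)
            ok = ~(np.isnan(b) | np.isnan(s) | np.isnan(self.ar))
            if ok.any():
                implied = b[ok] ** 2 / s[ok]
                rel = np.abs(implied - self.ar[ok]) / self.ar[ok]
                if np.any(rel > 0.01):
                    i = int(np.flatnonzero(ok)[int(np.argmax(rel))])
                    raise ValidationError(
                        f"AR inconsistent with b^2/S for taxon {self.taxa[i]!r}")

    @property
    def log_ar(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.log(self.ar)

    @property
    def log_mass(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.log(self.mass)

    @property
    def complete(self) -> np.ndarray:
        """Mask of taxa with both AR and M present (rows usable in X)."""
        return ~(np.isnan(self.ar) | np.isnan(self.mass))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"AR": self.ar, "M": self.mass}, index=self.taxa)
        df["log_AR"] = self.log_ar
        df["log_M"] = self.log_mass
        df["ar_annotation"] = [self.ar_annotation.get(t, np.nan) for t in self.taxa]
        df.index.name = "taxon"
        return df


@dataclass
class TreeSet:
    """Ordered collection of rooted trees sharing a tip-label universe."""

    trees: dendropy.TreeList
    tip_map: dict[str, str] = field(default_factory=dict)  # taxon -> tip label

    def __post_init__(self) -> None:
        if len(self.trees) < 1:
            raise ValidationError("tree set is empty")
        for k, tree in enumerate(self.trees):
            for edge in tree.preorder_edge_iter():
                if edge.length is not None and edge.length < 0:
                    raise ValidationError(f"negative branch length in tree {k}")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, k: int) -> dendropy.Tree:
        return self.trees[k]

    @property
    def tip_labels(self) -> set[str]:
        return {t.label for t in self.trees.taxon_namespace}


def read_character_matrix(path: str | Path) -> CharacterMatrix:
    """Read a character matrix CSV (taxon + drp,crp,dpf,iip1,iip2,fp [+ extinct])."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"taxon": str})
    if df.empty:
        raise ValidationError(f"no taxa in {path}")
    missing_cols = [c for c in CHARACTERS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing character columns {missing_cols} in {path}")
    taxa = df["taxon"].astype(str).str.strip().tolist()
    scores = np.full((len(df), len(CHARACTERS)), MISSING, dtype=int)
    for j, ch in enumerate(CHARACTERS):
        for i, v in enumerate(df[ch]):
            if pd.isna(v) or (isinstance(v, str) and not v.strip()):
                continue
            fv = float(v)
            if not fv.is_integer():
                raise ValidationError(
                    f"non-integer score {v!r} at row {taxa[i]!r}, column {ch!r}")
            scores[i, j] = int(fv)
    extinct = (df["extinct"].fillna(0).astype(int).to_numpy().astype(bool)
               if "extinct" in df.columns else np.zeros(len(df), bool))
    return CharacterMatrix(taxa, scores, extinct)


def write_character_matrix(cm: CharacterMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path)


def read_trait_table(path: str | Path,
                     character_taxa: Sequence[str] | None = None) -> TraitTable:
    """Read a trait table CSV with AR (or b and S) and M columns.

    AR is computed from ``b**2 / S`` where the AR column is absent or blank.
    Taxa not present in ``character_taxa`` (when given) are retained with a
    warning.
    """
    df = pd.read_csv(Path(path), dtype={"taxon": str})
    if df.empty or "taxon" not in df.columns:
        raise ValidationError(f"no taxa in {path}")
    taxa = df["taxon"].astype(str).str.strip().tolist()
    n = len(df)

    def col(name):
        return (pd.to_numeric(df[name], errors="coerce").to_numpy(float)
                if name in df.columns else np.full(n, np.nan))

    ar, mass, b, s = col("AR"), col("M"), col("b"), col("S")
    derivable = np.isnan(ar) & ~np.isnan(b) & ~np.isnan(s)
    ar[derivable] = b[derivable] ** 2 / s[derivable]
    ann = {}
    if "ar_annotation" in df.columns:
        av = pd.to_numeric(df["ar_annotation"], errors="coerce")
        ann = {taxa[i]: float(av.iloc[i]) for i in range(n) if not pd.isna(av.iloc[i])}
    if character_taxa is not None:
        extra = [t for t in taxa if t not in set(character_taxa)]
        if extra:
            logger.warning("trait taxa absent from character matrix: %s", extra)
    span = b if "b" in df.columns else None
    area = s if "S" in df.columns else None
    return TraitTable(taxa, ar, mass, span=span, area=area, ar_annotation=ann)


def write_trait_table(tt: TraitTable, path: str | Path) -> None:
    tt.to_frame().to_csv(path)


def _match_tips(taxa: Sequence[str], tip_labels: Sequence[str]) -> dict[str, str]:
    """Map each study taxon to a tree tip label.

    Exact match first; failing that a unique genus-prefix match (characters
    are coded at genus level).  Ambiguous genus matches are errors.
    """
    tips = list(tip_labels)
    norm = {lbl: lbl.replace("_", " ") for lbl in tips}
    mapping: dict[str, str] = {}
    unmatched: list[str] = []
    for taxon in taxa:
        exact = [lbl for lbl in tips if norm[lbl] == taxon]
        if exact:
            mapping[taxon] = exact[0]
            continue
        genus = taxon.split()[0]
        cands = [lbl for lbl in tips if norm[lbl].split()[0] == genus]
        if len(cands) == 1:
            mapping[taxon] = cands[0]
            logger.info("genus-level tip match: %r -> %r", taxon, cands[0])
        elif len(cands) > 1:
            raise ValidationError(
                f"ambiguous genus match for {taxon!r}: {sorted(cands)}")
        else:
            unmatched.append(taxon)
    if unmatched:
        raise ValidationError(f"taxa missing from tree tips: {unmatched}")
    return mapping


def read_tree_set(path: str | Path, taxa: Sequence[str] | None = None) -> TreeSet:
    """Read rooted trees (Newick or Nexus, sniffed from content)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"tree file not found: {path}")
    head = path.read_text().lstrip()[:6].lower()
    schema = "nexus" if head.startswith("#nexus") else "newick"
    trees = dendropy.TreeList.get(path=str(path), schema=schema, rooting="force-rooted")
    ts = TreeSet(trees)
    if taxa is not None:
        for k, tree in enumerate(trees):
            labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            try:
                mapping = _match_tips(taxa, labels)
            except ValidationError as exc:
                raise ValidationError(f"tree {k}: {exc}") from exc
            if k == 0:
                ts.tip_map = mapping
    return ts


def write_tree_set(ts: TreeSet, path: str | Path) -> None:
    ts.trees.write(path=str(path), schema="newick", suppress_rooting=True)


def load_study_fixture() -> tuple[CharacterMatrix, TraitTable]:
    """Load the packaged study dataset: 74 taxa, 71 extant with AR and M."""
    data = resources.files("wingrda") / "data"
    with resources.as_file(data / "characters.csv") as p:
        cm = read_character_matrix(p)
    with resources.as_file(data / "traits.csv") as p:
        tt = read_trait_table(p, character_taxa=cm.taxa)
    return cm, tt
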