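"""End-to-end study orchestration: data -> PCO -> per-tree PGLS RDA/VARPART
ensemble -> representative-tree tests, ANOVA, and passive placement."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, anova, ensemble, io, pco, rda
from .simulate import SimConfig, make_synthetic_study

logger = logging.getLogger(__name__)

#: ANOVA families tested in the study: character grouping x continuous trait
ANOVA_FAMILY = (("iip2", "AR"), ("iip2", "M"), ("fp", "AR"),
                ("fp", "M"), ("dpf", "AR"), ("dpf", "M"))


@dataclass
class RunConfig:
    characters: str | None = None
    traits: str | None = None
    trees: str | None = None
    use_fixture: bool = False
    synthetic: SimConfig | None = None
    n_pco_axes: int = 12
    n_perm: int = 999
    n_sim: int = 1000
    seed: int = 0
    outdir: str = "wingrda_out"
    range_y: bool = False
    perms_all_trees: bool = False
    anova_log_scale: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        sources = sum([bool(self.use_fixture), self.synthetic is not None,
                       self.characters is not None])
        if sources != 1:
            raise ValueError("exactly one of use_fixture / synthetic / "
                             "characters+traits must be given")


@dataclass
class StudyReport:
    pco_result: pco.PcoResult
    ensemble_result: ensemble.EnsembleResult
    representative: int
    varpart_representative: rda.VarpartResult
    permutation: dict
    placements: pd.DataFrame
    root_ar: float
    anova_table: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _anova_groups(cm: io.CharacterMatrix, char: str,
                  mask: np.ndarray) -> np.ndarray:
    """Presence/absence grouping (score > 0); when every included taxon has
    the feature, split on prominence (score > 1) instead."""
    j = io.CHARACTERS.index(char)
    scores = cm.scores[mask, j]
    groups = anova.binarize_character(scores)
    if len(np.unique(groups)) < 2:
        logger.info("character %s present in all taxa; grouping on "
                    "prominence (score > 1)", char)
        groups = (scores > 1).astype(int)
    return groups


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full analysis; every stage failure is re-raised with the
    stage name attached."""
    stage = "data_io"
    try:
        if config.use_fixture:
            cm, tt = io.load_study_fixture()
            if config.trees is None:
                raise ValueError("tree file required with the fixture dataset")
            trees = io.read_tree_set(config.trees,
                                     taxa=[t for t, e in zip(cm.taxa, cm.extinct)
                                           if not e])
        elif config.synthetic is not None:
            cm, tt, trees = make_synthetic_study(config.synthetic)
        else:
            cm = io.read_character_matrix(config.characters)
            tt = io.read_trait_table(config.traits, character_taxa=cm.taxa)
            trees = io.read_tree_set(config.trees,
                                     taxa=[t for t, e in zip(cm.taxa, cm.extinct)
                                           if not e])

        stage = "pco"
        d = pco.hamming_distances(cm)
        d_corr, c = pco.cailliez_correction(d)
        pres = pco.principal_coordinates(d_corr, n_axes=config.n_pco_axes,
                                         cailliez_constant=c)

        stage = "assemble"
        trait_idx = {t: k for k, t in enumerate(tt.taxa)}
        extant = [t for t, e in zip(cm.taxa, cm.extinct) if not e]
        usable = [t for t in extant
                  if t in trait_idx and tt.complete[trait_idx[t]]]
        rows = [cm.taxa.index(t) for t in usable]
        Y = pres.coordinates[rows]
        X = np.column_stack([tt.log_ar[[trait_idx[t] for t in usable]],
                             tt.log_mass[[trait_idx[t] for t in usable]]])

        stage = "tree_ensemble"
        er = ensemble.run_ensemble(usable, Y, X, trees, range_y=config.range_y)
        rep = ensemble.select_representative(er)
        rec = er.records[rep]

        stage = "rda_varpart"
        Yw, Xw = rec.centering_y.whitened, rec.centering_x.whitened
        vp = rda.varpart(Yw, Xw[:, 0], Xw[:, 1],
                         n_perm=config.n_perm, seed=config.seed)
        perms = rda.permutation_tests(Yw, Xw, n_perm=config.n_perm,
                                      seed=config.seed + 1)

        stage = "passive_placement"
        ext_taxa = [t for t, e in zip(cm.taxa, cm.extinct) if e]
        ext_rows = [cm.taxa.index(t) for t in ext_taxa]
        ext_scores = ((pres.coordinates[ext_rows] - rec.centering_y.roots)
                      / rec.centering_y.scales)
        placements = rda.place_passive_taxa(ext_scores, rec.rda_result,
                                            rec.centering_x, taxa=ext_taxa)
        root = rda.root_ar(rec.centering_x)

        stage = "phyl_anova"
        rows_anova = []
        raw_ps = []
        mask = np.array([t in usable for t in cm.taxa])
        tr_cols = {"AR": np.log(tt.ar) if config.anova_log_scale else tt.ar,
                   "M": np.log(tt.mass) if config.anova_log_scale else tt.mass}
        for k, (char, trait) in enumerate(ANOVA_FAMILY):
            groups = _anova_groups(cm, char, mask)
            vals = tr_cols[trait][[trait_idx[t] for t in usable]]
            ar_res = anova.phylogenetic_anova(vals, groups, rec.cov,
                                              n_sim=config.n_sim,
                                              seed=config.seed + 100 + k)
            raw_ps.append(ar_res.p_value)
            rows_anova.append({"character": char, "trait": trait,
                               "F": ar_res.f_observed, "p_raw": ar_res.p_value,
                               "n_sim": ar_res.n_sim})
        p_holm = anova.holm_adjust(raw_ps)
        anova_table = pd.DataFrame(rows_anova)
        anova_table["p_holm"] = p_holm

        summary = ensemble.summarize_ensemble(er)
        summary["cailliez_constant"] = c
        summary["root_AR"] = root
        return StudyReport(
            pco_result=pres, ensemble_result=er, representative=rep,
            varpart_representative=vp, permutation=perms,
            placements=placements, root_ar=root, anova_table=anova_table,
            summary=summary)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc


def compute_study_targets(trees_path: str, seed: int = 0,
                          n_perm: int = 999, n_sim: int = 1000) -> dict:
    """Recompute the study's tree-dependent headline numbers.

    Requires the external 1,000-tree sample (birdtree.org subset deposited
    with the study); it is not redistributable with this package, so this
    is the documented recipe rather than a desk-reproducible computation.

    Returns, on the scales the study reports them:
      - ``mean_lambda``: mean joint lambda estimate across the tree sample
      - ``first_canonical_pct``: first canonical RDA eigenvalue as % of the
        total whitened-response variance, representative tree
      - ``ichthyornis_fitted_ar``: back-predicted AR for the passively
        placed *Ichthyornis* scores
      - ``root_ar``: back-transformed GLS root estimate of log AR
    """
    cfg = RunConfig(use_fixture=True, trees=trees_path, seed=seed,
                    n_perm=n_perm, n_sim=n_sim)
    report = run_study(cfg)
    rec = report.ensemble_result.records[report.representative]
    rel = rec.rda_result.relative_eigenvalues
    fitted = report.placements.loc["Ichthyornis dispar", "fitted_AR"]
    return {
        "mean_lambda": float(report.ensemble_result.lambdas.mean()),
        "first_canonical_pct": float(rel[0] * 100.0),
        "ichthyornis_fitted_ar": float(fitted),
        "root_ar": float(report.root_ar),
        "n_trees": len(report.ensemble_result.records),
    }


def write_report(report: StudyReport, config: RunConfig) -> Path:
    """Serialize all study artifacts plus a manifest with seed, version and
    content checksums."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.pco_result.eigenvalue_table().to_csv(out / "pco_eigenvalues.csv")
    report.pco_result.to_frame().to_csv(out / "pco_coordinates.csv")
    report.ensemble_result.to_frame().to_csv(out / "ensemble_records.csv",
                                             index=False)
    report.varpart_representative.to_frame().to_csv(out / "varpart.csv")
    report.placements.to_csv(out / "extinct_placements.csv")
    report.anova_table.to_csv(out / "anova.csv", index=False)
    rec = report.ensemble_result.records[report.representative]
    rec.rda_result.eigenvalue_table().to_csv(out / "rda_eigenvalues.csv")
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=1, sort_keys=True)
    manifest = {
        "wingrda_version": __version__,
        "seed": config.seed,
        "n_pco_axes": config.n_pco_axes,
        "n_perm": config.n_perm,
        "n_sim": config.n_sim,
        "range_y": config.range_y,
        "anova_log_scale": config.anova_log_scale,
        "files": {},
    }
    for p in sorted(out.glob("*.csv")) + [out / "summary.json"]:
        manifest["files"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
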