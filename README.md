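# wingrda

A tested, reusable implementation of a phylogenetic comparative pipeline that
links categorical skeletal characters of flight-feather attachment to wing
aspect ratio (AR) and body mass (M) across neoavian birds:

1. **PCO** — principal coordinates of pairwise Hamming distances between
   six ordinal skeletal characters (drp, crp, dpf, iip1, iip2, fp), with the
   Cailliez additive correction for negative eigenvalues, plus projections of
   the raw characters onto the retained axes.
2. **Phylogenetic whitening** — per tree: covariance from topology and
   branch lengths, one Pagel's λ jointly estimated by maximum likelihood over
   all variables (retained PCO axes + log AR + log M), likelihood-ratio tests
   against λ = 0 and λ = 1, GLS root centering, ranging of the explanatory
   variables to [−1, 1], and pre-multiplication by the symmetric
   C<sub>λ</sub><sup>−1/2</sup>.
3. **RDA + VARPART** — redundancy analysis of the whitened PCO block on
   whitened (log AR, log M); variation partitioning of Ezekiel-adjusted R²
   into AR, M, shared and residual fractions; row-permutation tests for axes,
   loadings and model fractions.
4. **Tree ensemble** — the whole chain iterated over a tree sample, with the
   representative tree chosen as the one whose seven partition terms are
   closest (Euclidean) to the ensemble means.
5. **Passive placement** — extinct taxa (scored for characters but lacking
   AR/M) are projected into the canonical space from their PCO scores and
   their AR is back-predicted on the natural scale; the GLS root estimate of
   log AR is back-transformed the same way.
6. **Phylogenetic ANOVA** — simulation-based one-way ANOVA (Brownian-motion
   null on the representative tree) of AR/M across character-state groups,
   with Holm adjustment across the declared six-test family.
7. **Synthetic data** — pure-birth trees, Brownian traits with tunable λ,
   and threshold-model ordinal characters, so every inference stage is
   testable against known ground truth without downloads.

The 74-taxon study dataset (71 extant taxa with AR and M; *Ichthyornis
dispar*, *Eocypselus rowei* and *Parargornis messelensis* extinct, with
fossil AR estimates stored as annotations that never enter the explanatory
matrix) ships with the package under `src/wingrda/data/`.

## CLI

Each stage is a subcommand; all stochastic stages require `--seed`.

```sh
wingrda pco --fixture --out out/pco
wingrda simulate --n-taxa 74 --n-trees 5 --seed 1 --out out/sim
wingrda run-all --synthetic --seed 1 --out out/study
wingrda run-all --fixture --trees trees.nex --seed 1 --out out/study
wingrda lambda --fixture --trees trees.nex --out out/lambda.json
```

`run-all` writes eigenvalue tables, per-tree ensemble records, the VARPART
table, RDA eigenvalues, extinct-taxon placements, the ANOVA summary, and a
manifest with seed, version and SHA-256 checksums of every artifact
(bit-stable across reruns with the same configuration).

## Layout

| module                | purpose                                              |
|-----------------------|------------------------------------------------------|
| `wingrda.io`          | CSV/Newick/Nexus readers & writers, packaged dataset |
| `wingrda.pco`         | Hamming distances, Cailliez correction, PCO, projections |
| `wingrda.phylo`       | covariance, λ ML, LR tests, centering/ranging, whitening |
| `wingrda.rda`         | RDA, adjusted R², VARPART, permutations, passive placement |
| `wingrda.anova`       | F statistic, simulation-based phylogenetic ANOVA, Holm |
| `wingrda.ensemble`    | per-tree runs, summaries, representative tree        |
| `wingrda.simulate`    | pure-birth trees, Brownian traits, threshold characters |
| `wingrda.pipeline`    | end-to-end orchestration, manifests, study recipe    |
| `wingrda.cli`         | click command line                                   |
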