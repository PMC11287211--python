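# corrsoil

Tools for studying **corrinoid ecology in soil microbiomes** — how vitamin
B₁₂-family cofactors (cobalamin, cobinamide and other lower-ligand variants)
are produced, shared, adsorbed and responded to in soil microbial
communities. The package is aimed at microbial ecologists working with
metagenome-assembled genomes (MAGs), microbiological bioassay data, serial
soil extractions and treatment-structured 16S rRNA zOTU tables.

## What it computes

**Genome roles** (`corrsoil.genome_roles`). Each genome is classified into
one of four corrinoid ecological roles from its annotations:

| ≥1 biosynthesis marker | ≥1 corrinoid-dependent enzyme | role |
|---|---|---|
| yes | yes | producer |
| yes | no  | producer/non-user |
| no  | yes | dependent |
| no  | no  | independent |

Biosynthesis markers are the corrin-ring genes *cbiC*/*cobH* (K06042),
*cbiF*/*cobM* (K05936), *cbiL*/*cobI* (K03394). The class II
(corrinoid-dependent) ribonucleotide reductase is detected via Pfam PF08471,
never via K00525 (which conflates RNR classes I and II). A redundancy report
counts, per function, genomes carrying the corrinoid-dependent enzyme, its
corrinoid-independent alternative, both, or neither.

**Bioassay quantification** (`corrsoil.bioassay`). OD₆₀₀ readings of a
corrinoid-requiring indicator strain are inverted to cobalamin-equivalent
nM through a monotone piecewise-linear standard curve in log₁₀
concentration, with explicit censoring at the limit of detection
(blank + 3 sd) and at 95 % of the plateau OD (the assay saturates near 1 nM
cobalamin).

**Partition model** (`corrsoil.partition`). Serial batch extractions of soil
deplete the adsorbed corrinoid pool geometrically under an equilibrium
partition coefficient K_d = [B12]_aq / [B12]_soil. For consecutive rounds,

    K_d = vol_soil · (aq_n − aq_{n+1}) / (vol_aq · aq_{n+1})

and the pool k rounds earlier is `soil · (1 + K_d·vol_aq/vol_soil)^k`.
The module estimates K_d per round pair, back-extrapolates the initial soil
pool (pmol/g), sums total extracted corrinoid with interval propagation of
censored rounds, bounds K_d from spike non-detections, and converts pools to
molecules per microbial cell.

**Community statistics** (`corrsoil.community`). Taxonomy-level aggregation,
Bray–Curtis and Jaccard dissimilarity, PCoA, seeded ANOSIM and PERMANOVA,
per-taxon Kruskal–Wallis responsiveness screens across ranks and timepoints
(raw P ≤ .05 as the headline call, BH-adjusted column always emitted), the
count-based and abundance-weighted "fraction responsive" summaries, and
pairwise Mann–Whitney treatment comparisons.

**Synthetic data** (`corrsoil.synthetic`). Seeded generators emulate every
input stream — annotation tables with planted roles, extraction series from
a known K_d, treatment-structured zOTU tables (7 corrinoid conditions ×
replicates × timepoints) with planted responders, and saturating standard
curves — each alongside a machine-readable truth record.

## Worked example

```python
from corrsoil import (ExtractionGeometry, estimate_kd, back_extrapolate,
                      molecules_per_cell, gen_extraction_series, total_pool)

geometry = ExtractionGeometry(vol_aq=0.01, vol_soil=0.001, soil_mass=1.0)
series, truth = gen_extraction_series(
    true_kd=0.04, initial_pool_pmol_per_g=34.0, geometry=geometry,
    n_rounds=12, noise_sd=0.05, seed=1)

est = estimate_kd(series, rounds_used=(1, 12))
print(f"K_d = {est.kd_mean:.4f} +/- {est.kd_sd:.4f}")
residual = truth.params["residual_pool_pmol_per_g"]
pool0 = back_extrapolate(residual, est.kd_mean, geometry, k_rounds=12)
print(f"initial pool = {pool0:.1f} pmol/g")
print("molecules/cell = %.0f (order 10^%d)" % molecules_per_cell(pool0, 1e9))
```

prints

```
K_d = 0.0400 +/- 0.0072
initial pool = 34.1 pmol/g
molecules/cell = 20550 (order 10^4)
```

i.e. from a noisy 12-round extraction the estimator recovers the planted
partition coefficient (0.04) to within a few percent, reconstructs the
planted 34 pmol/g pool, and a pool of that size spread over 10⁹ cells/g is
on the order of 10⁴ corrinoid molecules per cell.

The same stages are available from the shell:

```bash
corrsoil simulate extraction --seed 1 --out sim/
corrsoil estimate-kd --series sim/series.csv --rounds 6:9 --out out/
corrsoil simulate microcosm --seed 1 --out mic/
corrsoil ordinate --counts mic/counts.tsv --taxonomy mic/taxonomy.tsv \
    --metadata mic/metadata.tsv --rank order --out out/
```

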