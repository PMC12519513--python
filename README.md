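# cortsub

Cortical-thickness subtyping and thinning-mechanism analysis on synthetic
cohorts.

`cortsub` implements an end-to-end pipeline for studying data-driven
atrophy subtypes in an amyloid-positive, cognitively unimpaired
population:

1. **Subtyping** — baseline regional cortical thickness is inverted
   (per-ROI max-plus-margin, so larger values mean more atrophy) and
   decomposed by multi-restart non-negative matrix factorization (NMF,
   multiplicative-update Frobenius solver). Restarts are combined into a
   consensus co-assignment matrix; the rank is selected by the
   cophenetic coefficient with a silhouette tie-break.
2. **Longitudinal stability** — each follow-up scan is re-assigned to a
   baseline subtype by Pearson correspondence with the NMF regional
   profiles; baseline/follow-up agreement is quantified with
   Krippendorff's nominal alpha, and instability is modelled by
   logistic regression.
3. **Subtype-specific thinning** — per-ROI random-intercept linear
   mixed models (in-package profile-REML engine, cross-checked against
   statsmodels) yield marginal thinning slopes per subtype with Wald
   inference.
4. **Coordinated deformation models (CDM)** — each region's thinning is
   predicted from the connectivity-weighted thinning of its neighbours;
   the predicted-observed spatial correlation is tested against (a)
   degree-, weight- and geometry-preserving rewired networks and (b)
   variogram-matched spatially autocorrelated surrogate maps.
5. **Imaging transcriptomics** — regional gene-expression maps are
   spatially correlated with the thinning maps, tested against shared
   surrogate maps, and significant genes feed a hypergeometric
   over-representation analysis (ORA) with Benjamini–Hochberg
   correction.
6. **Synthetic cohort generator** — a sphere-shell parcellation with
   mirrored hemispheres and canonical network sectors, distance- and
   community-structured connectomes, planted thickness subtypes with
   covariate enrichment, network-coupled thinning rates, and regional
   expression maps with planted spatial coupling. Every published-style
   quantity the pipeline estimates has a known ground truth here.

See `docs/methods.md` for the statistical details and the rationale
behind every default.

## Quick start (Python)

```python
import cortsub as cs

parc = cs.generate_parcellation(100, seed=1)
templates = cs.generate_connectomes(parc, seed=2)
cfg = cs.SimulationConfig(seed=11)  # 400 subjects, 2 planted subtypes
table, labels, true_maps = cs.generate_cohort(cfg, parc,
                                              templates["functional"])

# subtype the baseline scans
X, offsets = cs.invert_thickness(table.baseline_matrix()[0])
report = cs.rank_selection(X, [2, 3, 4, 5, 6], n_restarts=10, seed=3)
model = cs.fit_nmf(X, report.selected_k, n_restarts=20, seed=3,
                   subject_ids=table.baseline_matrix()[1],
                   inversion_offsets=offsets)

# follow-up stability and thinning maps
stab = cs.stability_analysis(table, model)
maps = cs.thinning_betamaps(table, model)

# network test of one subtype's thinning map
res = cs.spatial_test(maps[0], templates["functional"], n_perm=500, seed=4)
print(report.selected_k, round(stab.alpha, 2),
      round(res.observed_r, 2), res.p_rewired)
```

## Command-line interface

Every stage is exposed as a `cortsub` subcommand operating on
plain TSV/JSON files:

```bash
cortsub simulate --out data --seed 5               # synthetic study
cortsub rank  --thickness data/thickness.tsv --kmin 2 --kmax 6 \
              --out rank.json
cortsub fit   --thickness data/thickness.tsv --k 2 --out model.json
cortsub stability --thickness data/thickness.tsv --model model.json \
              --out stability.json
cortsub lmm   --thickness data/thickness.tsv --model model.json \
              --out betamaps.tsv
cortsub cdm   --betamaps betamaps.tsv \
              --template data/connectome_functional.tsv \
              --parcellation data/parcellation.tsv --nperm 1000 \
              --out cdm.json
cortsub genes --betamaps betamaps.tsv --expr data/expression.tsv \
              --parcellation data/parcellation.tsv --nsurr 1000 \
              --out genes.tsv
cortsub ora   --genes genes.tsv --gmt sets.gmt --out ora.tsv
cortsub run   --config pipeline.yaml                # everything at once
```

`cortsub run` writes every artifact plus a `manifest.json` recording
the configuration, derived per-stage seeds and input checksums; the
manifest contains no timestamps, so a fixed configuration reproduces it
byte for byte.

## Worked example

`python scripts/acceptance.py --seed 1 --out acceptance.json` simulates
a default-scale study (400 subjects, 100 ROIs, three visits) and runs
the full analysis. Representative output:

```text
selected_k                 2        (planted k = 2)
subtype_ari                1.00     (planted vs recovered assignment)
krippendorff_alpha         1.00     unstable_fraction 0.00
slope_coverage_subtype1    1.00     (ROIs with slope within 3 SE of truth)
slope_coverage_subtype2    0.99
cdm_observed_r_subtype1    0.90     p_rewired 0.005   p_autocorr 0.005
gene_power                 1.00     null_gene_rejection 0.025
ora_top_set_is_planted     1        ora_planted_q 1.3e-18
manifest_byte_identical    1
```

The planted subtype 1 (limbic/default-network vulnerable set) is
recovered with its enriched covariates (older age, higher centiloid,
more APOE-e4 carriers), its thinning map is flagged as
network-constrained by both null models, and the planted gene set
attains the smallest ORA q-value.

## Layout

```
src/cortsub/
  types.py           dataclass containers and validation
  synthetic.py       synthetic cohort / connectome / expression generator
  subtyping.py       inversion, consensus NMF, rank selection
  longitudinal.py    LMM engine, thinning maps, stability, Krippendorff
  network.py         CDM, rewired nulls, variogram surrogates
  transcriptomics.py gene correlations, surrogate tests, ORA
  io.py              TSV/JSON readers and writers, config, seeding
  pipeline.py        end-to-end orchestration with manifest
  cli.py             click-based command-line interface
```
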