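# brainpad

Brain-age prediction and its molecular correlates on multi-site structural
morphometry: brain-PAD group inference, ComBat-harmonized cortical difference
maps, spatially-corrected receptor-map association, PLS-based imaging
transcriptomics, and gene-set enrichment — with a first-class synthetic-data
module so every stage is testable end-to-end without any restricted imaging,
PET, or microarray download.

## Who this is for

Researchers studying accelerated brain aging in clinical populations (the
package's motivating case is major depressive disorder) who want a tested,
reproducible re-implementation of the standard analysis chain, and
methodologists who want calibrated synthetic benchmarks for each stage.

## The analysis

**Brain age.** A linear support-vector regression is trained on healthy
controls to predict chronological age from region-wise cortical thickness and
subcortical volume features (z-scored with training statistics only). For a
test subject with predicted age ŷ and chronological age *y*, the
brain-predicted age deviation is

    brain-PAD = ŷ − y   (years)

Group differences in brain-PAD (patients minus controls) are tested with a
pooled-variance two-sample *t*-test and Cohen's *d* with a 95% CI from
SE(d) = √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))), plus a permutation test in two
modes: retraining the model under shuffled training-age labels (the
procedure the literature describes) or permuting test-set diagnosis labels
(exactly calibrated; see `docs/methods.md`).

**Difference maps.** Features are harmonized across acquisition sites with
parametric empirical-Bayes ComBat (normal prior on per-site locations,
inverse-gamma prior on scales), preserving age and sex effects. A per-region
two-sample *t*-map (negative = thinning in patients) is corrected with
Benjamini–Hochberg FDR at q < 0.05; a regression-diagnosis route (per-region
OLS with group, age, sex, and site dummies) provides a cross-method check.

**Receptor maps.** Spearman correlations between the *t*-map and
receptor/transporter density maps (5-HT1a/1b/2a, D1, D2, DAT, F-DOPA, GABAa,
mGluR5) are Fisher-z transformed and tested against variogram-matched
surrogate maps that preserve the *t*-map's value distribution exactly and its
spatial autocorrelation approximately — naive permutation grossly
over-rejects on autocorrelated maps.

**Transcriptomics.** PLS1 (NIPALS, X-deflation) regresses the regional
expression matrix on the *t*-map; component significance uses the same
spatial surrogate null, and genes are ranked by the bootstrap-corrected
weight w/SE(w) over region resamples. A designated risk-gene list is ranked,
and over-representation of annotation terms is tested with the exact
hypergeometric upper tail plus BH-FDR.

## Worked example

```python
import brainpad as bp
from brainpad.brainage import split_cohort, train_brainage, predict_and_pad, compare_groups
from brainpad.harmonize import fit_combat, apply_combat
from brainpad.groupmaps import roi_ttest_map
from brainpad.mapstats import map_association

geometry = bp.make_geometry(120, seed=0)
cohort = bp.make_cohort(n_hc=200, n_mdd=120, n_sites=4, seed=1)
features, truth = bp.simulate_thickness(cohort, geometry, seed=2,
                                        n_age_regions=60, n_affected=15)
meta = cohort.set_index("subject_id")

train_ids, test_ids = split_cohort(cohort, 0.5, seed=3)
model = train_brainage(features.loc[train_ids], meta.loc[train_ids, "age"])
pad = predict_and_pad(model, features.loc[test_ids], meta.loc[test_ids, "age"])
diff = compare_groups(pad.brain_pad, meta.loc[test_ids, "group"].to_numpy())
print(f"test r = {pad.pearson_r:.3f}, MAE = {pad.mae_years:.2f} yr")
print(f"brain-PAD difference (MDD - HC) = {diff.mean_difference_years:+.2f} yr, "
      f"d = {diff.cohens_d:.2f} [{diff.d_ci_low:.2f}, {diff.d_ci_high:.2f}]")

site = meta["site"].to_numpy(); design = meta[["age", "sex"]].to_numpy(float)
harmonized = apply_combat(fit_combat(features, site=site, design=design),
                          features, site=site, design=design)
tmap = roi_ttest_map(harmonized, meta["group"].to_numpy())
print(f"significant regions at q<0.05: {tmap.significant.sum()}")

receptors = bp.simulate_receptor_maps(geometry, truth, seed=4)
assoc = map_association(tmap, receptors, geometry, n_surr=499, seed=5)
print(assoc.round(3).to_string(index=False))
```

Output:

```
test r = 0.993, MAE = 2.40 yr
brain-PAD difference (MDD - HC) = +3.67 yr, d = 3.03 [2.64, 3.42]
significant regions at q<0.05: 15
map_name    rho  fisher_z  p_spatial     q
  5-HT1a -0.197    -0.199      0.706 0.854
  5-HT1b -0.098    -0.098      0.854 0.854
  5-HT2a -0.411    -0.437      0.070 0.630
      D1  0.117     0.118      0.834 0.854
      D2  0.143     0.144      0.470 0.854
     DAT  0.364     0.382      0.224 0.854
  F-DOPA -0.109    -0.109      0.804 0.854
   GABAa -0.229    -0.233      0.622 0.854
  mGluR5 -0.376    -0.396      0.310 0.854
```

The model predicts held-out ages almost perfectly on this clean synthetic
cohort, the injected 15-region thinning cluster is recovered exactly at
q < 0.05, and receptor maps generated with nonzero target correlations (DAT,
5-HT2a, mGluR5) show correspondingly larger |rho|, while the spatial
surrogate null correctly refuses to call these moderate correlations
significant at this map size.

## Command line

All stages are also exposed as a CLI over TSV/GMT files:

```sh
brainpad run --config config.yaml        # whole pipeline + manifest.json
brainpad harmonize --features features.tsv --meta cohort.tsv --out combat.tsv
brainpad tmap --features combat.tsv --meta cohort.tsv --method combat --out tmap.tsv
brainpad spatial --tmap tmap.tsv --receptors receptors.tsv --geometry geometry.tsv --out assoc.tsv
```

A pipeline config names either a `simulate:` block (generator parameters) or
an `inputs:` block (paths to the seven input tables); `profile: test` caps
permutation counts for fast runs. Outputs are written with a
`manifest.json` of SHA-256 content hashes; identical config + seed gives
identical hashes.

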