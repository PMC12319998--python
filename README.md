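# restfc

Linking **resting-state thought contents**, **functional-connectivity
fingerprints**, and **behavior**.

Resting-state fMRI studies routinely relate functional connectivity (FC)
to behavioral phenotypes, yet subjects are not idle during "rest": they
mind-wander. If behavioral traits shape the contents of spontaneous
thought, and those thought contents in turn perturb FC, then measured
FC–behavior associations may be partly carried by what people were
thinking about in the scanner. `restfc` implements the statistical
pipeline to test exactly that, for researchers working with multi-run
resting-state cohorts that include post-scan thought-content
questionnaires (e.g., the 12-item SNYCQ, rated 0–100 in steps of 5 after
each run):

1. **Fingerprint similarity.** For every subject with ≥ 3 valid runs,
   the mean absolute difference (MAD) between run pairs is computed for
   the half-vectorized Fisher-z FC matrix and for the questionnaire
   scores, and modeled with a random-intercept mixed model

   MAD_FC(i,jk) = β₀ + β₁·MAD_SNYCQ(i,jk) + uᵢ + ε,  uᵢ ~ N(0, σ²ᵤ),

   fitted by REML with the variance ratio profiled out; standardized
   β̂·σₓ/σᵧ with 95% CI is reported, plus Nakagawa marginal/conditional
   R². Item-level variants use each item's absolute difference, with
   Benjamini–Hochberg FDR over the 12 item tests, and a sensitivity
   rerun restricted to non-overlapping run pairs.
2. **Network correlates.** FC edges are averaged into a K×K (default
   8×8) functional network connectivity (FNC) matrix whose diagonal is
   the within-network mean. Each of the K(K+1)/2 = 36 unique entries is
   regressed on each questionnaire item (432 mixed models), with a
   36-test FDR family per item.
3. **CCA-chained mediation.** Per behavioral phenotype (kept when ≥ 90%
   of subjects have valid data), canonical correlation analysis against
   the univariate phenotype reduces the 12 questionnaire means and the
   36 concatenated-run FNC edges to one canonical variate (CV) each,
   scored by structure loadings. The mediation
   CV_FNC → CV_SNYCQ → behavior is then estimated with standardized
   least-squares paths A, B, C, C′; the indirect effect A·B gets a
   percentile 95% CI from 5000 seeded case-resampling bootstrap
   replicates, and FDR is applied across phenotypes.

Because suitable open datasets require heavy volumetric preprocessing,
the package ships a first-class **synthetic generator**
(`restfc.synthetic`) that plants this exact causal structure — stable
subject fingerprints, run-level thought states perturbing a disjoint
edge block, grid-valued questionnaire readouts, and behavior with known
standardized paths a, b, c′ — so every stage can be validated against
ground truth. A Monte-Carlo power harness and a motion-exclusion /
denoising front end (confound regression, cosine drift basis, zero-phase
0.1 Hz low-pass, strict > 0.25 mm mean-RMS-displacement exclusion)
complete the pipeline.

## Worked example

```python
import restfc as rf
from restfc.pipeline import (prepare_run_level, prepare_subject_level,
                             run_hypothesis1, run_hypothesis3)
from restfc.similarity import average_snycq

cfg = rf.SyntheticConfig(n_subjects=164, n_runs=4, n_nodes=50,
                         n_timepoints=120, seed=23)
timeseries, snycq, behavior, truth = rf.generate_dataset(cfg)

fc_vectors, fnc_table = prepare_run_level(timeseries)
results, nonoverlap, contrast = run_hypothesis1(fc_vectors, snycq)
print(results[["model", "beta_std", "ci_low", "ci_high", "p", "p_fdr"]]
      .head(4).round(4).to_string(index=False))
```

```
     model  beta_std  ci_low  ci_high      p  p_fdr
full_scale    0.1178  0.0563   0.1792 0.0002    NaN
   item_01    0.1498  0.0887   0.2110 0.0000 0.0000
   item_02    0.0398 -0.0207   0.1004 0.1968 0.3936
   item_03    0.0064 -0.0554   0.0682 0.8402 0.8402
```

164 subjects × C(4,2) = 6 run pairs give 984 contrast records; run-pair
similarity in thought content predicts fingerprint similarity
(standardized β = 0.12), and the planted dominant "vigilance-like" item
(`item_01`, generator loading 0.9) is the strongest single-item
predictor, surviving FDR.

```python
res3 = run_hypothesis3(prepare_subject_level(timeseries),
                       average_snycq(snycq), behavior,
                       n_boot=5000, seed=0)
```

```
  phenotype  path_a  path_b  path_c_prime  indirect  indirect_ci_low  indirect_ci_high  indirect_p_fdr
   mediated   0.381   0.382         0.439     0.146            0.081             0.216           0.001
direct_only   0.318   0.014         0.518     0.005           -0.036             0.050           0.829
 null_pheno  -0.076   0.174         0.381    -0.013           -0.049             0.015           0.510
```

The generator planted a = b = 0.4, c′ = 0.3 (indirect a·b = 0.16) for
`mediated`, a direct-only control with the same total effect, and a pure
noise control. The pipeline recovers paths near (0.38, 0.38, 0.44) and a
significant FDR-corrected indirect effect of 0.146 for the mediated
phenotype only — the two controls' bootstrap CIs cover zero.

A thin CLI mirrors the stages:

```bash
restfc simulate --n-subjects 20 --out data/
restfc preprocess --in data/timeseries --out clean/ --motion-threshold 0.25
restfc h1 --data data/ --out results/
restfc power --analysis mediation --n-sims 1000 --seed 1
```

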