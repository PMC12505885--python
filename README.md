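# warmnet

Soil microfauna co-occurrence network analysis under multilevel experimental
warming: network construction with random-matrix-theory (RMT) threshold
selection, per-sample complexity and stability metrics, a multinutrient
cycling index, and the mixed-model inference layer that ties them together —
exercised end-to-end on a synthetic-data generator that emulates a
4-block × 5-treatment warming experiment.

## The scientific problem

Soil microfauna (nematodes and protists) occupy several trophic levels of
the soil food web. How experimental warming (ambient, +0.8, +1.5, +3.0,
+4.2 °C) reshapes the *co-occurrence structure* of these communities — and
whether network complexity and stability in turn predict soil nutrient
cycling — is a question that runs through four analysis stages:

1. **Network construction** (`warmnet.netbuild`). Pairwise Spearman rank
   correlations ρ across the 20 samples of a depth layer, two-sided
   p-values from the t approximation, Benjamini–Hochberg FDR adjustment.
   The correlation threshold *s* is chosen automatically by RMT: the
   thresholded matrix's unfolded eigenvalue spacings *d* are tested against
   the Wigner surmise P(d) = (πd/2)·exp(−πd²/4) (correlated noise, GOE)
   and the Poisson law P(d) = exp(−d) (uncorrelated, signal-dominated);
   the smallest *s* whose spacing distribution persistently accepts the
   Poisson law is selected. An edge requires both |ρ| ≥ s and
   p_adj < 0.05, signed by the sign of ρ.
2. **Complexity and stability** (`warmnet.netmetrics`, `warmnet.cohesion`).
   Per-sample induced subnetworks (taxa with abundance > 0) yield node and
   edge counts, average degree 2E/N, connectance 2E/(N(N−1)), clustering,
   global efficiency E(G) = mean of 1/d(i,j) over ordered pairs, and
   vulnerability max_i (E − E_i)/E under single-node removal. Stability is
   additionally summarized by cohesion: each taxon's connectedness is its
   mean positive (negative) null-corrected correlation with all other taxa
   (null = "taxa shuffle" permutations); per-sample cohesion is the
   abundance-weighted sum, and NPC = |negative|/positive cohesion.
3. **Ecosystem function** (`warmnet.ecofunction`). The multinutrient
   cycling index (MNC) is the per-sample mean of within-layer z-scores of
   ten nutrient-pool variables (SOC, TN, TP, AP, NH₄-N, NO₃-N, DOC, MBC,
   MBN, MBP).
4. **Inference** (`warmnet.inference`). Effect sizes β per warming level
   come from Gaussian linear mixed models with block random intercepts
   (treatment factor tested by a Wald type II χ², with a small-sample
   F-calibrated p-value); response shapes are compared by ML AIC
   (linear vs quadratic, decisive when ΔAIC > 2); soil drivers are ranked
   by hierarchical variance partitioning of the marginal R²; and
   metric → MNC links are fit with the same mixed-model machinery.

Because the field study's raw data live in a sequencing archive, the
package ships a first-class synthetic generator (`warmnet.synthetic_data`)
that plants known correlation modules through a Gaussian copula
(latent Pearson r = 2·sin(πρ/6)) and known treatment-response curves, so
every stage is testable against ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 0):

```bash
python analysis/01_simulate.py --seed 0   # data -> results/data/
python analysis/02_networks.py            # 6 networks -> results/networks/
python analysis/03_metrics.py             # per-sample metrics
python analysis/04_multinutrient.py       # MNC per layer
python analysis/05_inference.py --seed 0  # effect sizes, shapes, links
```

Step 02 reports one RMT-thresholded network per community × depth layer:

```
nematode_0-10cm: threshold=0.36 (RMT=yes) nodes=37 edges=183 (68 negative)
protist_0-10cm:  threshold=0.30 (RMT=yes) nodes=37 edges=144 (29 negative)
whole_0-10cm:    threshold=0.58 (RMT=yes) nodes=74 edges=450 (171 negative)
```

Step 04 shows the hump-shaped nutrient response planted in the topsoil
(means of the MNC by warming level) and its attenuation in the subsoil:

```
0-10cm:  +0.0: -0.82  +0.8: -0.12  +1.5: +0.11  +3.0: +0.53  +4.2: +0.30
10-20cm: +0.0: -0.09  +0.8: -0.03  +1.5: +0.04  +3.0: +0.03  +4.2: +0.06
```

Step 05 prints the topsoil effect sizes (β vs ambient; stars from the
treatment Wald test), e.g. for this seed:

```
protist:connectance  +0.8: +0.011  +1.5: +0.040  +3.0: +0.052  +4.2: +0.031  ***
protist:npc          +0.8: -0.051  +1.5: -0.027  +3.0: +0.184  +4.2: +0.076  *
mnc                  +0.8: +0.700  +1.5: +0.925  +3.0: +1.346  +4.2: +1.120  ***
```

— the β pattern peaks at +3.0 °C, the nonlinear (hump-shaped) response the
generator plants for complexity, stability and nutrient cycling.

The same pipeline is available as a CLI (`warmnet run --seed 0 --outdir out/`)
with per-stage verbs `simulate`, `network`, `metrics`, `mnc`, `infer`.

## Layout

```
src/warmnet/        library: synthetic_data, netbuild, netmetrics,
                    cohesion, ecofunction, inference, pipeline, cli
analysis/           numbered narrative drivers (01_simulate ... 05_inference)
scripts/acceptance.py   from-scratch recomputation of headline quantities
tests/              pytest suite (unit, property, acceptance)
docs/methods.md     model and design notes
```
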