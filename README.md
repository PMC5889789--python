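# efsubtype

Data-driven subtyping of executive-function-related behavioral difficulties
in children, and linkage of the subtypes to brain-network structure.

Many children referred for problems with attention, learning or memory do
not fit neatly into diagnostic categories: behavioral profiles are
heterogeneous even within a diagnosis such as ADHD. `efsubtype` implements
an alternative, data-driven route for researchers working with
questionnaire batteries (here the six Conners 3 subscales: Inattention,
Hyperactivity/Impulsivity, Learning Problems, Executive Function,
Aggression, Peer Relationships) and, optionally, structural connectomes:

1. **Person-by-person similarity network.** After regressing age out of
   each subscale and z-scoring, every pair of children *i, j* gets a signed
   edge `w_ij = corr(x_i, x_j)` between their six-scale profiles.
2. **Signed-modularity consensus clustering.** Subgroups are communities of
   this signed network, found by maximizing the asymmetric signed quality
   index

   `Q* = Q⁺ − v⁻/(v⁺+v⁻) · Q⁻`,
   `Q± = 1/v± · Σ_ij (w±_ij − s±_i s±_j / v±) δ(c_i, c_j)`,

   where `w⁺`/`w⁻` are the positive part and the magnitude of the negative
   part of the weights, `s±_i` the corresponding node strengths and `v±`
   the total weights. Optimization is a Louvain-style two-phase greedy
   search, stabilized by consensus clustering: 100 randomized runs vote
   through a co-assignment (agreement) matrix that is thresholded and
   re-clustered until all runs agree.
3. **Subgroup characterization.** Mann-Whitney U contrasts per scale and
   subgroup pair with Bonferroni correction, robust descriptives
   (median/MAD), chi-square enrichment of diagnosis labels, and a bootstrap
   **homogeneity statistic**: repeatedly subsample *m* children per group
   and compare the mean within-group pairwise profile correlation between
   the data-driven and a diagnosis-based grouping.
4. **Connectome PLS.** Each participant's FA-weighted connectome is reduced
   to node degrees; PLS2 regression of the centered one-hot group indicator
   on degrees identifies the region combinations that best separate the
   subgroups, evaluated by train/test RMSE against label-permuted refits,
   10-fold cross-validation, and bootstrap ratios (mean loading / bootstrap
   SE, |BSR| > 2 read as reliable) with orthogonal Procrustes alignment
   across refits.

Because cohort questionnaire data of this kind are rarely shareable, the
package ships first-class synthetic generators (`efsubtype.synthetic`) for
cohorts with planted subtype structure (defaults follow published
three-subtype profile medians/MADs and diagnosis enrichment of a referred
cohort of 442 children), planted-partition benchmark networks, and
connectome sets with implanted degree effects — so every claim the pipeline
makes can be verified against a known ground truth.

## Worked example

`examples/01_cohort_clustering.py` simulates 3 × 80 children from the
default subtype profiles and recovers the structure:

```
children clustered : 187
communities found  : 3 (planted: 3)
community sizes    : [79, 65, 43]
quality index Q    : 0.452
consensus rounds   : 3
ARI vs planted     : 0.258
```

Three communities are found with a clearly positive signed quality index;
the moderate adjusted Rand index reflects the deliberately strong profile
noise in the generator (see `docs/methods.md`). The connectome example
(`examples/03_connectome_pls.py`) implants +8-edge degree effects on eight
regions and recovers them:

```
explained variance : [94.57, 1.7] %
components retained: 1 (>= 5% floor)
test RMSE          : 0.167 (label-permuted null 0.608)
permutation p      : 0.0050
10-fold CV RMSE    : 0.142 (SE 0.010)
```

with all eight implanted regions flagged at |BSR| > 2. The remaining
examples cover subgroup contrasts/homogeneity and the planted-partition
noise benchmark. A thin CLI mirrors the stages
(`efsubtype simulate|preprocess|cluster|contrast|enrichment|homogeneity|pls|run`);
`efsubtype run --config run.yaml` executes the whole pipeline.

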