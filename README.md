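# netperturb

Single-sample **gene-interaction perturbation** scoring and consensus
subtyping for bulk tumor expression cohorts.

Tumor cohorts — glioblastoma being the motivating case — hide molecular
subtypes that gene-level statistics blur: two samples can express the same
genes at similar levels while wiring them differently. `netperturb`
quantifies, for every sample and every edge of a confidence-filtered
interaction network (e.g. a STRING export over immune-related genes), how far
that sample displaces the interaction from its normal-tissue reference state,
and discovers subtypes from that edge × sample matrix. It is aimed at
computational biologists subtyping bulk (or pseudo-bulk) expression cohorts
who have a tumor cohort, a normal cohort, and an interaction edge list.

## The statistic

For sample *S* over *G* genes, let *R<sub>A,S</sub>* be the within-sample
rank of gene *A* (ascending, ties averaged). For network edge *E = (A, B)*:

- delta rank: δ<sub>E,S</sub> = R<sub>A,S</sub> − R<sub>B,S</sub>
- benchmark: δ̄<sub>E</sub>, the delta rank of the pseudo-sample obtained by
  averaging all normal profiles (mean first, then rank)
- perturbation: Δ<sub>E,S</sub> = δ<sub>E,S</sub> − δ̄<sub>E</sub>

Because ranks are computed within each sample, Δ is invariant to any monotone
transform of a single profile, making it comparable across samples and
platforms. The pipeline then:

1. selects clustering features as the intersection of the top-*K* edges by
   two-sided Wilcoxon rank-sum *p* (tumor vs normal Δ) and the top-*K* by
   tumor-cohort SD (*K* = 4000 by default, scaled down for small networks);
2. clusters samples by subsampled consensus PAM (Euclidean distance,
   1000 repetitions by default, 80% subsamples), choosing the number of
   clusters *k* from the relative increase in area under the consensus CDF;
3. derives per-subtype upregulated signature genes (one-vs-rest rank-sum,
   BH < 0.05, top-300 per subtype by effect size);
4. re-assigns subtypes in external cohorts by nearest-template prediction
   (cosine distance to binary marker templates, gene-resampling null,
   FDR ≤ 0.2 confidence gate) and tests subtype correspondence between
   cohorts with a centroid-correlation permutation test (adjusted p < 0.05).

A simulation module generates scale-free networks, conservative normals,
tumors with planted subtype-specific shifts on hub-biased gene sets, and
subtype-dependent censored survival, so the whole chain is verifiable without
external downloads.

## Worked example

```python
import netperturb as npb

result = npb.run_discovery(
    {"seed": 1, "simulate": {"seed": 1}, "n_reps": 250, "k_p": 1500, "k_sd": 1500}
)
```

Running `python examples/02_discover_subtypes.py` (which does the above and
prints diagnostics) gives:

```
selected 1068 interactions for clustering
delta-area per k: 2: 0.405, 3: 0.598, 4: 0.162, 5: 0.050, 6: 0.040, 7: 0.035, 8: 0.020, 9: 0.016
chosen number of subtypes: k = 4
subtype sizes: {'C1': 57, 'C2': 51, 'C3': 50, 'C4': 42}
adjusted Rand index vs planted labels: 1.000
```

The relative CDF-area gain stays above the 0.1 stability threshold up to
k = 4 and collapses beyond it, so four subtypes are called — and the
assignment matches the four planted subtypes exactly (ARI 1.0).
`examples/01_perturbation_scores.py` shows the tumor/normal perturbation
contrast (ratio ≈ 2.4 on the default study), `examples/03_validate_new_cohort.py`
the NTP re-assignment of a fresh cohort (100% confident-sample agreement,
significant correspondence only on the diagonal), and
`examples/04_survival_by_subtype.py` the Kaplan–Meier / log-rank comparison.

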