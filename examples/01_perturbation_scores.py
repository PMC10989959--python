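"""Score every sample's gene-interaction perturbation against a normal benchmark.

Builds a small synthetic study (scale-free network, 40 normals, 80 tumors),
reduces each sample to within-sample expression ranks, takes rank differences
across network edges, and contrasts them with the delta-rank vector of the
averaged normal cohort.
"""

import netperturb as npb

study = npb.simulate_study(
    npb.SimulationConfig(seed=1, n_genes=300, n_normal=40, n_tumor=80,
                         n_dysregulated_per_subtype=25)
)
tumor_pert, normal_pert, benchmark = npb.compute_perturbation(
    study.tumor_expr, study.normal_expr, study.network
)

tumor_mag = npb.perturbation_magnitude(tumor_pert)
normal_mag = npb.perturbation_magnitude(normal_pert)
print(f"network: {len(study.network.nodes)} genes, {study.network.n_edges} interactions")
print(f"mean |perturbation| in tumors:  {tumor_mag.mean():.1f}")
print(f"mean |perturbation| in normals: {normal_mag.mean():.1f}")
print(f"ratio: {tumor_mag.mean() / normal_mag.mean():.2f}")
print(
    "Tumors displace their interactions far more than normals do — the same "
    "contrast that makes per-sample perturbation a usable subtyping substrate."
)
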