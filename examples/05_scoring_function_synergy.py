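"""Set-theoretic complementarity between scoring functions.

Computes, for every metric pair, the union / symmetric difference /
relative complement of the complexes each finds (acceptable or better
in the top 10), clusters the metrics by complete linkage on the
symmetric-difference cardinality, and prints the matrices and the
dendrogram in Newick form.
"""

from dockscore import (
    SyntheticMetricSpec,
    benchmark_case_specs,
    run_synthetic_benchmark,
    synergy_matrices,
)

cases = benchmark_case_specs(24, seed=31, n_decoys=60)
metrics = [
    SyntheticMetricSpec("alpha", rho=0.8),
    SyntheticMetricSpec("alpha_kin", rho=0.7, shared_noise_with="alpha"),
    SyntheticMetricSpec("beta", rho=0.8),
    SyntheticMetricSpec("gamma", rho=0.55),
]
results = run_synthetic_benchmark(cases, metrics, seed=9)

syn = synergy_matrices(results, [m.name for m in metrics])
print("symmetric difference (clustered order):")
print(syn.symmetric_difference.to_string())
print()
print("union:")
print(syn.union.to_string())
print()
print("relative complement (ordered by individual success):")
print(syn.relative_complement.to_string())
print()
print("dendrogram:", syn.dendrogram.to_newick())
# A large symmetric difference marks a pair succeeding on different
# complexes — candidates for synergistic combination.  Metrics sharing
# failure modes (alpha and alpha_kin) cluster together at low height.
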