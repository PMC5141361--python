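"""Topological pathway analysis: which pathway is deregulated, and where.

Each pathway graph is moralized, triangulated and decomposed into a clique
tree; permutation mean/variance tests on the Gaussian graphical model flag
deregulated pathways, and clique-level tests score leaf-to-leaf paths to
localize the signal.
"""

from mirpathnet import (
    GeneratorConfig,
    adjust_pathway_qvalues,
    analyze_pathway,
    generate,
)

bundle = generate(GeneratorConfig(seed=1))
ann = bundle.annotation
samples = [s for s in bundle.gene_mat.sample_ids
           if ann.condition[s] in ("case", "ctrl_a")]
mat = bundle.gene_mat.subset_samples(samples)

tests, paths_by_pw = [], {}
for i, pw in enumerate(bundle.pathways):
    test, ct, clique_results, scored = analyze_pathway(
        mat, pw, "case", "ctrl_a", n_perm=500, seed=10 + i)
    tests.append(test)
    paths_by_pw[pw.pathway_id] = scored

for t in adjust_pathway_qvalues(tests, q_max=0.1):
    flag = "<-- significant" if t.significant else ""
    print(f"{t.pathway_id}: q_mean={t.q_mean:.3f} q_var={t.q_var:.3f} {flag}")

best = paths_by_pw["pw1"][0]
print(f"top path in pw1: score={best.score:.2f}, nodes={sorted(best.nodes)}")
print("planted path:   ", bundle.truth.planted_path_nodes["pw1"])
# Only pw1 carries the planted 1.5-sigma shift; its top-scoring clique path
# coincides with the planted cascade.
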