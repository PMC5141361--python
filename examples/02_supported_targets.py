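"""Anticorrelation support for predicted miRNA targets.

Predicted miRNA-target pairs (score >= 0.8) are kept only when their
expression profiles are significantly anticorrelated: Pearson r < -0.5 with
Benjamini-Hochberg FDR < 0.1 across the tested family.
"""

from mirpathnet import GeneratorConfig, generate, select_supported

bundle = generate(GeneratorConfig(seed=1))
ann = bundle.annotation
samples = [s for s in bundle.gene_mat.sample_ids
           if ann.condition[s] in ("case", "ctrl_a")]

supported = select_supported(
    bundle.predictions,
    bundle.mirna_mat.subset_samples(samples),
    bundle.gene_mat.subset_samples(samples),
)
passed = [s for s in supported if s.passed]
print(f"tested {len(supported)} predicted pairs, {len(passed)} supported")
for s in passed[:5]:
    print(f"  {s.mirna_id} -| {s.gene_id}: r={s.r:+.2f}, q={s.q:.2e}")

truth_pairs = {(m, g) for m, g, _ in bundle.truth.planted_pairs}
found = {(s.mirna_id, s.gene_id) for s in passed}
print(f"planted pairs recovered: {len(found & truth_pairs)}/{len(truth_pairs)}")
# All ten pairs planted at rho=-0.8 pass; extra discoveries are the planted
# circuit edges, which are genuinely anticorrelated too.
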