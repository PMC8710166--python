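"""Threshold screening of differentially expressed genes.

Builds a synthetic 1000-gene matrix with 7 up- and 5 down-spiked genes at
|log2FC| = 2 (6 samples per group), runs the fold-change + Welch-test +
BH-FDR screen at |log2FC| >= 1 and p < 0.05, and checks the spikes were
recovered.  Also shows 2^-ddCt relative quantification for qPCR.
"""

from moxatox import DdctInput, ddct_relative_expression, differential_expression
from moxatox.synthetic import SpikeDesign, gen_expression_matrix

design = SpikeDesign(n_genes=1000, n_up=7, n_down=5, effect_log2fc=2.0,
                     n_per_group=6, seed=0)
mat, truth = gen_expression_matrix(design)
res = differential_expression(mat)

print(f"screen counts: total={res.counts['total']} "
      f"up={res.counts['up']} down={res.counts['down']}")
spiked = set(truth.loc[truth.spike != 'null', 'gene_id'])
found = set(res.up) | set(res.down)
print(f"spiked genes recovered: {len(found & spiked)}/{len(spiked)}, "
      f"false positives: {len(found - spiked)}")

fold = ddct_relative_expression(DdctInput(25.0, 20.0, 24.0, 20.0))
print(f"\nqPCR example: target 2^-ddCt fold change = {fold:.2f}")
print("(<1 means the gene is down in the treated condition relative to control)")
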