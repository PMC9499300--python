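"""Gene-set overrepresentation of VUS-containing genes.

Hypergeometric upper-tail test of a query gene set against user-supplied
gene sets (GMT), BH-adjusted across the tested sets and ranked by gene
ratio (query-hits / query-size).
"""

from germlinekit import synthetic
from germlinekit.models import ora_test

cfg = synthetic.SyntheticConfig(seed=1)
sets = synthetic.build_gene_sets(cfg)
universe = {g.symbol for g in synthetic.build_panel(cfg)}

# query: the model genes plus a few decoys, mimicking a VUS-containing list
query = set(synthetic.DEFAULT_MODEL_GENES) | {"DEC0001", "DEC0002", "DEC0100"}

print(f"{'set':24s} {'k/K':>8s} {'gene_ratio':>10s} {'p':>10s} {'q':>10s}")
for r in ora_test(query, sets, universe):
    print(f"{r.name:24s} {r.k:3d}/{r.K:<4d} {r.gene_ratio:10.3f} {r.p:10.3g} {r.q:10.3g}")
print("\nThe PI3K-Akt-like set contains all six model genes, so it dominates the")
print("ranking; p is P[X >= k] under Hypergeometric(N, K, n).")
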