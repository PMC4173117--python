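"""Why min-max scaling changes the clustering, and how to display raw values.

Molecular weight spans hundreds of daltons while logP spans a few units, so
an unscaled Euclidean clustering is driven almost entirely by weight.
Scaling each feature to [0, 1] balances them; the write-original option then
keeps the raw values in the heatmap while the row order stays that of the
normalized clustering.
"""

import numpy as np

from dendroheat import DataMatrix, RunConfig, api_run, leaf_order

values = np.array([
    # logP, MW: logP pairs (a,b) and (c,d); weight pairs (a,d) and (b,c)
    [3.00, 250.0],
    [3.02, 500.0],
    [6.00, 520.0],
    [6.02, 270.0],
])
data = DataMatrix(["a", "b", "c", "d"], ["logP", "MW"], values)

raw = api_run(RunConfig(), data)
scaled = api_run(RunConfig(normalize=True, write_original=True), data)

print("row order, raw clustering:      ", leaf_order(raw.row_tree))
print("row order, normalized clustering:", leaf_order(scaled.row_tree))
leaves = {tuple(nd.objects): nd.features for nd in scaled.row_tree.nodes.values() if nd.is_leaf}
print("displayed features for row 'a':  ", leaves[("a",)])
# Raw clustering pairs rows by weight (a with d, b with c); after scaling,
# logP matters equally and a pairs with b.  The displayed features are still
# the original values (250 Da, not 0.0) thanks to write_original.
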