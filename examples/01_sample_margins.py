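"""Sample one limited-information dataset and inspect its structure.

A dataset is not a person-by-item response matrix: it is every item's
univariate category-probability vector plus one bivariate probability
table per item pair, with shared margins exactly consistent.
"""

import numpy as np

from sisquoc import ItemSpec, frechet_bounds, sample_dataset

rng = np.random.default_rng(0)
spec = ItemSpec.uniform(n_items=4, n_categories=3)
d = sample_dataset(spec, rng)

print(f"{d.n_items} items, {len(d.bivariate)} pair tables")
print("\nitem 0 margin:", np.round(d.univariate[0].probs, 4))
print("item 1 margin:", np.round(d.univariate[1].probs, 4))

t = d.bivariate[(0, 1)]
print("\npair (0, 1) table:")
print(np.round(t.cells, 4))
print("row sums:", np.round(t.cells.sum(axis=1), 4), "(= item 0 margin)")
print("col sums:", np.round(t.cells.sum(axis=0), 4), "(= item 1 margin)")

b = frechet_bounds(d.univariate[0], d.univariate[1], None, 0, 0)
print(
    f"\nFrechet interval for the first cell: [{b.lower:.4f}, {b.upper:.4f}]; "
    f"sampled value {t.cells[0, 0]:.4f} lies inside it."
)
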