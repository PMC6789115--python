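"""Show accuracy degrading as priors move away from the true abundances.

Interpolates the classifier's prior from the habitat's own bespoke weights
towards the most dissimilar other habitat's weights and reruns the CV
benchmark at each step, printing the species-level error next to the L1
distance between the priors and the generating abundances.
"""

import numpy as np
from scipy.stats import pearsonr

from taxaprior import (
    SyntheticSpec,
    TaxonomicWeights,
    assemble_weights,
    make_habitats,
    make_reference,
    make_samples,
    run_cv,
)


def pooled_bespoke(table, taxa):
    counts = {}
    for sample in table.samples:
        for taxon, c in table.sample_counts(sample).items():
            counts[taxon] = counts.get(taxon, 0) + c
    return assemble_weights(counts, taxa)


spec = SyntheticSpec(seed=0)
reference = make_reference(spec)
habitats = make_habitats(spec, 14)
table, _ = make_samples(habitats[0], reference, n_samples=40, depth=2000, seed=0)
taxa = reference.taxa()

own = pooled_bespoke(table, taxa)
others = [
    pooled_bespoke(make_samples(h, reference, n_samples=20, depth=2000, seed=100 + j)[0], taxa)
    for j, h in enumerate(habitats[1:])
]
l1 = lambda a, b: sum(abs(a[t] - b[t]) for t in taxa)
wrong = others[int(np.argmax([l1(own, w) for w in others]))]

print(f"{'mix':>5} {'L1 to truth':>12} {'species error':>14}")
dists, errors = [], []
for t in (0.0, 0.25, 0.5, 0.75, 1.0):
    weights = TaxonomicWeights({x: (1 - t) * own[x] + t * wrong[x] for x in taxa})
    report = run_cv(reference, table, "fixed", fixed_weights=weights, seed=0, levels=(7,))
    d = sum(abs(weights[x] - habitats[0][x]) for x in taxa)
    e = report.summary(7, "error_rate")
    dists.append(d)
    errors.append(e)
    print(f"{t:>5.2f} {d:>12.3f} {e:>14.3f}")
r, _ = pearsonr(dists, errors)
print(f"Pearson r(error, L1 misspecification) = {r:.3f}")
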