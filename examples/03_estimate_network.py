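"""Estimate a symptom network from ordinal data with known ground truth.

Draws Likert-style 0-3 data from a Gaussian copula whose latent correlation
matrix encodes a known sparse partial-correlation network, then recovers
the network with the Spearman-based Gaussian graphical model and, as a
sparse sensitivity variant, the EBIC graphical lasso.
"""

import numpy as np

from sympnet import EstimatorConfig, estimate_network, global_strength
from sympnet.synthetic import TrueNetworkSpec, make_true_network, sample_ordinal_visit

W_true, R = make_true_network(TrueNetworkSpec(target_strength=1.8, seed=4))
X = sample_ordinal_visit(n=2000, covariance=R, thresholds=(-1, 0, 1), mean_shift=0.0, seed=0)

ggm = estimate_network(X)
lasso = estimate_network(X, EstimatorConfig(estimator="glasso"))

print(f"true global strength:        {global_strength(W_true):.3f}")
print(f"estimated (partial corr.):   {global_strength(ggm):.3f}")
print(f"estimated (EBIC glasso):     {global_strength(lasso):.3f}")
edges = np.count_nonzero(np.triu(lasso.weights, 1))
print(f"glasso edges kept: {edges} of 36 (truth has 9)")
print(
    "\nOrdinal coarsening attenuates absolute weights, so estimates sit a"
    "\nlittle off truth; rank comparisons across groups are what the"
    "\nanalysis relies on."
)
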