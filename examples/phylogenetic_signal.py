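"""Phylogenetic signal (Pagel's lambda, D statistic) and SES diversity.

Pagel's lambda near 1 says a continuous trait tracks the tree like
Brownian motion, near 0 that it is phylogenetically random; the D
statistic is the binary analogue (D ~ 0 Brownian-clumped, D ~ 1 random).
SES metrics ask whether the species sharing a state are more
phylogenetically clustered than a random tip draw.
"""

import numpy as np

from terebra import (fritz_purvis_d, pagels_lambda, ses_metric, simulate_bm,
                     simulate_mk, simulate_yule_tree)

tree = simulate_yule_tree(0.1, 150, seed=7)

bm_trait = simulate_bm(tree, sigma2=1.0, seed=1)[:, 0]
res = pagels_lambda(tree, bm_trait)
print(f"Brownian trait: lambda = {res.lam:.2f} (expect ~1)")

iid_trait = np.random.default_rng(2).standard_normal(tree.n_tips)
print(f"i.i.d. trait:   lambda = {pagels_lambda(tree, iid_trait).lam:.2f} "
      "(expect ~0)")

states, _ = simulate_mk(tree, 0.03, 0.03, 0, seed=3)
d = fritz_purvis_d(tree, states, n_null=1000, seed=4)
print(f"Mk binary trait: D = {d.d:.2f} "
      f"(p_random={d.p_random:.3f}, p_brownian={d.p_brownian:.3f})")
# A slowly evolving binary trait is clumped, so D sits nearer 0 than 1.

comm = {f"state{s}": [l for l, v in states.items() if v == s]
        for s in (0, 1)}
for name, r in ses_metric(tree, comm, metric="MPD", n_rand=499,
                          seed=5).items():
    print(f"SES MPD {name}: z = {r.z:+.2f}, p = {r.p:.3f}")
# Negative z: species in that state are closer on the tree than chance.
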