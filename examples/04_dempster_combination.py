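"""Combine two bodies of evidence over the five beat classes by hand.

Shows Dempster's rule on two per-beat probability assignments: the fused
mass, the conflict K between the sources, and the belief/plausibility of a
hypothesis set.
"""

import numpy as np

import ecgfuse as ef

m_cnn = np.array([0.70, 0.10, 0.10, 0.05, 0.05])  # CNN leans N
m_svr = np.array([0.40, 0.05, 0.05, 0.45, 0.05])  # SVR torn between N and V

result = ef.combine(m_cnn, m_svr)
print("fused mass :", np.round(result.fused, 4))
print("conflict K :", round(result.conflict, 4))
print("decision   :", result.decided)

bel, pls = ef.bel_pls(result.fused, {"N", "V"})
print("Bel/Pls of {N,V}:", round(bel, 4), round(pls, 4))
# agreement on N concentrates the fused mass there; K is the probability
# mass the two sources assign to contradictory classes.
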