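"""Methylation measurement scales and how to convert between them.

Builds a toy pair of methylated/unmethylated intensity matrices,
derives beta values (proportion methylated) and M values (log2 ratio),
and shows that the base-2 logit links the two scales exactly.
"""

import numpy as np

from diffvar import IntensityPair, beta_to_m, intensities_to_beta, intensities_to_m, m_to_beta

meth = np.array([[900.0, 100.0, 450.0]])
unmeth = np.array([[0.0, 900.0, 450.0]])
pair = IntensityPair(methylated=meth, unmethylated=unmeth)  # offset 100 by default

beta = intensities_to_beta(pair)
m = intensities_to_m(pair)
print("beta values:", np.round(beta.values, 3))
print("M values:   ", np.round(m.values, 3))
# beta near 1 means fully methylated; M is symmetric around 0 (50% methylation)

round_trip = m_to_beta(beta_to_m(beta))
print("logit round-trip error:", float(np.abs(round_trip.values - beta.values).max()))
# the beta -> M -> beta chain is exact to machine precision on (0, 1)
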