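"""How many experiments does a target counting precision require?

The Fisher information of the summed photon count (emitter counts relaxed
to real values through Gamma functions) gives a Cramér–Rao bound per
experiment; dividing by nu and inverting yields the experiments needed for
any target standard error.  Two identical species carry no distinguishing
information at all — the matrix is singular and no number of experiments
suffices.
"""

import numpy as np

from pnrcount import MixtureParams, crlb_at, fisher_information, required_nu

theta = MixtureParams.from_flat([8, 0.1, 10, 0.2])
res = crlb_at(theta, nu=10**10)
print("sqrt CRLB diagonal at nu=1e10 (M1, p1, M2, p2):")
print("  ", np.array2string(np.sqrt(np.diag(res.crlb)), precision=4))

nu_1pct = required_nu(theta, param_index=0, rel_precision=0.01)
print(f"experiments for 1% relative sqrt-CRLB on M1: {nu_1pct:.3e}")

dup = MixtureParams.from_flat([8, 0.1, 8, 0.1])
print("duplicated species singular:", fisher_information(dup).singular)
# The singular case is the white pixel of the two-species precision map:
# the bound does not exist when the species are indistinguishable.
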