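"""High/low-frequency spectral pooling on a toy association graph.

Shows the Rayleigh quotient separating smooth from rough graph signals,
the Chebyshev filter response of the low-pass initialization, and the
convex fusion of the two branch outputs.
"""

import numpy as np

import freqlink as fl
from freqlink.ofd import cheb_filter_response, cheb_lowpass_init, normalized_laplacian

graph = fl.BipartiteGraph(["p1", "p2"], ["m1", "m2"], {(0, 0), (0, 1), (1, 1)})
op = normalized_laplacian(graph)

smooth = np.sqrt(graph.degrees())          # the frequency-0 eigenvector
rough = np.array([1.0, -1.0, 1.0, -1.0])
print(f"Rayleigh quotient of the smooth signal: {fl.rayleigh_quotient(op, smooth):.3f}")
print(f"Rayleigh quotient of an alternating signal: {fl.rayleigh_quotient(op, rough):.3f}")
# 0 means all energy at frequency zero; values near 2 are maximally rough.

coeffs = cheb_lowpass_init(3)
lam = np.linspace(0, 2, 5)
print("low-pass init response g(lambda) on [0,2]:",
      np.round(cheb_filter_response(coeffs, lam), 3))
# gain 1 at frequency 0 decaying linearly to 0 at the top of the spectrum.

rng = np.random.default_rng(0)
X = rng.normal(size=(4, 3))
h_rq = fl.rayleigh_pool(op, X, theta_rq=1.0, mu_rq=1.0, W=np.eye(3))
h_cwt = fl.chebyshev_pool(op, X, coeffs, np.eye(3))
fused = fl.fuse(h_rq, h_cwt, pi=0.5)
print("fused embedding shape:", fused.shape,
      "= 0.5*high-frequency + 0.5*low-frequency branches")
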