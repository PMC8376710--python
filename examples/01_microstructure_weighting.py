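"""Edge-level microstructure math and parameter-weighted connectomes.

Builds a tiny synthetic subject, derives axon volume fraction (AVF) and the
g-ratio from myelin/NODDI compartment fractions, and weights a streamline
count (NOS) matrix to produce the full 14-matrix suite.
"""

import numpy as np

import connectocam as cc

# Scalar identities first: AVF = (1-MVF)(1-ISOVF)ICVF and
# g = sqrt(AVF/(MVF+AVF)).  The second call reproduces the corpus-callosum
# calibration point g = 0.7.
avf = cc.compute_avf(cc.MicrostructureEdgeParams(mvf=0.2, isovf=0.1, icvf=0.5))
g = cc.compute_gratio(mvf=0.51, avf=0.49)
print(f"AVF(MVF=0.2, ISOVF=0.1, ICVF=0.5) = {avf:.2f}")
print(f"g-ratio(MVF=0.51, AVF=0.49)      = {g:.2f}")

# One synthetic subject: a sparse NOS matrix plus the 11 measured
# tract-averaged parameter maps, here drawn uniformly for illustration.
rng = np.random.default_rng(0)
upper = np.triu(rng.random((84, 84)) * (rng.random((84, 84)) < 0.6), k=1)
nos = cc.ConnectomeMatrix("demo", "NOS", 200 * (upper + upper.T))
params = {}
for name in cc.core.MEASURED_PARAMS:
    vals = np.triu(rng.random((84, 84)), k=1)
    params[name] = cc.ConnectomeMatrix("demo", name, vals + vals.T)

suite = cc.build_matrix_suite(nos, params)
print(f"\nmatrix suite for one subject: {len(suite)} matrices")
print("  " + ", ".join(suite))

# Weighted edges are streamline count x tract-averaged parameter, so the NOS
# zero pattern (absent connections) is inherited by every weighted matrix.
rk = suite["RK"]
i, j = 2, 5
print(f"\nNOS[{i},{j}] = {nos.values[i, j]:.1f}, RK map = "
      f"{params['RK'].values[i, j]:.3f}, weighted = {rk.values[i, j]:.1f}")
print("weighted matrices inherit NOS zero pattern:",
      bool(np.all((rk.values == 0) == (nos.values == 0))))
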