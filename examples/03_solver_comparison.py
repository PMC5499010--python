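"""Separating the two artifact sources with three solvers.

On the same cohort:
* nnls  — non-negative least squares, no sum constraint: its *raw*
  coefficients carry no closure artifact, so their correlation isolates
  what the regression itself does;
* svr   — nu-SVR with clip-and-renormalize (the CIBERSORT-style pipeline);
* cls   — least squares constrained to the simplex at fit time.

Comparing the raw-NNLS correlation with the normalized ones shows how much
of the negative correlation the sum-to-one step adds.
"""

import numpy as np

from deconartifact import (FractionSampler, artifact_report,
                           deconvolve_cohort, make_synthetic_signature,
                           pearson, simulate_mixtures)

sig = make_synthetic_signature(250, 22, rho_spec=[((0, 1), 0.0)], seed=11)
mix = simulate_mixtures(sig, (0, 1), FractionSampler(), 200, seed=11)

for solver in ("nnls", "svr", "cls"):
    ests = deconvolve_cohort(sig, mix, solver=solver)
    rep = artifact_report(mix, ests)
    raw = np.array([e.raw for e in ests])
    r_raw = pearson(raw[:, 0], raw[:, 1])
    print(f"{solver:4s}: raw-coefficient r = {r_raw:+.3f}   "
          f"normalized r = {rep.r_est:+.3f}")

print("\nRaw NNLS coefficients stay near-uncorrelated (the truth is "
      "independent); every sum-to-one view is pushed negative.")
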