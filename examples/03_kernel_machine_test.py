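"""Linear vs quadratic kernel machine tests on epistatic data.

Simulates a SNP set whose effect is a pure SNP x SNP interaction (no
marginal effects) and compares the two kernel schemes: the quadratic
kernel models pairwise interactions and should reject, while the linear
kernel sees no marginal signal.
"""

import numpy as np
from scipy.special import expit

from snpset import kernel_machine_test, standardize_columns

rng = np.random.default_rng(3)
n = 400
Z = rng.binomial(2, rng.uniform(0.2, 0.45, 6), size=(n, 6)).astype(float)
sex = rng.binomial(1, 0.5, n).astype(float)
smoke = rng.binomial(1, 0.3, n).astype(float)
X = np.column_stack([np.ones(n), rng.normal(0, 1, n), sex, smoke])

zc, _ = standardize_columns(Z[:, :2])
interaction = zc[:, 0] * zc[:, 1]
y = rng.binomial(1, expit(-0.85 + 0.2 * sex + 0.4 * smoke + 1.0 * interaction)).astype(float)

for kernel in ("linear", "quadratic"):
    res = kernel_machine_test(y, X, Z, smoke, main_kernel=kernel)
    (k1, n1), *rest = res.moments
    print(f"{kernel:9s}: Q = {res.statistic:7.2f}, p = {res.p_value:.4f} "
          f"(component 1 moment-matched to {k1:.2f} * chi2_{n1:.1f})")

# Expected: the quadratic kernel rejects (small p) because its feature
# space contains the pairwise product carrying the signal; the linear
# kernel's p stays near uniform.
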