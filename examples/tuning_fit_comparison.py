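"""Linear vs sigmoid encoding fits on heat-ramp-style activity.

Two noiseless archetypes over the 60 s stimulus window: a linear ramp
and a saturating sigmoid (c=1, k=0.2 1/s, x0=30 s).  Each is fit with
an OLS line and a four-parameter logistic; delta_se = se_lin - se_sig
is positive when the sigmoid describes the data better.  A noisy
sigmoid population is then bootstrapped (resampling neurons) to show
the population-level summary.
"""

import numpy as np

import ceatopo as ct

t = np.arange(0.0, 60.0 + 1e-9, 1.0 / 6.0)

for name, y in (("linear ramp", t / 60.0), ("sigmoid", ct.sigmoid(t, 1.0, 0.2, 30.0, 0.0))):
    lin = ct.fit_linear(t, y)
    sig = ct.fit_sigmoid(t, y, include_linear_limit=True)
    cmp_ = ct.compare_models(lin, sig)
    print(
        f"{name:12s} r2_lin={lin.r2:.4f} r2_sig={sig.r2:.4f} "
        f"k={sig.k:.3f}/s x0={sig.x0:.1f}s delta_se={cmp_.delta_se:+.4f}"
    )

rng = np.random.default_rng(0)
ks = []
for _ in range(100):
    y = ct.sigmoid(t, 1.0, 0.1, 30.0, 0.0) + rng.normal(0.0, 0.1, t.size)
    fit = ct.fit_sigmoid(t, y)
    if fit.converged:
        ks.append(fit.k)
boot = ct.bootstrap_population_stat(np.array(ks), "k", n_boot=10_000, seed=1)
print(f"\npopulation sigmoid k: bootstrap mean {boot.mean:.4f} +/- {boot.sd:.4f} 1/s (true 0.1)")
print("-> positive delta_se flags saturating neurons; the ramp stays linear.")
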