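"""Regime structure of the replicator-ecology ODE models.

Two mass-action schemes abstract the grid model: units of replication X
with helpers H and parasites P (scheme with helpers), and X with stallers
S, parasites and junk (scheme with stallers).  The persistence threshold
is the largest mutation rate at which the replicators survive.
"""

import numpy as np

from rnaqs.ode import (HelperModel, OdeParams1, OdeParams2, StallerModel,
                       integrate, persistence_threshold)

mus = np.arange(0.05, 0.9, 0.05)
y0_p = np.array([0.3, 0.01, 0.001, 0, 0, 0, 0, 0])
y0_np = np.array([0.3, 0.01, 0, 0, 0, 0, 0, 0])

print("helpers scheme: persistence threshold in mu vs helper fraction lam_H")
for lam_h in (0.0, 0.5, 0.95):
    with_p = persistence_threshold(
        lambda mu, l=lam_h: HelperModel(OdeParams1(mu=mu, lam_H=l)),
        mus, y0_p, t_end=2000)
    without_p = persistence_threshold(
        lambda mu, l=lam_h: HelperModel(OdeParams1(mu=mu, lam_H=l,
                                                   include_parasites=False)),
        mus, y0_np, t_end=2000)
    print(f"  lam_H={lam_h:4.2f}: with parasites {with_p}, without {without_p}")
print("-> parasites exploit helpers, so helper production destabilizes the")
print("   system earlier; without parasites, helpers extend the viable range.")

print("\nstallers scheme (mu=0.3): final X and P when parasites are seeded")
for lam_s in (0.0, 0.6):
    m = StallerModel(OdeParams2(mu=0.3, lam_S=lam_s, lam_P=0.0))
    z = np.array([0.3, 0.01, 0.01, 0, 0, 0, 0, 0])
    sol = integrate(m, z, (0, 6000), t_eval=[6000])
    print(f"  lam_S={lam_s}: X={sol.y[0, -1]:.4f}  P={sol.y[2, -1]:.4f}")
print("-> with few stallers parasites overrun the system; enough stallers")
print("   sequester them and the replicators persist.")
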