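"""Fit the three coupled equilibria from synthetic titrations.

Generates noisy titration curves from the published constants —
self-trimerization K = 4.6e4 nM^2, Hill binding K_D = 550 pM with
n_Hill = 1.6, second-trimer K_D' = 1.2 uM — and refits each model,
demonstrating parameter recovery and the derived quantities (C_1/2,
femtomolar effective dissociation constant, binding free energy).

Run:  python examples/04_equilibrium_fits.py
"""

import numpy as np

from pscfcs import equilibria as eq, simulate as sim

trimer = eq.TrimerEquilibrium(K=4.6e4)  # nM^2
print(f"C_1/2 = sqrt(4K/3) = {eq.trimer_c_half(trimer):.0f} nM")

# --- self-trimerization titration (observable: effective stoichiometry n)
table = sim.synth_equilibrium_data(
    "trimer_titration", trimer, np.logspace(0, 4, 12), sigma=0.1, replicates=1, seed=3
)
fit_tri, k_err = eq.fit_trimer_titration(
    list(zip(table["concentration"], table["observable"]))
)
print(f"trimerization fit: K = {fit_tri.K:.3g} nM^2 (true 4.6e4)")

# --- Hill binding at sub-nanomolar chaperone
hill = eq.HillBinding(k_d=550.0, n_hill=1.6)  # pM
table = sim.synth_equilibrium_data(
    "hill", hill, np.geomspace(500, 8000, 8), sigma=0.05, replicates=1, seed=4
)
fit_hill, err = eq.fit_hill(list(zip(table["concentration"], table["observable"])))
print(f"Hill fit: K_D = {fit_hill.k_d:.0f} pM, n = {fit_hill.n_hill:.2f} "
      f"(true 550 pM, 1.6)")

# --- second trimer binding at micromolar chaperone
second = eq.SecondTrimerBinding(k_d_prime=1.2, trimer=trimer)  # uM
table = sim.synth_equilibrium_data(
    "second_trimer", second, np.geomspace(0.2, 10, 8), sigma=0.07, replicates=1, seed=5
)
fit_2, err2 = eq.fit_second_trimer(
    list(zip(table["concentration"], table["observable"])), trimer
)
print(f"second-trimer fit: K_D' = {fit_2.k_d_prime:.2f} uM (true 1.2)")

# --- composed constants
k_eff = (fit_hill.k_d * 1e-12) ** 3 / (trimer.K * 1e-18)  # molar
dg = eq.binding_free_energy(k_eff)
print(f"effective trimer-client K_D = {k_eff*1e15:.1f} fM -> "
      f"binding free energy {dg:.1f} kcal/mol")
# The apparent picomolar binding composes with trimerization into a
# femtomolar effective constant: about -20 kcal/mol of binding energy.
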