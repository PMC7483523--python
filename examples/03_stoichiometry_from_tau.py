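"""From diffusion times to molecular weights and binding stoichiometry.

Diffusion times measured for the chaperone-bound and free (apo) client
are converted to a chaperone:client stoichiometric ratio through the
Stokes-Einstein cubic mass law, using the apo client as the internal
reference. The numbers below are the published Skp-OmpC measurements.

Run:  python examples/03_stoichiometry_from_tau.py
"""

from pscfcs import hydro

conditions = hydro.SolventConditions()  # 23 C, water
focus = hydro.FocusGeometry(waist=0.25e-6)

# free chaperone monomer: hydrodynamic radius 2.3 nm
triple = hydro.stokes_einstein(conditions, radius=2.3e-9, focus=focus)
print(f"R = 2.3 nm  ->  D = {triple.diffusion_coefficient:.3g} m^2/s, "
      f"tau = {triple.tau*1e6:.0f} us")

# bound vs apo client diffusion times (us) and labelled masses (Da)
r, r_sd = hydro.stoichiometric_ratio(
    tau_bound=549e-6, tau_apo=422e-6,
    m_client=40_200.0, m_chaperone=18_800.0,
    tau_bound_sd=27e-6, tau_apo_sd=26e-6,
)
print(f"stoichiometric ratio r = {r:.2f} +/- {r_sd:.2f} chaperone monomers per client")
# r near 3 indicates the client recruits a full chaperone trimer.

# diffusion-limited association rates, monomer vs trimer pathway
d_mono = hydro.stokes_einstein(conditions, radius=2.3e-9).diffusion_coefficient
d_tri = hydro.stokes_einstein(conditions, radius=3.3e-9).diffusion_coefficient
d_client = hydro.stokes_einstein(conditions, radius=2.5e-9).diffusion_coefficient
k_mono = hydro.diffusion_limited_rate((d_mono, 2.3e-9), (d_client, 2.5e-9))
k_tri = hydro.diffusion_limited_rate((d_tri, 3.3e-9), (d_client, 2.5e-9))
print(f"k+ monomer = {k_mono:.2g} /M/s, k+ trimer = {k_tri:.2g} /M/s")
# Both are ~7e9 /M/s: the binding is essentially diffusion-controlled.
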