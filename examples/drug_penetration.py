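"""Spatial drug penetration: radial profiles and their effect on response.

Shows how the dimensionless penetration parameter rho shapes the drug
profile across the proliferating shell, and how limited penetration
weakens treatment in the full trajectory.
"""

import numpy as np

from dlgrowth import (
    DLParams,
    SpatialDrugParams,
    penetration_ratio,
    shell_profile,
    simulate_spatial,
    weekly_protocol,
)

R, R_n = 0.6, 0.3  # outer and necrotic radii, cm

print("Fraction of the surface concentration reaching the necrotic core:")
for rho in (0.0, 1.0, 2.0, 5.0, 10.0):
    print(f"  rho = {rho:4.1f}: {100 * penetration_ratio(R, R_n, rho):5.1f}%")

print("\nRadial profile c(r)/c_b at rho = 5 (drug enters from the surface):")
for r in np.linspace(R_n, R, 7):
    print(f"  r = {r:.2f} cm: {shell_profile(r, R, R_n, 5.0, 1.0):.3f}")

params = DLParams(lambda_net=0.12, lambda_nec=0.05, k_drug=5.7e-3, R_c=0.41, V0=0.25)
schedule = weekly_protocol(1, dose=50.0)
t = np.linspace(0.0, 30.0, 31)
print("\nDay-30 volume under weekly 50 mg/kg as penetration worsens:")
for rho in (0.0, 2.0, 5.0, 10.0):
    traj = simulate_spatial(params, schedule, SpatialDrugParams(rho=rho), t)
    print(f"  rho = {rho:4.1f}: V(30) = {traj.V[-1]:.3f} cm^3")
print(
    "\nrho = 0 is a uniformly distributed drug (small molecules); larger rho "
    "confines the drug\nto the tumor surface (antibody-scale agents), so the "
    "same dose removes less tumor."
)
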