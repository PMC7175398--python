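"""Characteristic times of borehole equilibration.

Computes, for a 10 mm borehole, the radial diffusion time, the turnover
time of the borehole air, and the relaxation time of the vapor content —
the three numbers that tell you whether air leaving the borehole has had
time to equilibrate with the xylem water on the walls.
"""

from boreq import (
    AirflowSpec,
    BoreholeGeometry,
    Environment,
    Species,
    diffusion_time,
    isotope_time_constants,
    turnover_time,
    vapor_time_constant,
)

# A borehole through a 9.9 cm stem; fittings block 2 cm of contact.
geom = BoreholeGeometry(r=0.005, stem_diameter=0.099)
flow = AirflowSpec.from_ml_per_min(80.0)
env = Environment(T=16.8 + 273.15)

t_d = diffusion_time(geom, env)
t_u = turnover_time(geom, flow)
t_w = vapor_time_constant(geom, flow, env)
tc = isotope_time_constants(geom, flow, env, w_in=0.0)

print(f"wetted length            l   = {geom.l * 100:.1f} cm")
print(f"radial diffusion time    t_d = {t_d:.2f} s")
print(f"borehole turnover time   t_u = {t_u:.2f} s")
print(f"vapor relaxation time    t_w = {t_w:.2f} s")
print(f"isotope relaxation t_x,x(18O) = {tc.t_x_x[Species.O18]:.2f} s")
print(f"ratio t_u / t_d              = {t_u / t_d:.0f}")
print()
print(
    "t_u >> t_d: each air parcel resides in the borehole far longer than\n"
    "diffusion needs to carry vapor to and from the walls, so the outflow\n"
    "approaches saturation and isotopic equilibrium with the xylem water."
)
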