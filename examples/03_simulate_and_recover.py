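"""Simulate the ten-species experiment and recover per-species sidedness.

Generates landmark data at the built-in study conditions (sample sizes,
duration distributions, true mean angles), measures the settling-point angles
through the geometry module and runs the Bonferroni-corrected per-species
contrast against zero.  Only the two genuinely right-sided species should be
strongly significant.
"""

from copasym import reference, simulate, species_angle_test
from copasym.pipeline import angles_table

sim = simulate(reference.default_specs(), seed=1)
species_of = {e.experiment_id: e.species_code for e in sim.experiments}
settling = angles_table(
    [o for o in sim.observations if o.timepoint_label == "settling" and o.replicate_id == 1]
)
settling["species_code"] = settling["experiment_id"].map(species_of)

print(f"{'species':8s} {'n':>3s} {'truth':>7s} {'estimate':>9s} {'z':>7s} {'p_bonf':>9s}")
for t in species_angle_test(settling, m=10):
    truth = reference.SETTLING_ANGLE_MEAN[t.species_code]
    star = " *" if t.p_bonf < 0.05 else ""
    print(f"{t.species_code:8s} {t.n:3d} {truth:+7.2f} {t.estimate_deg:+9.2f} "
          f"{t.z:+7.2f} {t.p_bonf:9.2g}{star}")
print("-> estimates track the generating means; 'pac' and 'nan' (true means")
print("   +21.4 and +32.5 deg) are the right-sided maters, the rest are symmetric.")
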