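"""Flow recovery, critical strain, and culture growth bookkeeping.

Three short capabilities in one script: fitting the exponential rebuild
of G' after flow cessation, locating the yield strain of an amplitude
sweep, and computing sampling-corrected fold expansion from culture
records.
"""

import numpy as np

from aggrheo import (
    CultureRecord,
    OscillatorySweep,
    RecoveryTrace,
    critical_strain,
    fit_recovery,
    fold_expansion,
)

# --- recovery after shear: thixotropic structure rebuilds exponentially
t = np.linspace(0.0, 120.0, 40)
g = 520.0 - (520.0 - 140.0) * np.exp(-t / 18.0) + np.random.default_rng(1).normal(0, 3, 40)
fit = fit_recovery(RecoveryTrace(time=t, g_prime=np.abs(g)))
print(f"recovery: G'_inf = {fit.g_inf:.0f} Pa, G'_0 = {fit.g0:.0f} Pa, "
      f"tau_r = {fit.tau_r:.1f} s")

# --- amplitude sweep: where does the slurry yield?
strain = np.logspace(-4, np.log10(0.5), 50)
gp = np.where(strain <= 0.03, 900.0, 900.0 * (strain / 0.03) ** -1.5)
sweep = OscillatorySweep(
    abscissa=strain, g_prime=gp,
    g_double_prime=np.full_like(strain, 90.0), mode="amplitude",
)
print(f"critical strain (10% G' drop): {critical_strain(sweep):.3f}")

# --- fold expansion with daily sampling of 5 mL from a 250 mL vessel
records = [
    CultureRecord(day=0, viable_density=0.21e6, viability=0.90,
                  vessel_volume=250.0, sampled_volume=0.0),
    CultureRecord(day=1, viable_density=0.35e6, viability=0.80,
                  vessel_volume=245.0, sampled_volume=5.0),
    CultureRecord(day=3, viable_density=1.9e6, viability=0.95,
                  vessel_volume=240.0, sampled_volume=10.0),
    CultureRecord(day=5, viable_density=4.8e6, viability=0.96,
                  vessel_volume=235.0, sampled_volume=15.0),
]
for day, fold in fold_expansion(records).items():
    print(f"day {day}: {fold:.1f}-fold expansion")

# tau_r sets how long a printed filament needs to re-solidify; the
# critical strain marks the end of the linear viscoelastic window; fold
# expansion credits cells removed by sampling back to the totals so the
# growth rate is not understated.
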