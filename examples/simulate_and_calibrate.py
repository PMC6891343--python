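"""Simulate a six-species measurement campaign and fit each calibration line.

Generates the full study design (59 leaves across six broadleaf species)
with the default instrument noise, computes each leaf's optical depth from
the raw intensity readings, and fits tau*L_A = C1*M_w + C0 per species.
The printed slopes should recover each species' generating value (C_A 0.47,
O_C 0.45, Q_S 0.45, V_V 0.39, Q_I 0.45, L_N 0.31 cm^2/mg) to within the
fit's standard error, with adjusted R^2 typically above 0.9.
"""

import io
import warnings

from leafthz import SPECIES_DEFAULTS, fit_calibration, read_measurements, simulate_study

warnings.simplefilter("ignore")

df, truth = simulate_study(seed=42)
print(f"simulated {len(df)} leaves across {df.species_code.nunique()} species\n")

buf = io.StringIO()
df.to_csv(buf, index=False)
buf.seek(0)
records = [leaf for leaf, _ in read_measurements(buf).records]

by_species = {}
for leaf in records:
    by_species.setdefault(leaf.species_code, []).append(leaf)

print(f"{'species':>8} {'n':>3} {'C1 (cm^2/mg)':>14} {'generating K':>13} {'adj R^2':>8}")
for code, leaves in sorted(by_species.items()):
    m = fit_calibration(leaves, species_code=code)
    print(
        f"{code:>8} {m.n:>3} {m.C1:>8.3f} ± {m.se_C1:.3f}"
        f" {SPECIES_DEFAULTS[code].slope_K:>13.2f} {m.adj_r2:>8.3f}"
    )
print(
    "\nEach fitted slope C1 estimates the species' water-absorption slope"
    " K = alpha/rho_w less dry-matter losses; adj R^2 close to 1 means the"
    " product tau*L_A tracks the gravimetric water mass almost perfectly."
)
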