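"""Compose the four model stratum-corneum systems.

The SC lipid matrix is mixed from cholesterol (CHOL), the ceramide
N-stearoylsphingosine (DPCE) and behenic acid (BCN) at an integer ratio,
optionally extended with linoleic acid (LA) and solvated with polarizable
water, half-replaced by ethanol in the enhancer systems.
"""

from scmem.protocols import table_compositions

for name, summary in table_compositions().items():
    counts = summary["counts"]
    lipids = {k: v for k, v in counts.items() if k in ("CHOL", "DPCE",
                                                       "BCN", "LA")}
    solvent = {k: v for k, v in counts.items() if k in ("PW", "EtOH")}
    print(f"{name:12s} lipids {lipids}  solvent {solvent}  "
          f"ions Na+ {counts.get('NA', 0)} / Cl- {counts.get('CL', 0)}  "
          f"net charge {summary['net_charge']:+d} e")

print()
print("Counts follow the integer-ratio rules: 625 lipids at 1:1:1 split "
      "208/209/208 (remainder to the ceramide), the 18:18:18:5 ratio adds "
      "floor(208*5/18) = 57 LA, and the 50% molar solvent is an equal "
      "bead split.  The net charge is reported as composed; ion counts "
      "are explicit inputs of the model systems.")
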