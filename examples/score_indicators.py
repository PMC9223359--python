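"""Score raw indicator observations on the packaged threshold ladders.

Each indicator has a piecewise-linear ladder (or a parabolic / composite
rule) mapping raw monitoring values onto a [0, 1] health score.
"""

import riverhealth as rh

registry = rh.default_registry()

# Dissolved oxygen: a benefit ladder — higher concentration, higher score.
do = rh.RawObservation("Pangduo", 2011, "C6", {"value": 6.75})
print(f"DO 6.75 mg/L            -> score {registry['C6'].score(do):.2f}")

# Flow deviation: a cost ladder — larger deviation from natural runoff,
# lower score.
dev = rh.RawObservation("Pangduo", 2011, "C1", {"value": 0.55})
print(f"flow deviation 0.55     -> score {registry['C1'].score(dev):.2f}")

# Nutrients: four concentrations scored separately, worst one governs.
nutrients = rh.RawObservation(
    "Lhasa", 2011, "C7", {"CODMn": 2.0, "COD": 15.0, "BOD": 3.75, "NH3N": 0.15}
)
print(f"nutrients (BOD worst)   -> score {registry['C7'].score(nutrients):.2f}")

# Water-resource utilization: parabolic — 30% utilization is the healthy
# optimum, 60% or more scores zero.
for rate in (0.10, 0.30, 0.60):
    wru = rh.RawObservation("Lhasa", 2011, "C13", {"value": rate})
    print(f"utilization {rate:.0%}         -> score {registry['C13'].score(wru):.2f}")

# The scores quantify how far each measurement sits from the undisturbed
# reference state (1 = pristine, 0 = worst threshold).
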