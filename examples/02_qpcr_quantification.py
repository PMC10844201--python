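"""qPCR quantification: standard curve, copy numbers, herring DNA fraction.

Builds a dilution-series standard curve spanning 3x10^0..3x10^6
copies/reaction, quantifies duplicate sample wells for herring and sprat,
and converts copy numbers into the herring DNA fraction that feeds the
calibration model.
"""

import numpy as np

from ednabycatch import (
    QPCRMeasurement,
    aggregate_technical_replicates,
    compute_fraction,
    fit_standard_curve,
)
from ednabycatch.synthetic import DILUTION_SERIES_COPIES

slope_true, intercept_true = -3.3219, 38.0
points = [(c, intercept_true + slope_true * np.log10(c)) for c in DILUTION_SERIES_COPIES]
curve = fit_standard_curve(points)
print(f"standard curve over {len(points)} dilution levels "
      f"({min(DILUTION_SERIES_COPIES):.0f}..{max(DILUTION_SERIES_COPIES):.0f} copies/reaction):")
print(f"  slope {curve.slope:.4f} cycles/decade, efficiency {curve.efficiency:.3f} "
      f"(1.0 = perfect doubling), R^2 {curve.r_squared:.4f}")

# duplicate wells for one water sample: herring ~300 copies, sprat ~700 copies
wells = []
for target, copies in (("herring", 300.0), ("sprat", 700.0)):
    for rep in range(2):
        cq = intercept_true + slope_true * np.log10(copies) + (-1) ** rep * 0.05
        wells.append(QPCRMeasurement("sample1", target, cq, rep))

per_sample = aggregate_technical_replicates(wells, curve)
herring = per_sample["sample1"]["herring"]
sprat = per_sample["sample1"]["sprat"]
frac = compute_fraction(herring, sprat, sample_id="sample1")
print(f"\nsample1: herring {herring:.0f} copies, sprat {sprat:.0f} copies "
      f"(geometric mean of duplicates)")
print(f"herring DNA fraction = {frac.herring_fraction:.3f}  "
      f"# the observed fraction O fed to the calibration model")
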