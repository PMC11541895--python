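"""Calibrate area-fraction response against known 9E/9Z molar mixtures.

Five mixtures spanning 1-99% molar E fraction (technical triplicate, 1%
multiplicative noise) are simulated; the fitted line's slope near 1 and
intercept near 0 show that the diagnostic-pair area ratio reads out the
molar cis/trans composition directly.
"""

from ccmeldi import fit_calibration
from ccmeldi.simulate import calibration_mixtures, simulate_calibration_series

table = simulate_calibration_series(
    ratios=(99.0, 90.0, 50.0, 10.0, 1.0), noise_cv=0.01, replicates=3, seed=42
)
print(table.groupby("molar_e_pct").area_fraction_pct.mean().rename("mean area fraction %"))

fit = fit_calibration(calibration_mixtures(table))
print(f"\nslope {fit.slope:.4f}  intercept {fit.intercept:.3f}  r² {fit.r2:.4f}")
# slope ≈ 1 and r² > 0.99: the measured area fraction is an unbiased
# estimator of the molar E-isomer fraction at these noise levels.
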