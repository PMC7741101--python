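"""Calibrate a single radiocarbon determination and read off its HPD region.

Builds a small synthetic calibration curve with realistic wiggles, turns a
measured ¹⁴C age of 900 ± 30 BP into a probability density over calendar
years, and prints the mode and the 95% highest-density region.  With a
wiggly curve the density is multimodal, which is why the HPD region (the
smallest set of years holding 95% of the mass) can be several intervals.
"""

from paleospd import (
    RadiocarbonDetermination,
    calibrate,
    hpd_region,
    make_curve,
)

curve = make_curve("wiggly", amplitude=40.0, period=300.0, sigma_curve=8.0)
det = RadiocarbonDetermination(c14_age=900.0, sigma=30.0)
density = calibrate(det, curve)

print(f"determination: {det.c14_age:.0f} ± {det.sigma:.0f} ¹⁴C BP")
print(f"density support: {density.grid[0]}–{density.grid[-1]} cal BP "
      f"(total mass {density.total:.6f})")
print(f"mode: {density.argmax_bp()} cal BP")
for w in hpd_region(density, level=0.95):
    print(f"95% HPD interval: {w.start_bp}–{w.end_bp} cal BP "
          f"({w.n_years} years)")
# The mode is the single most probable calendar year; the HPD intervals
# together contain at least 95% of the calibrated probability mass.
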