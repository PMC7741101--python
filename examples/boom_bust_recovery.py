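"""Recover a boom-bust population history from synthetic tree-ring dates.

Samples 500 dated events from a population that rises to a peak at
AD 1300 and then collapses, builds the degenerate-distribution SPD,
smooths it with the 21-year / 5-sd Gaussian kernel, and checks how close
the recovered peak is to the truth.
"""

import numpy as np

from paleospd import (
    BinnableDate,
    CalendarWindow,
    PopulationModel,
    TreeRingRecord,
    ad_to_bp,
    bin_dates,
    build_spd,
    degenerate_density,
    population_curve,
    sample_event_years,
    smooth_spd,
)

window = CalendarWindow(start_bp=1750, end_bp=150)
span = CalendarWindow(start_bp=ad_to_bp(600), end_bp=ad_to_bp(1600))
model = PopulationModel()  # boom-bust, peak AD 1300
pop = population_curve(model, span)

rng = np.random.default_rng(7)
years = sample_event_years(pop, 500, rng)
records = [
    TreeRingRecord(f"S{i}", "Montezuma, CO", int(y), "r") for i, y in enumerate(years)
]
dates = [BinnableDate(i, r.site_id, float(r.year_bp)) for i, r in enumerate(records)]
densities = {i: degenerate_density(r) for i, r in enumerate(records)}
spd = build_spd(bin_dates(dates), densities, window)
smoothed = smooth_spd(spd)

peak = smoothed.peak_year_ad()
sel = (smoothed.years_ad >= 1300) & (smoothed.years_ad <= 1600)
slope = np.polyfit(smoothed.years_ad[sel].astype(float), smoothed.density[sel], 1)[0]

print(f"true population peak: AD {model.peak_ad}")
print(f"recovered SPD peak:   AD {peak}  (error {peak - model.peak_ad:+d} years)")
print(f"post-peak AD 1300-1600 trend: {slope:+.2e} per year "
      f"({'decline' if slope < 0 else 'growth'})")
print(f"SPD mass {smoothed.total:.1f} over {len(records)} singleton site-phases")
# A peak within ±50 years of the truth and a negative post-peak trend are
# the two directional signals the dates-as-data proxy is expected to carry.
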