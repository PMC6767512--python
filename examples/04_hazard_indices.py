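"""Score yearly drought / heat / soil-moisture / fire hazard intensities.

Monthly series become standardized anomalies (SPI for precipitation);
months beyond +-1 sd define yearly severity/frequency/duration, which
fuzzy-linear memberships squash to [0,1] and the fuzzy-gamma operator
(gamma = 0.9) overlays into one intensity per object-year.
"""

import geodefol as gd
from geodefol.hazards import (
    compute_spi, fire_severity, hazard_index, monthly_anomalies, yearly_dimensions,
)

tidy, panel, _ = gd.generate_climate_panel(gd.PanelSpec(seed=3))
precip = tidy[tidy["variable"] == "precip"][["object_id", "year", "month", "value"]]
tmax = tidy[tidy["variable"] == "tmax"][["object_id", "year", "month", "value"]]

spi = compute_spi(precip, timescale_months=12, baseline=(1989, 2008))
drought_dims = yearly_dimensions(spi, "deficit", threshold=1.0)
drought = hazard_index(drought_dims, gamma=0.9)
print("drought intensity, object 1:")
print(drought[drought.object_id == 1].tail(5).to_string(index=False))

heat = hazard_index(
    yearly_dimensions(monthly_anomalies(tmax, (1988, 2007)), "excess"), gamma=0.9
)
print(f"\nheat index range: {heat['index'].min():.2f}..{heat['index'].max():.2f}")

fires = gd.generate_fire_records(19, (2010, 2017), rate=0.6, seed=4)
sev = fire_severity(fires, range(1, 20), range(2010, 2018), gamma=0.9)
print(f"fire severity > 0 in {(sev['index'] > 0).mean() * 100:.0f}% of object-seasons")
# All indices live in [0,1]: 0 = no anomalous months, values near 1 =
# severe, frequent and persistent exceedances in that year.
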