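"""Path-length-normalize plate-reader OD600 readings.

Microtiter wells have fill-dependent optical paths; the water absorbance
difference OD977 − OD900 (relative to a 1 cm cuvette reference) estimates
the path, and OD600/d gives absorbance per cm comparable across wells.
"""

import pandas as pd

from microhet import normalize_od_table

plate = pd.DataFrame({
    "well":  ["A1", "A2", "A3", "B1"],
    "od600": [0.50, 0.30, 0.65, 0.48],
    "od900": [0.10, 0.10, 0.11, 0.10],
    "od977": [0.28, 0.19, 0.29, 0.27],
})
out = normalize_od_table(plate, od977_ref=0.28, od900_ref=0.10)
print(out.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

# A1 sits at exactly the reference path (d = 1 cm) so its OD is unchanged;
# A2's half-filled well (d = 0.5 cm) doubles on normalization — the wells
# become comparable to cuvette readings.
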