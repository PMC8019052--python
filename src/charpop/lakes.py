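"""Study-lake metadata: morphometry, transparency and char abundance.

These are measured field inputs to the analysis (the lake morphometry /
fish community table of the study), not simulated quantities.  Densities
(fish per hectare) are derived from abundance and surface area by
:func:`charpop.permanova.char_density`.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = [
    "group", "lake", "latitude", "longitude", "surface_area_ha",
    "volume_1e5_m3", "max_depth_m", "mean_depth_m", "prop_area_lt3m",
    "prop_vol_lt3m", "secchi_depth_m", "community", "abundance",
    "abundance_ci", "density_fish_ha",
]

_ROWS = [
    ("Fog", "Fog1", 68.684, 149.082, 3.5, 2.9, 19.7, 8.4, 0.33, 0.29, 4.9,
     "AC,SS", 448, (290, 693), 128),
    ("Fog", "Fog2", 68.679, 149.091, 5.9, 4.4, 19.8, 7.8, 0.21, 0.34, 7.1,
     "AC,SS", 163, (105, 288), 27),
    ("Fog", "Fog3", 68.673, 149.088, 3.9, 3.1, 21.0, 7.6, 0.30, 0.31, 6.0,
     "AC,SS", 666, (477, 1073), 170),
    ("Fog", "Fog5", 68.678, 149.065, 0.7, 0.3, 9.9, 3.5, 0.52, 0.61, 5.0,
     "AC,SS", 75, (55, 119), 107),
    ("LTER", "LTER345", 68.623, 149.151, 30.7, 38.2, 28.6, 12.3, 0.16, 0.22, 1.5,
     "AC,AG,LT,SS", 277, (177, 540), 9),
    ("LTER", "LTER347", 68.625, 149.139, 13.5, 7.6, 17.6, 5.6, 0.28, 0.45, 1.8,
     "AC,AG,LT,SS", 73, (40, 196), 5),
    ("LTER", "LTER348", 68.641, 149.127, 5.7, 1.9, 9.6, 3.2, 0.56, 0.70, 3.7,
     "AC,BT,SS", 331, (227, 563), 58),
]

LAKE_TABLE = pd.DataFrame(_ROWS, columns=_COLUMNS)
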