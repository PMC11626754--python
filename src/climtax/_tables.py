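"""Built-in reference tables for the default synthetic-data configuration.

Numbers are transcribed from the published cross-tabulations of a national
school-injury surveillance study (five climate patterns, two injury
sub-patterns each): per-leaf categorical percentages, per-leaf mean age,
leaf sizes, and the five climate-pattern centroids on their native scales.
They parameterize :func:`climtax.synthetic.default_config` and are not used
by any estimation code.
"""

from __future__ import annotations

import numpy as np

# Climate items, in canonical column order.
CLIMATE_ITEMS = [
    "closeness",      # teachers and students' closeness, 0-100
    "efforts",        # efforts involved, 0-100
    "violence",       # violence cases, count scale (>= 0)
    "satisfaction",   # teachers' satisfaction, 0-100
    "parents",        # parents involvement, 0-100
    "gpf",            # general positive feeling, 0-100
]

# Five climate-pattern centroids (rows) x six items (columns), native scales,
# spanning a good (row 3) to poor (row 5) climate spectrum.
CLIMATE_CENTROIDS = np.array(
    [
        [72.574, 65.733, 9.043, 77.386, 87.419, 82.741],
        [59.320, 56.787, 11.858, 76.064, 88.062, 72.409],
        [87.489, 82.626, 5.096, 80.000, 90.473, 93.520],
        [63.047, 59.159, 12.455, 60.428, 80.514, 74.369],
        [46.302, 42.616, 14.560, 69.648, 83.265, 59.400],
    ]
)

# Observed case counts per climate pattern and per leaf sub-pattern.
CLASS_CASE_COUNTS = np.array([3414, 3210, 1523, 1865, 843])
LEAF_CASE_COUNTS = np.array(
    [[900, 2514], [2055, 1155], [1136, 387], [713, 1152], [477, 366]]
)

# Mean age group per leaf (flattened row-major: 1.1, 1.2, 2.1, ..., 5.2).
LEAF_AGE_MEANS = np.array(
    [8.393, 9.155, 9.152, 8.595, 8.595, 9.560, 9.485, 8.518, 8.724, 9.203]
)

# Per-leaf categorical percentages (columns ordered 1.1, 1.2, ..., 5.2).
# Keys and category labels match the injury-record schema; "extremities" is
# split into foot/hand downstream. Columns sum to ~100 up to printed rounding,
# except cluster 1.1's injury-type column whose trauma entry is an evident
# misprint in the source (column sums to ~37) and is therefore set to the
# remainder that completes the column to 100.
_TRAUMA_11 = 100.0 - (0.4 + 16.2 + 6.0 + 8.7)

LEAF_CATEGORY_PCT = {
    "gender": {
        "boy": [27.4, 84.1, 70.7, 67.5, 84.9, 25.8, 68.2, 70.3, 66.7, 67.8],
        "girl": [72.6, 15.9, 29.3, 32.5, 15.1, 74.2, 31.8, 29.7, 33.3, 32.2],
    },
    "event_place": {
        "classroom": [35.7, 7.2, 12.8, 20.7, 13.9, 15.5, 16.5, 15.3, 12.4, 24.0],
        "corridor": [11.9, 7.1, 7.3, 6.8, 7.6, 9.8, 6.5, 8.8, 8.4, 7.1],
        "sportsground": [6.1, 13.6, 15.5, 6.7, 15.3, 8.5, 12.8, 12.7, 14.3, 10.4],
        "sports_hall": [3.0, 4.0, 4.1, 3.4, 3.6, 6.2, 3.5, 2.1, 1.5, 5.2],
        "stairs": [5.4, 2.1, 2.0, 3.4, 1.6, 5.2, 2.4, 2.9, 2.5, 2.7],
        "yard": [18.1, 47.1, 54.2, 12.0, 41.8, 33.6, 12.5, 53.2, 57.7, 9.8],
        "otherwise": [19.7, 19.0, 4.2, 47.1, 16.2, 21.2, 45.8, 5.1, 3.3, 40.7],
    },
    "event_term": {
        "before_after_school": [4.0, 2.7, 2.5, 2.7, 2.0, 2.6, 2.0, 2.6, 2.5, 2.2],
        "break": [40.6, 50.2, 66.9, 9.7, 50.5, 47.0, 6.6, 76.1, 68.1, 7.4],
        "lesson": [17.4, 10.4, 13.8, 15.8, 13.0, 16.5, 17.7, 11.2, 12.4, 18.3],
        "sports_class": [2.6, 3.5, 3.2, 1.6, 2.6, 3.6, 4.8, 2.3, 4.4, 2.2],
        "otherwise": [35.4, 33.1, 13.6, 70.2, 31.8, 30.2, 69.0, 7.7, 5.9, 69.9],
    },
    "anatomic_place": {
        "extremities": [42.4, 39.9, 39.3, 35.6, 22.9, 74.9, 45.4, 33.3, 42.3, 43.2],
        "head": [52.3, 52.6, 52.4, 56.8, 70.9, 17.8, 47.4, 60.2, 51.8, 47.8],
        "other": [5.3, 7.5, 8.4, 7.5, 6.3, 7.2, 7.2, 6.4, 5.9, 9.0],
    },
    "injury_cause": {
        "game": [10.7, 54.6, 54.1, 26.1, 57.2, 23.8, 47.5, 42.4, 56.4, 26.8],
        "falling_from_height": [4.3, 3.0, 3.6, 3.6, 2.3, 2.6, 3.1, 3.3, 3.6, 2.7],
        "slipping": [49.8, 15.1, 11.2, 43.1, 15.2, 49.9, 23.4, 21.2, 20.5, 28.1],
        "violence": [5.4, 4.7, 5.0, 5.8, 6.3, 2.1, 8.3, 5.8, 3.8, 5.2],
        "otherwise": [29.8, 22.6, 26.0, 21.3, 19.1, 21.8, 17.6, 27.2, 15.7, 37.1],
    },
    "injury_type": {
        "medium_deep_incision": [0.4, 0.5, 0.2, 0.8, 0.9, 0.5, 0.1, 0.5, 0.6, 0.3],
        "superficial_incision": [16.2, 11.1, 11.4, 15.2, 16.9, 8.3, 12.3, 12.8, 16.6, 16.4],
        "rubbing_tear": [6.0, 7.1, 7.0, 6.5, 6.5, 4.7, 5.6, 7.2, 4.8, 4.9],
        "trauma": [_TRAUMA_11, 71.0, 69.0, 72.3, 68.3, 75.7, 75.3, 66.8, 69.9, 66.9],
        "otherwise": [8.7, 10.3, 12.3, 5.3, 7.3, 10.7, 6.5, 12.7, 8.2, 11.5],
    },
}

# Marginal foot:hand split of extremity injuries, and the marginal share of
# light local burns (absent from the per-leaf table; carved out of
# "otherwise" when building generator distributions).
FOOT_SHARE_OF_EXTREMITIES = 1810.0 / (1810.0 + 2410.0)
LIGHT_BURN_PCT = 0.1
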