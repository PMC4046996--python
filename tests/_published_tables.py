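"""Published per-strategy expected QALYs and costs, used as worked-example
inputs for the incremental-analysis arithmetic.

Values are exactly as printed in the source study's results tables (base-case
probabilistic analysis and the five sensitivity analyses); QALYs are on the
printed reporting scale, costs in GBP.
"""

# strategy label -> (expected QALYs, expected costs), base case, ids 1..7
BASE_CASE = [
    ("UC", 25056.393, 19317.0),
    ("E", 25056.401, 20055.0),
    ("E+FE", 25056.416, 20094.0),
    ("E+FE+HI", 25056.416, 22091.0),
    ("E+FE+F", 25056.416, 21638.0),
    ("E+HI", 25056.403, 21991.0),
    ("E+FE+F+HI", 25056.417, 23596.0),
]

# printed base-case incremental steps along the frontier: (strategy, dQALY, dCost)
BASE_CASE_INCREMENTS = [("E+FE", 0.023, 777.0), ("E+FE+F+HI", 0.001, 3502.0)]

# sensitivity analyses: the rows the published table reports, in printed order
SENSITIVITY = {
    "SA1": [
        ("UC", 25056.054, 20813.0),
        ("E", 25056.070, 23732.0),
        ("E+FE", 25056.079, 25715.0),
        ("E+FE+F+HI", 25056.081, 37863.0),
    ],
    "SA2": [
        ("UC", 25056.159, 19470.0),
        ("E+FE", 25056.177, 19695.0),
        ("E+FE+F+HI", 25056.177, 21656.0),
    ],
    "SA3": [
        ("UC", 25056.404, 18839.0),
        ("E", 25056.413, 19530.0),
        ("E+FE", 25056.416, 20094.0),
        ("E+FE+F+HI", 25056.417, 23596.0),
    ],
    "SA4": [
        ("UC", 44349.503, 32867.0),
        ("E+FE", 44349.544, 33050.0),
        ("E+FE+F+HI", 44349.546, 36531.0),
    ],
    "SA5": [
        ("UC", 25056.511, 15279.0),
        ("E+FE", 25056.519, 16562.0),
        ("E+FE+F+HI", 25056.520, 20080.0),
    ],
}

# printed incremental (dQALY, dCost) between successive reported rows
SENSITIVITY_INCREMENTS = {
    "SA1": [(0.016, 2919.0), (0.009, 1983.0), (0.002, 12148.0)],
    "SA2": [(0.018, 225.0), (0.000, 1961.0)],
    "SA3": [(0.009, 691.0), (0.003, 564.0), (0.001, 3502.0)],
    "SA4": [(0.041, 183.0), (0.002, 3481.0)],
    "SA5": [(0.008, 1283.0), (0.001, 3518.0)],
}
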