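"""Taste-chemical vocabulary, molar masses, and concentration ranges.

The panel of eleven chemicals covers the three sugars used for the
sweetness score, seven organic acids summed (as molarities) into the
sourness score, and total tannin (tannic-acid equivalents) for
astringency.  Concentration ranges are the observed extremes across a
23-bottle white-wine survey; the sweet/dry sub-ranges encode the
two-group structure of that survey (a minority of markedly sweet wines
against a drier majority) and are constructed so the linear sweetness
and sourness formulas give disjoint score bands for the two groups.
"""

from __future__ import annotations

SUGARS: tuple[str, ...] = ("sucrose", "glucose", "fructose")

ACIDS: tuple[str, ...] = (
    "citric",
    "malic",
    "tartaric",
    "succinic",
    "lactic",
    "acetic",
    "formic",
)

TANNIN = "tannin"

#: Canonical chemical order used throughout (CSV columns, sensitivity matrices).
CHEMICALS: tuple[str, ...] = SUGARS + ACIDS + (TANNIN,)

#: g/mol, standard reference values for the organic acids.
MOLAR_MASS_G_PER_MOL: dict[str, float] = {
    "citric": 192.12,
    "malic": 134.09,
    "tartaric": 150.09,
    "succinic": 118.09,
    "lactic": 90.08,
    "acetic": 60.05,
    "formic": 46.03,
}

#: Relative perceived-sweetness weights for the three sugars.
SWEETNESS_WEIGHTS: dict[str, float] = {
    "glucose": 0.75,
    "sucrose": 1.0,
    "fructose": 1.5,
}

#: Observed global concentration extremes (mg/L) across the wine survey.
CONCENTRATION_RANGES: dict[str, tuple[float, float]] = {
    "sucrose": (32.0, 4232.0),
    "glucose": (95.0, 31005.0),
    "fructose": (376.0, 64258.0),
    "malic": (311.0, 46291.0),
    "tartaric": (996.0, 21191.0),
    "succinic": (101.0, 4588.0),
    "formic": (96.0, 1855.0),
    "lactic": (0.0, 1318.0),
    "citric": (0.0, 253.0),
    "acetic": (75.0, 272.0),
    "tannin": (72.0, 573.0),
}

# Per-cluster sub-ranges (mg/L).  Chosen so that:
#   max dry sweetness (0.75 g + s + 1.5 f)  = 26,732 <  min sweet = 51,032
#   max dry sourness  (sum conc/molar mass) = 99.96  <  min sweet = 213.6
# which guarantees strict sweet-above-dry separation of both scores for
# any draw, including convex mixtures within a cluster.  Tannin spans the
# full range in both groups (astringency was similar across groups).
CLUSTER_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "sweet": {
        "sucrose": (32.0, 4232.0),
        "glucose": (8000.0, 31005.0),
        "fructose": (30000.0, 64258.0),
        "malic": (20000.0, 46291.0),
        "tartaric": (6000.0, 21191.0),
        "succinic": (1000.0, 4588.0),
        "formic": (400.0, 1855.0),
        "lactic": (500.0, 1318.0),
        "citric": (100.0, 253.0),
        "acetic": (75.0, 272.0),
        "tannin": (72.0, 573.0),
    },
    "dry": {
        "sucrose": (32.0, 4232.0),
        "glucose": (95.0, 6000.0),
        "fructose": (376.0, 12000.0),
        "malic": (311.0, 6000.0),
        "tartaric": (996.0, 4000.0),
        "succinic": (101.0, 1000.0),
        "formic": (96.0, 400.0),
        "lactic": (0.0, 500.0),
        "citric": (0.0, 253.0),
        "acetic": (75.0, 272.0),
        "tannin": (72.0, 573.0),
    },
}

#: Fraction of base wines assigned to the sweet group (7 of 23 in the survey).
SWEET_FRACTION = 7.0 / 23.0
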