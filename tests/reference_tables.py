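"""Published reference tables from the candidate-gene latitudinal study.

These are frozen printed values used as regression-test inputs: the ten
populations with representative latitudes (degrees north) and per-network
carrier frequencies with their denominators (sample sizes after removing
individuals missing any network SNP).  The "Yamane" row of the original
frequency table is read as the Yemenite population (latitude 16).
"""

POPULATION_LATITUDE = {
    "Sub-Saharan": 8,
    "Yemenite": 16,
    "Egypt": 30,
    "Arab Muslim": 28,
    "Arab Christian": 32,
    "Maghreb": 34,
    "Spain": 40,
    "W. Eur. ancestry": 50,
    "India": 25,
    "Amerindian": 15,
}

# network -> population -> (carrier frequency, denominator)
NETWORK_CARRIER_FREQUENCIES = {
    "65_1": {
        "Sub-Saharan": (0.667, 99), "Yemenite": (0.662, 71), "Egypt": (0.571, 49),
        "Arab Muslim": (0.510, 51), "Arab Christian": (0.453, 64), "Maghreb": (0.474, 78),
        "Spain": (0.375, 72), "W. Eur. ancestry": (0.413, 143), "India": (0.828, 29),
        "Amerindian": (0.667, 18),
    },
    "65_2": {
        "Sub-Saharan": (0.021, 95), "Yemenite": (0.278, 72), "Egypt": (0.273, 44),
        "Arab Muslim": (0.552, 58), "Arab Christian": (0.817, 60), "Maghreb": (0.590, 78),
        "Spain": (0.805, 77), "W. Eur. ancestry": (0.886, 149), "India": (0.344, 32),
        "Amerindian": (0.529, 17),
    },
    "65_3": {
        "Sub-Saharan": (0.142, 106), "Yemenite": (0.595, 74), "Egypt": (0.723, 47),
        "Arab Muslim": (0.704, 54), "Arab Christian": (0.786, 70), "Maghreb": (0.662, 80),
        "Spain": (0.836, 73), "W. Eur. ancestry": (0.800, 145), "India": (0.667, 33),
        "Amerindian": (0.526, 19),
    },
    "65_4": {
        "Sub-Saharan": (1.000, 78), "Yemenite": (0.897, 68), "Egypt": (0.949, 39),
        "Arab Muslim": (0.895, 57), "Arab Christian": (0.966, 59), "Maghreb": (0.966, 58),
        "Spain": (0.870, 54), "W. Eur. ancestry": (0.873, 150), "India": (0.793, 29),
        "Amerindian": (1.000, 13),
    },
    "65_5": {
        "Sub-Saharan": (0.420, 69), "Yemenite": (0.629, 35), "Egypt": (0.571, 35),
        "Arab Muslim": (0.500, 42), "Arab Christian": (0.667, 48), "Maghreb": (0.527, 55),
        "Spain": (0.706, 51), "W. Eur. ancestry": (0.687, 131), "India": (0.792, 24),
        "Amerindian": (0.818, 11),
    },
    "65_6": {
        "Sub-Saharan": (0.620, 71), "Yemenite": (0.721, 68), "Egypt": (0.703, 37),
        "Arab Muslim": (0.800, 50), "Arab Christian": (0.709, 55), "Maghreb": (0.607, 56),
        "Spain": (0.722, 54), "W. Eur. ancestry": (0.655, 142), "India": (0.538, 26),
        "Amerindian": (0.600, 10),
    },
    "65_7": {
        "Sub-Saharan": (0.877, 106), "Yemenite": (0.892, 74), "Egypt": (0.729, 48),
        "Arab Muslim": (0.727, 55), "Arab Christian": (0.600, 70), "Maghreb": (0.612, 80),
        "Spain": (0.554, 74), "W. Eur. ancestry": (0.574, 148), "India": (0.758, 33),
        "Amerindian": (0.750, 20),
    },
}

# genome-wide inter/intra-chromosomal association counts at the 0.84 threshold:
# candidate genes (3 inter, 38 intragenic) vs remainder of the genome
ENRICHMENT_TABLE = (3, 38, 618, 21083)
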