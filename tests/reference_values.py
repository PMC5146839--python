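"""Frozen published summaries of the packaged cohort, used as expectations.

Risk entries are (posterior mean, posterior SD, significant); ``None``
marks a quantity that is not applicable (the male classes of pyometra).
"""

#: Published per-disease risk summaries, keyed disease -> quantity.
PUBLISHED_RISK = {
    "ATOP": {"OR_F": (2.24, 0.27, True), "OR_M": (1.51, 0.27, True),
             "RR_F": (2.21, 0.26, True), "RR_M": (1.50, 0.13, True)},
    "AIHA": {"OR_F": (1.67, 0.28, True), "OR_M": (1.76, 0.31, True),
             "RR_F": (1.67, 0.28, True), "RR_M": (1.76, 0.31, True)},
    "CMG":  {"OR_F": (1.19, 0.37, False), "OR_M": (1.97, 1.01, False),
             "RR_F": (1.19, 0.37, False), "RR_M": (1.97, 1.01, False)},
    "COL":  {"OR_F": (1.03, 0.11, False), "OR_M": (0.98, 0.09, False),
             "RR_F": (1.03, 0.11, False), "RR_M": (0.98, 0.08, False)},
    "ADD":  {"OR_F": (1.49, 0.32, True), "OR_M": (2.07, 0.54, True),
             "RR_F": (1.49, 0.32, True), "RR_M": (2.07, 0.53, True)},
    "HYPO": {"OR_F": (3.03, 0.39, True), "OR_M": (1.29, 0.11, True),
             "RR_F": (2.99, 0.39, True), "RR_M": (1.28, 0.10, True)},
    "IMPA": {"OR_F": (1.49, 0.37, False), "OR_M": (1.02, 0.14, False),
             "RR_F": (1.49, 0.37, False), "RR_M": (1.02, 0.14, False)},
    "ITP":  {"OR_F": (3.14, 0.73, True), "OR_M": (2.05, 0.42, True),
             "RR_F": (3.13, 0.73, True), "RR_M": (2.05, 0.42, True)},
    "IBD":  {"OR_F": (2.20, 0.54, True), "OR_M": (1.43, 0.23, True),
             "RR_F": (2.19, 0.54, True), "RR_M": (1.43, 0.23, True)},
    "LUP":  {"OR_F": (2.64, 1.24, True), "OR_M": (0.68, 0.16, False),
             "RR_F": (2.64, 1.24, True), "RR_M": (0.68, 0.16, False)},
    "PEMC": {"OR_F": (1.35, 0.39, False), "OR_M": (1.64, 0.56, False),
             "RR_F": (1.35, 0.39, False), "RR_M": (1.64, 0.56, False)},
    "PYO":  {"OR_F": (0.04, 0.01, True), "OR_M": None,
             "RR_F": (0.04, 0.01, True), "RR_M": None},
}

#: Published "percent in study population" column (pyometra over females only).
PUBLISHED_PERCENT = {
    "ATOP": 1.82, "AIHA": 0.56, "CMG": 0.12, "COL": 0.77, "ADD": 0.34,
    "HYPO": 1.89, "IMPA": 0.43, "ITP": 0.51, "IBD": 0.47, "LUP": 0.17,
    "PEMC": 0.17, "PYO": 0.44,
}

#: Published cohort profile.
DENOMINATORS = {"F": 9_133, "NF": 36_574, "M": 12_555, "NM": 31_828}
POPULATION_TOTAL = 90_090
NEUTERED_SHARE_PERCENT = 75.93
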