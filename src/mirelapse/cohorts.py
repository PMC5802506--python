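"""Published patient-characteristics counts for two DLBCL cohorts.

These are the printed per-subtype category counts from the patient-
characteristics summaries of the CGCI (n = 92) and LLMPP (n = 233)
chemoimmunotherapy-treated DLBCL cohorts: molecular subtype (GCB vs
non-GCB), gender, age group, stage, IPI stratum, and dichotomized (low vs
high) expression of six survival-associated genes.  The per-patient tables
returned by :func:`cohort_table` are *reconstructed* from those marginal
counts — each characteristic column is filled independently within a
subtype, so cross-characteristic joint distributions are arbitrary, but
every characteristic x subtype margin reproduces the published counts
exactly, which is all :func:`mirelapse.survival.cohort_summary` consumes.

Known quirks of the printed source, kept as printed: the CGCI IMPA1 "High"
total is internally inconsistent with its subtype cells (the subtype cells,
which sum correctly to 92, are used here); LLMPP stage and IPI cells do not
sum to the cohort size (missing data) and the remainder is filled with NA.
"""

from __future__ import annotations

import pandas as pd

# characteristic -> category -> (GCB count, non-GCB count)
CGCI_COUNTS = {
    "gender": {"Female": (19, 12), "Male": (32, 29)},
    "age": {"<60": (20, 19), "60-65": (9, 6), ">65": (22, 16)},
    "stage": {"I-II": (28, 16), "III-IV": (23, 25)},
    "IPI": {"0-2": (35, 27), "3-5": (16, 14)},
    "IMPA1": {"Low": (42, 27), "High": (9, 14)},
    "MAPK1": {"Low": (12, 15), "High": (39, 26)},
    "PIP5K1A": {"Low": (46, 32), "High": (5, 9)},
    "CACNG3": {"Low": (46, 31), "High": (5, 10)},
    "RASGRP3": {"Low": (47, 35), "High": (4, 6)},
    "SYK": {"Low": (44, 37), "High": (7, 4)},
}
CGCI_SUBTYPE_N = {"GCB": 51, "non-GCB": 41}

LLMPP_COUNTS = {
    "gender": {"Female": (49, 50), "Male": (58, 76)},
    "age": {"<60": (56, 53), "60-65": (13, 16), ">65": (38, 57)},
    "stage": {"I-II": (54, 51), "III-IV": (49, 72)},
    "IPI": {"0-2": (56, 56), "3-5": (18, 34)},
    "IMPA1": {"Low": (104, 114), "High": (3, 12)},
    "MAPK1": {"Low": (27, 23), "High": (80, 103)},
    "PIP5K1A": {"Low": (104, 119), "High": (3, 7)},
    "CACNG3": {"Low": (63, 68), "High": (44, 58)},
    "RASGRP3": {"Low": (77, 106), "High": (30, 20)},
    "SYK": {"Low": (98, 121), "High": (9, 5)},
}
LLMPP_SUBTYPE_N = {"GCB": 107, "non-GCB": 126}


def _expand(counts: dict, subtype_n: dict[str, int], cohort: str) -> pd.DataFrame:
    subtypes = []
    for subtype, n in subtype_n.items():
        subtypes.extend([subtype] * n)
    table = pd.DataFrame(
        {
            "patient": [f"{cohort}_{i + 1:04d}" for i in range(len(subtypes))],
            "subtype": subtypes,
        }
    )
    for char, cats in counts.items():
        col = []
        for si, (subtype, n) in enumerate(subtype_n.items()):
            filled = []
            for cat, cells in cats.items():
                filled.extend([cat] * cells[si])
            if len(filled) > n:
                raise ValueError(f"{cohort}/{char}: counts exceed subtype size")
            filled.extend([pd.NA] * (n - len(filled)))  # missing data in source
            col.extend(filled)
        table[char] = col
    return table


def cohort_table(name: str) -> pd.DataFrame:
    """Reconstructed per-patient characteristics table ("CGCI" or "LLMPP")."""
    if name == "CGCI":
        return _expand(CGCI_COUNTS, CGCI_SUBTYPE_N, "CGCI")
    if name == "LLMPP":
        return _expand(LLMPP_COUNTS, LLMPP_SUBTYPE_N, "LLMPP")
    raise ValueError(f"unknown cohort {name!r}")
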