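"""Published reference values from the NCI-60 withanolide screen.

The original screening and microarray data live in the NCI DTP database
and were never deposited alongside the study this package re-implements,
so they cannot be recomputed from raw data here.  What *was* printed —
the 40 COMPARE coefficients for genes whose expression correlated with
withaferin A diacetate potency (|r| > 0.6), and the 4 x 2
cluster-versus-sensitivity contingency table at the median cut-off
log10 IC50 = -6.5 — is carried verbatim as input for reproduction
checks and worked examples.  Gene-function annotation is deliberately
omitted (pass-through metadata only elsewhere in the package).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "withaferin_a_diacetate_compare_table",
    "cluster_sensitivity_counts",
    "SENSITIVITY_CUTOFF",
]

#: median log10 molar IC50 used to split sensitive from resistant lines
SENSITIVITY_CUTOFF = -6.5

# (probe id, gene symbol, GenBank accession, COMPARE coefficient r)
_COMPARE_ROWS = [
    ("GC9728", "CORO1A", "AA047478", 0.65),
    ("GC31813", "LSM2", "AJ245416", 0.646),
    ("GC34797", "HCLS1", "X16663", 0.676),
    ("GC34785", "unknown", "X79234", 0.643),
    ("GC37799", "PLS3", "M22299", -0.606),
    ("GC32858", "RAD54L", "X97795", 0.654),
    ("GC36655", "RPL5", "U14966", 0.648),
    ("GC61547", "IKZF1", "AI247840", 0.648),
    ("GC10718", "DLG2", "R41930", -0.612),
    ("GC37806", "RPS23", "D14530", 0.669),
    ("GC33814", "unknown", "D11327", 0.674),
    ("GC67595", "RNF138", "AI608790", 0.688),
    ("GC31615", "unknown", "X79234", 0.663),
    ("GC27422", "LCP1", "J02923", 0.649),
    ("GC18026", "LAMB1", "AA004918", -0.610),
    ("GC16071", "SH3BP4", "W72796", -0.608),
    ("GC14684", "UACA", "N66980", -0.624),
    ("GC14433", "BCAR3", "N48319", -0.636),
    ("GC15668", "ZNF112", "W15410", -0.640),
    ("GC36107", "LOC440055", "AA977163", 0.721),
    ("GC14769", "unknown", "N92652", -0.601),
    ("GC16889", "ALDH7A1", "AA024918", -0.642),
    ("GC15762", "ADAM9", "W47533", -0.611),
    ("GC14991", "TRIM3", "N71362", -0.616),
    ("GC19072", "ITGB1", "AA044261", -0.638),
    ("GC15931", "RGS12", "W67134", -0.639),
    ("GC12455", "TJP1", "R79560", -0.612),
    ("GC15131", "ASAP2", "N70773", -0.638),
    ("GC11515", "STMN4", "H29581", -0.650),
    ("GC69113", "WAS", "AI655719", 0.654),
    ("GC30164", "NACA", "AF054187", 0.652),
    ("GC83792", "NASP", "AW003362", 0.657),
    ("GC31589", "LOC729362", "T89651", 0.679),
    ("GC31915", "GNA11", "N36926", -0.639),
    ("GC32458", "unknown", "M69013", -0.658),
    ("GC89937", "CD53", "M37033", 0.666),
    ("GC28763", "PPIH", "AF016371", 0.662),
    ("GC90165", "PTPN7", "M64322", 0.707),
    ("GC90123", "ANXA2P3", "M62895", -0.652),
    ("GC85483", "ANXA2", "D00017", -0.659),
]


def withaferin_a_diacetate_compare_table() -> pd.DataFrame:
    """The 40 published COMPARE coefficients for withaferin A diacetate.

    Indexed by probe id with columns ``symbol``, ``genebank`` and ``r``
    (positive r = resistance-associated, negative = sensitivity-
    associated).  Every printed magnitude exceeds 0.6 — the study's own
    candidate cut-off.
    """
    table = pd.DataFrame(
        _COMPARE_ROWS, columns=["probe_id", "symbol", "genebank", "r"]
    ).set_index("probe_id")
    return table


def cluster_sensitivity_counts() -> pd.DataFrame:
    """The published 4 x 2 cluster-by-sensitivity contingency table.

    59 of the 60 lines are classified (one lacks a value), split at the
    median log10 IC50 of -6.5 for withaferin A diacetate.
    """
    counts = pd.DataFrame(
        {"sensitive": [3, 9, 4, 6], "resistant": [2, 17, 18, 0]},
        index=pd.Index([1, 2, 3, 4], name="cluster"),
    )
    counts.columns.name = "response"
    return counts
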