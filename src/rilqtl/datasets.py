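"""Bundled reference QTL catalog.

Interaction-scan results for the 14 QTLs detected across two biparental
Drosophila melanogaster RIL panels (an Ethiopia-derived and a
France-derived cross against a Zambian ancestral population) — the panels
whose statistical structure the synthetic generator emulates. Each row
carries the QTL's additive LOD score and its genome-wide interaction-scan
P-value (10,000 focal-fixed permutations). The two stripe-ratio QTLs
overlap and form one correlated group, of which only the higher-LOD
member enters the meta-analysis, leaving 13 independent P-values.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # (qtl_id, panel, trait, lod, interaction_p, overlap_group)
    ("Q1", "EF", "A4Back 25C", 3.274, 0.736, None),
    ("Q2", "EF", "Mesopl 15C", 5.819, 0.699, None),
    ("Q3", "EF", "Mesopl 25C", 5.890, 0.714, None),
    ("Q4", "EF", "Stripe 25C", 6.335, 0.643, "stripe"),
    ("Q5", "EF", "Stripe 15C", 9.924, 0.244, "stripe"),
    ("Q6", "EF", "Wing", 9.581, 0.322, None),
    ("Q7", "EF", "Wing", 8.628, 0.672, None),
    ("Q8", "EF", "Wing", 3.867, 0.444, None),
    ("Q9", "EF", "Wing", 3.526, 0.941, None),
    ("Q10", "EF", "Wing", 4.286, 0.183, None),
    ("Q11", "FR", "EtOH", 3.565, 0.208, None),
    ("Q12", "FR", "EtOH", 3.253, 0.853, None),
    ("Q13", "FR", "EtOH", 3.740, 0.476, None),
    ("Q14", "FR", "Song", 9.111, 0.273, None),
]


def qtl_catalog() -> pd.DataFrame:
    """The 14-QTL catalog as a DataFrame.

    Columns: qtl_id, panel, trait, lod, interaction_p, group (overlap
    group label or NaN for independent QTLs).
    """
    return pd.DataFrame(
        _ROWS, columns=["qtl_id", "panel", "trait", "lod", "interaction_p", "group"]
    )


def nonoverlapping_interaction_pvalues() -> list:
    """Interaction P-values of the 13 nonoverlapping QTLs.

    Within the overlapping stripe-ratio pair only the higher-LOD QTL is
    retained.
    """
    from .meta import select_nonoverlapping

    df = qtl_catalog().rename(columns={"interaction_p": "p"})
    return select_nonoverlapping(df)["p"].tolist()
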