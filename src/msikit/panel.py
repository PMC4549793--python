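"""Benchmark panel of hypermutated and discordantly classified tumors.

A small reference panel of 11 TCGA colorectal/endometrial tumor exomes
with published S.ind values (somatic microindels in simple repeats per Mb)
spanning the interesting corners of the classification space: eight
hypermutated cases (substitution burden above 60/Mb) — six with a
POLE-associated mutation signature and few repeat indels, two without —
and three further cases where repeat-indel-based calling disagrees with
the laboratory MSI assay.

Because only the hypermutation *condition* (T.sns > 60/Mb) is recorded for
these samples, not the exact substitution burdens, the panel carries it as
a boolean; the POLE flag on the panel combines that boolean with the S.ind
value.
"""

from __future__ import annotations

import pandas as pd

from .classifier import ClassifierBundle, PoleFlagRule
from .mutations import MSI_HIGH, NON_MSI_HIGH

# sample_id, S.ind (/Mb), hypermutated (T.sns > 60/Mb), laboratory MSI-H
_PANEL = [
    ("TCGA-F5-6814", 0.045, True, False),
    ("TCGA-CA-6717", 0.11, True, False),
    ("TCGA-AZ-4315", 0.045, True, False),
    ("TCGA-EI-6917", 0.091, True, False),
    ("TCGA-AA-3510", 0.023, True, False),
    ("TCGA-CA-6718", 0.023, True, False),
    ("TCGA-AM-5821", 0.25, True, True),
    ("TCGA-AM-5820", 2.61, True, False),
    ("TCGA-A5-A0GD", 0.00, False, True),
    ("TCGA-DC-6154", 0.045, False, True),
    ("TCGA-G4-6304", 0.27, False, True),
]


def hypermutated_panel() -> pd.DataFrame:
    """The panel as a DataFrame indexed by sample_id.

    Columns: ``S.ind``, ``hypermutated`` (bool), ``lab_msi_h`` (bool).
    """
    df = pd.DataFrame(
        _PANEL, columns=["sample_id", "S.ind", "hypermutated", "lab_msi_h"]
    )
    return df.set_index("sample_id")


def evaluate_panel(
    bundle: ClassifierBundle, pole_rule: PoleFlagRule | None = None
) -> pd.DataFrame:
    """Classify the panel and apply the POLE flag rule.

    Returns the panel with ``predicted_status`` (from the bundle's tree
    over S.ind) and ``pole_flag`` (hypermutated and S.ind below the rule's
    cutoff) columns added.
    """
    if pole_rule is None:
        pole_rule = PoleFlagRule()
    df = hypermutated_panel()
    df["predicted_status"] = [
        bundle.tree.predict(row, sample_id=str(sid))
        for sid, row in df.iterrows()
    ]
    df["pole_flag"] = df["hypermutated"] & (df["S.ind"] < pole_rule.s_ind_cutoff)
    return df
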