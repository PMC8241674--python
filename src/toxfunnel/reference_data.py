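"""Bundled reference datasets from the artemisinin cardiotoxicity screen.

Three small published result tables ship with the package so the
downstream analyses can be exercised and cross-checked without external
downloads:

* hERG docking results (mean +/- SD lowest binding energy and predicted
  inhibition constant) for seven artemisinin derivatives plus the
  cardiotoxic control doxorubicin and the cardioprotective control
  dexrazoxane;
* the 39-compound known-cardiotoxin reference list with per-compound
  model verdicts and auxiliary-toxicity star annotations;
* the nine reversely deregulated cardiotoxicity marker genes with their
  fold changes under artemisinin B, dexrazoxane and doxorubicin in AC16
  cardiomyocytes.
"""

from __future__ import annotations

import csv
from importlib.resources import files

from .cascade import CompoundVerdict
from .docking_post import AffinityEstimate
from .validation_analysis import FoldChangeTable

__all__ = [
    "herg_docking_table",
    "reference_cardiotoxin_verdicts",
    "reversal_fold_change_tables",
    "POSITIVE_CONTROL",
    "NEGATIVE_CONTROL",
]

POSITIVE_CONTROL = "doxorubicin"     # known cardiotoxic anchor
NEGATIVE_CONTROL = "dexrazoxane"     # cardioprotective anchor


def _read(name: str) -> list[dict]:
    text = files("toxfunnel.data").joinpath(name).read_text()
    return list(csv.DictReader(text.splitlines()))


def herg_docking_table() -> list[AffinityEstimate]:
    """Published per-compound hERG docking aggregates (3 runs each)."""
    return [
        AffinityEstimate(
            compound_id=row["compound"],
            lbe_mean=float(row["lbe_mean_kcal"]),
            lbe_sd=float(row["lbe_sd_kcal"]),
            ki_mean_uM=float(row["ki_mean_uM"]),
            ki_sd_uM=float(row["ki_sd_uM"]),
            n_runs=3,
        )
        for row in _read("herg_docking_table.csv")
    ]


def reference_cardiotoxin_verdicts() -> list[CompoundVerdict]:
    """The 39 known-cardiotoxic compounds with their published verdicts.

    ``endpoint_labels`` holds a single combined cardiotoxicity call (the
    published tables report one yes/no per compound); compounds detected
    only by an auxiliary category carry ``aux_flagged``.
    """
    verdicts = []
    for row in _read("reference_cardiotoxins.csv"):
        positive = row["predicted_cardiotoxicity"].strip().lower() == "yes"
        verdicts.append(
            CompoundVerdict(
                compound_id=row["name"],
                endpoint_labels={"cardiotoxicity": int(positive)},
                aux_flagged=bool(int(row["aux_flagged"])),
            )
        )
    return verdicts


def reversal_fold_change_tables() -> tuple[FoldChangeTable, FoldChangeTable, FoldChangeTable]:
    """Fold-change tables (artemisinin B, dexrazoxane, doxorubicin)."""
    rows = _read("reversal_fold_changes.csv")
    cols = ("artemisinin_b", "dexrazoxane", "doxorubicin")
    return tuple(
        FoldChangeTable(c, {r["gene"]: float(r[c]) for r in rows}) for c in cols
    )
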