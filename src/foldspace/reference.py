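"""Packaged reference table of the folds covered by capsid structural relatives.

The table lists the 21 SCOP folds covered by non-capsid domains lying
within structural distance 0.5 of the representative viral capsid set,
with fold descriptions, capsid-membership flags and one example relative
per fold.  It serves as a fixture for fold accounting: how many of the
shared folds themselves contain capsid proteins, and how many are
greek-key or jelly-roll topologies (the jelly-roll being a variation of
the greek-key).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_TABLE_RESOURCE = "capsid_relative_folds.tsv"


def load_capsid_fold_table() -> pd.DataFrame:
    """The packaged fold table as a DataFrame (one row per fold)."""
    ref = resources.files("foldspace.data").joinpath(_TABLE_RESOURCE)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def capsid_fold_summary(table: pd.DataFrame | None = None) -> dict[str, int]:
    """Fold accounting computed from the table.

    Returns total fold count, the number of folds that themselves contain
    capsid proteins, the number specific to non-capsid proteins, and the
    number whose topology is greek-key or jelly-roll (matched in the fold
    description).
    """
    if table is None:
        table = load_capsid_fold_table()
    desc = table["description"].str.lower()
    greek_or_jelly = (desc.str.contains("greek-key") | desc.str.contains("jelly-roll")).sum()
    contains = (table["contains_capsid"] == "Yes").sum()
    return {
        "total_folds": int(len(table)),
        "capsid_containing_folds": int(contains),
        "non_capsid_specific_folds": int(len(table) - contains),
        "greek_key_or_jelly_roll_folds": int(greek_or_jelly),
    }
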