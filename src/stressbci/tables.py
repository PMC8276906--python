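"""Loaders for the published result tables, shipped as CSV package data.

* table1 — per-participant FBCSP-SVM accuracies for the four condition
  pairs (11 participants after rejection).
* table2 — class-wise accuracies of the three CNN classifiers.
* table3 — class-wise accuracies of the three LSTM stacks and the LSTM-FCN.
* table4 — per-participant two-layer-LSTM accuracy, group and STAI-C
  trait-anxiety score.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

TABLE_NAMES = ("table1", "table2", "table3", "table4")


def load_table(name: str) -> pd.DataFrame:
    if name not in TABLE_NAMES:
        raise FileNotFoundError(f"unknown table fixture {name!r}")
    ref = resources.files("stressbci") / "data" / "tables" / f"{name}.csv"
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def load_all() -> dict[str, pd.DataFrame]:
    return {name: load_table(name) for name in TABLE_NAMES}
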