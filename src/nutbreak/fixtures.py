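"""Shipped report-table fixtures and the printed values they must reproduce.

Three small CSVs travel with the package: the BP versus GA-ANN score
comparison (``table4``), the 30-member published Pareto optimal set
(``table5``) and the prediction/validation pair at the selected optimum
(``table6``).  The printed derived percentages (RMSE reductions, relative
validation errors, and the percent-change comparisons between Pareto
groups) are frozen here so that the report arithmetic can be re-derived
from the raw fixture numbers and checked against what was printed.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .dataset import FactorialDataset, ProcessCondition, ResponseVector, RESPONSE_COLUMNS
from .moo import ParetoSet, ParetoSolution


def _fixture_path(name: str) -> Path:
    return Path(resources.files("nutbreak") / "data" / name)


def load_table4() -> pd.DataFrame:
    """BP and GA-ANN rows of per-response R² and RMSE, indexed by algorithm."""
    return pd.read_csv(_fixture_path("table4.csv"), index_col="algorithm")


def load_table5_dataset() -> FactorialDataset:
    """The published 30-member Pareto set as a dataset (fixture provenance)."""
    frame = pd.read_csv(_fixture_path("table5.csv")).drop(columns=["group"])
    return FactorialDataset(frame, provenance="fixture")


def load_table5_pareto() -> ParetoSet:
    """The published Pareto set as ParetoSolution records.

    Nondomination is not enforced: the printed precision introduces exact
    ties that make a few rows formally dominated.
    """
    return ParetoSet.from_dataset(load_table5_dataset())


def load_table6() -> tuple[ProcessCondition, ResponseVector, ResponseVector]:
    """Optimal condition with its predicted and experimentally validated
    responses."""
    frame = pd.read_csv(_fixture_path("table6.csv"), index_col="result")
    pred_row = frame.loc["prediction"]
    val_row = frame.loc["validation"]
    cond = ProcessCondition(
        float(pred_row["T"]), float(pred_row["V"]),
        float(pred_row["MC"]), int(pred_row["D"]),
    )
    pred = ResponseVector(*[float(pred_row[c]) for c in RESPONSE_COLUMNS])
    val = ResponseVector(*[float(val_row[c]) for c in RESPONSE_COLUMNS])
    return cond, pred, val


#: printed RMSE-reduction row of the BP vs GA-ANN comparison,
#: as (value, decimals printed)
PRINTED_RMSE_REDUCTION = {
    "DT": (32.8, 1),
    "SEC": (23.14, 2),
    "HR": (10.96, 2),
    "WR": (21.99, 2),
    "SR": (50.5, 1),
}

#: printed relative validation errors (%) at the selected optimum
PRINTED_VALIDATION_ERROR = {
    "DT": 3.56,
    "SEC": 3.88,
    "HR": 2.51,
    "WR": 3.32,
    "SR": 3.96,
}

#: printed percent-change comparisons between Pareto groups,
#: as (candidate, reference) -> {response: printed %}
PRINTED_PARETO_CHANGES = {
    (7, 1): {"DT": -39.0, "SEC": -23.3, "HR": -8.2, "WR": -14.1, "SR": 7.5},
    (30, 1): {"DT": -90.9, "SEC": -95.2, "HR": -48.2, "WR": -56.0, "SR": -33.4},
    (3, 1): {"DT": 12.9, "HR": -0.2, "WR": 0.6, "SR": -3.6},
}
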