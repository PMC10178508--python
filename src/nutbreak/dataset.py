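"""Tabular data model for the factorial drying/breaking experiment.

A run of the process is described by four input variables — infrared
temperature ``T`` (°C), air velocity ``V`` (m/s), target moisture content
``MC`` (% dry basis) and loading direction ``D`` (1 = sutural,
2 = longitudinal, 3 = vertical) — and five responses: drying time ``DT``
(min), specific energy consumption ``SEC`` (MJ/kg), high kernel rate ``HR``
(%), whole kernel rate ``WR`` (%) and shell-breaking rate ``SR`` (%).

Datasets are plain CSV with a one-line header and the fixed column order
``T,V,MC,D,DT,SEC,HR,WR,SR``.  The full factorial design spans
4 temperatures x 4 velocities x 4 moisture levels x 3 directions = 192 runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

INPUT_COLUMNS = ["T", "V", "MC", "D"]
RESPONSE_COLUMNS = ["DT", "SEC", "HR", "WR", "SR"]
COLUMNS = INPUT_COLUMNS + RESPONSE_COLUMNS

#: design-space box (the experimental operating window)
CONDITION_BOUNDS = {"T": (40.0, 55.0), "V": (1.0, 4.0), "MC": (10.0, 25.0)}
DIRECTION_CODES = {"sutural": 1, "longitudinal": 2, "vertical": 3}
DIRECTION_NAMES = {v: k for k, v in DIRECTION_CODES.items()}

#: factor levels of the full factorial design
FACTORIAL_LEVELS = {
    "T": (40.0, 45.0, 50.0, 55.0),
    "V": (1.0, 2.0, 3.0, 4.0),
    "MC": (10.0, 15.0, 20.0, 25.0),
    "D": (1, 2, 3),
}
N_FACTORIAL = 192  # 4 * 4 * 4 * 3


class SchemaError(ValueError):
    """Input file does not carry the expected columns."""


class ValidationError(ValueError):
    """A value violates a domain invariant; message names row and field."""


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass(frozen=True)
class ProcessCondition:
    """One point in the (T, V, MC, D) design space."""

    T: float
    V: float
    MC: float
    D: int

    def __post_init__(self) -> None:
        for name in ("T", "V", "MC"):
            lo, hi = CONDITION_BOUNDS[name]
            val = getattr(self, name)
            if not (lo <= val <= hi):
                raise ValidationError(
                    f"{name}={val} outside [{lo}, {hi}]"
                )
        if self.D not in (1, 2, 3):
            raise ValidationError(f"D={self.D} not in {{1, 2, 3}}")

    def as_array(self) -> np.ndarray:
        return np.array([self.T, self.V, self.MC, float(self.D)])


@dataclass(frozen=True)
class ResponseVector:
    """The five process responses at one condition."""

    DT: float
    SEC: float
    HR: float
    WR: float
    SR: float

    def __post_init__(self) -> None:
        if not self.DT > 0:
            raise ValidationError(f"DT={self.DT} must be > 0")
        if not self.SEC > 0:
            raise ValidationError(f"SEC={self.SEC} must be > 0")
        if not (0.0 <= self.WR <= self.HR <= 100.0):
            raise ValidationError(
                f"need 0 <= WR <= HR <= 100, got WR={self.WR}, HR={self.HR}"
            )
        if not (0.0 <= self.SR <= 100.0):
            raise ValidationError(f"SR={self.SR} outside [0, 100]")

    def as_array(self) -> np.ndarray:
        return np.array([self.DT, self.SEC, self.HR, self.WR, self.SR])


@dataclass
class FactorialDataset:
    """Ordered (condition, response) records backed by a DataFrame.

    ``provenance`` tags where the records came from: ``"synthetic"`` for
    generator output, ``"fixture"`` for shipped printed tables, ``"user"``
    otherwise.
    """

    frame: pd.DataFrame
    provenance: str = "user"

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        self.frame = self.frame[COLUMNS].reset_index(drop=True)
        dupes = self.frame.duplicated(subset=INPUT_COLUMNS)
        if dupes.any():
            rows = list(self.frame.index[dupes])
            raise ValidationError(f"duplicate conditions at rows {rows}")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[ProcessCondition, ResponseVector]],
        provenance: str = "user",
    ) -> "FactorialDataset":
        rows = [
            np.concatenate([c.as_array(), r.as_array()]) for c, r in records
        ]
        frame = pd.DataFrame(rows, columns=COLUMNS)
        frame["D"] = frame["D"].astype(int)
        return cls(frame, provenance=provenance)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[tuple[ProcessCondition, ResponseVector]]:
        out = []
        for row in self.frame.itertuples(index=False):
            cond = ProcessCondition(row.T, row.V, row.MC, int(row.D))
            resp = ResponseVector(row.DT, row.SEC, row.HR, row.WR, row.SR)
            out.append((cond, resp))
        return out

    def inputs(self) -> np.ndarray:
        """(n, 4) array of T, V, MC, D."""
        return self.frame[INPUT_COLUMNS].to_numpy(dtype=float)

    def responses(self) -> np.ndarray:
        """(n, 5) array of DT, SEC, HR, WR, SR."""
        return self.frame[RESPONSE_COLUMNS].to_numpy(dtype=float)

    def is_full_factorial(self) -> bool:
        """True iff each of the 192 design cells is present exactly once."""
        if len(self) != N_FACTORIAL:
            return False
        seen = {
            (row.T, row.V, row.MC, int(row.D))
            for row in self.frame.itertuples(index=False)
        }
        expected = {
            (t, v, mc, d)
            for t in FACTORIAL_LEVELS["T"]
            for v in FACTORIAL_LEVELS["V"]
            for mc in FACTORIAL_LEVELS["MC"]
            for d in FACTORIAL_LEVELS["D"]
        }
        return seen == expected


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split: a fraction of 0.8 over 192 runs gives the
    154/38 training/test partition."""

    fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction < 1.0):
            raise ConfigError(
                f"split fraction must lie in (0, 1), got {self.fraction}"
            )


def _validate_frame(frame: pd.DataFrame) -> None:
    """Row-by-row invariant checks; errors name the row and field."""
    problems: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        for name in ("T", "V", "MC"):
            lo, hi = CONDITION_BOUNDS[name]
            val = getattr(row, name)
            if not (lo <= val <= hi):
                problems.append(f"row {i}: {name}={val} outside [{lo}, {hi}]")
        if int(row.D) not in (1, 2, 3):
            problems.append(f"row {i}: D={row.D} not in {{1, 2, 3}}")
        if not row.DT > 0:
            problems.append(f"row {i}: DT={row.DT} must be > 0")
        if not row.SEC > 0:
            problems.append(f"row {i}: SEC={row.SEC} must be > 0")
        if not (0.0 <= row.WR <= row.HR <= 100.0):
            problems.append(
                f"row {i}: need 0 <= WR <= HR <= 100, got WR={row.WR}, HR={row.HR}"
            )
        if not (0.0 <= row.SR <= 100.0):
            problems.append(f"row {i}: SR={row.SR} outside [0, 100]")
    if problems:
        raise ValidationError("; ".join(problems))


def read_dataset(
    path: str | Path,
    schema: Sequence[str] = tuple(COLUMNS),
    provenance: str = "user",
) -> FactorialDataset:
    """Read a dataset CSV.

    The loading-direction column accepts either the integer codes 1/2/3 or
    the names sutural/longitudinal/vertical, which are normalized on read.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if frame["D"].dtype == object:
        frame["D"] = (
            frame["D"].astype(str).str.strip().str.lower().map(
                lambda s: DIRECTION_CODES.get(s, s)
            )
        )
    frame["D"] = pd.to_numeric(frame["D"], errors="raise")
    for col in COLUMNS:
        if col != "D":
            frame[col] = frame[col].astype(float)
    _validate_frame(frame)
    frame["D"] = frame["D"].astype(int)
    return FactorialDataset(frame, provenance=provenance)


def write_dataset(dataset: FactorialDataset, path: str | Path) -> Path:
    """Write the dataset CSV; numeric fields round-trip at full precision."""
    if len(dataset) == 0:
        raise ValidationError("refusing to write an empty dataset")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = dataset.frame.copy()
    # repr-precision floats so read(write(d)) == d exactly
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def split_dataset(
    dataset: FactorialDataset, spec: SplitSpec = SplitSpec()
) -> tuple[FactorialDataset, FactorialDataset]:
    """Uniform random disjoint partition into training and test sets.

    Sizes are round(fraction * n) and the remainder; identical seeds give
    identical membership.
    """
    n = len(dataset)
    if n < 5:
        raise ValidationError(f"need at least 5 records to split, got {n}")
    n_train = int(np.floor(spec.fraction * n + 0.5))
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    train = FactorialDataset(
        dataset.frame.iloc[train_idx].reset_index(drop=True),
        provenance=dataset.provenance,
    )
    test = FactorialDataset(
        dataset.frame.iloc[test_idx].reset_index(drop=True),
        provenance=dataset.provenance,
    )
    return train, test
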