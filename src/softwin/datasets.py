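"""In-memory container for long-format phenotyping cohorts.

One row per animal measurement: continuous time (days since the earliest
observation), a continuous response, a group label (``control`` or
``mutant``), sex, optional body weight and a batch identifier (all
measurements collected on the same day share a batch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingGroupError, SchemaError

REQUIRED_COLUMNS = ("time", "response", "group", "sex", "batch")
GROUP_LEVELS = ("control", "mutant")


@dataclass
class PhenotypeDataset:
    """Wrapper around a tidy DataFrame with validated phenotyping columns.

    Columns: ``time`` (float days), ``response`` (float), ``group``
    (control/mutant), ``sex`` (F/M), ``batch`` (categorical, constant within
    a day) and optionally ``body_weight``.
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(missing)
        bad = set(self.data["group"].unique()) - set(GROUP_LEVELS)
        if bad:
            raise SchemaError(
                [], message=f"group column contains unknown levels {sorted(bad)}"
            )
        if not (self.data["group"] == "control").any():
            raise MissingGroupError("dataset contains no control observations")
        self.data = self.data.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def response(self) -> np.ndarray:
        return self.data["response"].to_numpy(dtype=float)

    @property
    def is_mutant(self) -> np.ndarray:
        return (self.data["group"] == "mutant").to_numpy()

    @property
    def is_control(self) -> np.ndarray:
        return ~self.is_mutant

    @property
    def batch(self) -> np.ndarray:
        return self.data["batch"].to_numpy()

    @property
    def n_batches(self) -> int:
        return self.data["batch"].nunique()

    @property
    def body_weight(self) -> np.ndarray | None:
        """Body-weight column, or None when absent or entirely missing."""
        if "body_weight" not in self.data.columns:
            return None
        bw = self.data["body_weight"].to_numpy(dtype=float)
        if np.all(np.isnan(bw)):
            return None
        return bw

    @property
    def mutant_times(self) -> np.ndarray:
        return self.times[self.is_mutant]

    @property
    def time_span(self) -> float:
        t = self.times
        return float(t.max() - t.min()) if t.size else 0.0

    # -- helpers ---------------------------------------------------------
    def require_mutants(self) -> None:
        if not self.is_mutant.any():
            raise MissingGroupError("dataset contains no mutant observations")

    def controls_only(self) -> "PhenotypeDataset":
        """The control subset (drops all mutant rows)."""
        return PhenotypeDataset(self.data[self.is_control].reset_index(drop=True))

    def copy(self) -> "PhenotypeDataset":
        return PhenotypeDataset(self.data.copy())

    def __len__(self) -> int:
        return self.n
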