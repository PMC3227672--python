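"""Relative quantification of qPCR Ct values.

Implements the comparative-Ct method with amplification efficiency fixed
at 2 (one doubling per cycle):

    dCt(s)  = Ct(s, target) - Ct(s, housekeeping)
    ddCt    = dCt(sample) - dCt(calibrator)
    fold    = 2 ** (-ddCt)

``endogenous_level`` stops at the first normalisation (2^-dCt), expressing
a target's abundance relative to the housekeeping RNA within one sample.
Technical replicates are averaged on the Ct scale before any delta is
taken.  Undetermined Ct values (no amplification) are encoded as absent
records, never as a sentinel cycle number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QpcrTable",
    "relative_expression",
    "endogenous_level",
    "format_fold",
]

REQUIRED_COLUMNS = ["sample_id", "target_id", "replicate", "ct"]


@dataclass
class QpcrTable:
    """Ct records keyed by (sample, target, replicate), with a designated
    housekeeping target and calibrator sample."""

    data: pd.DataFrame
    housekeeping: str
    calibrator: str

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table lacks columns {missing}")
        if not np.isfinite(self.data["ct"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite Ct values; encode undetermined wells as absent")
        samples = set(self.data["sample_id"])
        hk = self.data[self.data["target_id"] == self.housekeeping]
        lacking = samples - set(hk["sample_id"])
        if lacking:
            raise ValueError(
                f"samples missing housekeeping ({self.housekeeping!r}) Ct: {sorted(lacking)}"
            )
        if self.calibrator not in samples:
            raise ValueError(f"calibrator sample {self.calibrator!r} not in table")

    def mean_ct(self, sample: str, target: str) -> float:
        """Arithmetic mean Ct over technical replicates."""
        sel = self.data[
            (self.data["sample_id"] == sample) & (self.data["target_id"] == target)
        ]
        if sel.empty:
            raise KeyError(f"no Ct for (sample={sample!r}, target={target!r})")
        return float(sel["ct"].mean())

    def delta_ct(self, sample: str, target: str) -> float:
        return self.mean_ct(sample, target) - self.mean_ct(sample, self.housekeeping)

    @classmethod
    def from_csv(
        cls, path: str | Path, housekeeping: str, calibrator: str
    ) -> "QpcrTable":
        df = pd.read_csv(path, dtype={"sample_id": str, "target_id": str})
        return cls(data=df, housekeeping=housekeeping, calibrator=calibrator)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, lineterminator="\n")


def relative_expression(table: QpcrTable, target: str, sample: str) -> float:
    """Fold change of ``target`` in ``sample`` versus the calibrator sample,
    2^-ddCt."""
    ddct = table.delta_ct(sample, target) - table.delta_ct(table.calibrator, target)
    return float(2.0 ** (-ddct))


def endogenous_level(table: QpcrTable, target: str, sample: str) -> float:
    """Expression of ``target`` relative to the housekeeping RNA within one
    sample, 2^-dCt."""
    return float(2.0 ** (-table.delta_ct(sample, target)))


def format_fold(fold: float, cap: float = 1000.0) -> str:
    """Render a fold change for a results table: values above ``cap``
    (strictly) print as e.g. '> 1,000', everything else to 3 significant
    digits with thousands separators."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    if fold > cap:
        return f"> {cap:,.0f}"
    rounded = float(f"{fold:.3g}")
    return f"{rounded:,g}"
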