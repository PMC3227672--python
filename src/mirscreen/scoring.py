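"""Hit scoring for the pooled invasion screen.

Per construct, the screen yields a read count in the control fraction and
one in the invasive fraction.  Counts are expressed as *scaled reads* R —
each fraction normalised so that the library-wide mean of R is exactly 1,
which makes R directly interpretable as "fold of average abundance".
Enrichment is the ratio E = R_invasive / R_control, and the hit score is
their product

    S = E x R_invasive,        hit  <=>  S > threshold (default 1)

so a construct must be both enriched by selection *and* well represented
in the invasive fraction to score.  The mean-1 scale makes the threshold
self-calibrating: an unenriched construct of average abundance sits at
S ~ 1.  A small pseudocount keeps E finite for dropout constructs.

Note the score has no null-calibration: without genuine selection
pressure (when most constructs neither enrich nor deplete) about half the
library exceeds S = 1.  It separates hits only when selection depletes
the background, as two rounds of invasion do.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .deconvolution import ReadCountTable
from .simulate import ScreenTruth

__all__ = [
    "HitTable",
    "RecoveryReport",
    "scale_counts",
    "compute_enrichment",
    "score_hits",
    "score_counts",
    "evaluate_recovery",
]

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_THRESHOLD = 1.0


def _as_series(x, name: str) -> pd.Series:
    if isinstance(x, pd.Series):
        return x.astype(float)
    return pd.Series(dict(x), dtype=float)


def scale_counts(
    raw: Mapping[str, int] | pd.Series, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.Series:
    """Scale raw counts so the library-wide mean is exactly 1:
    R_c = N * (x_c + pseudocount) / sum_j (x_j + pseudocount)."""
    x = _as_series(raw, "raw")
    if len(x) == 0:
        raise ValueError("no constructs to scale")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if (x < 0).any():
        raise ValueError("negative counts")
    shifted = x + pseudocount
    total = float(shifted.sum())
    if total == 0:
        raise ValueError(
            "all counts are zero and pseudocount is 0: scale undefined "
            "(use a positive pseudocount)"
        )
    return len(x) * shifted / total


def compute_enrichment(r_invasive: pd.Series, r_control: pd.Series) -> pd.Series:
    """E_c = R_invasive,c / R_control,c."""
    r_invasive = _as_series(r_invasive, "r_invasive")
    r_control = _as_series(r_control, "r_control")
    if set(r_invasive.index) != set(r_control.index):
        raise ValueError("construct sets differ between fractions")
    r_control = r_control.reindex(r_invasive.index)
    if (r_control <= 0).any():
        bad = r_control.index[r_control <= 0][:5].tolist()
        raise ValueError(
            f"control scaled reads are zero for {bad}; use a positive pseudocount"
        )
    return r_invasive / r_control


@dataclass
class HitTable:
    """Per-construct R, E, S = E x R_invasive and hit flags, sorted by S
    descending (ties broken by construct_id)."""

    table: pd.DataFrame  # columns R_control, R_invasive, E, S, is_hit
    threshold: float
    pseudocount: float | None = None

    @property
    def hit_ids(self) -> list[str]:
        return self.table.index[self.table["is_hit"]].tolist()

    @property
    def n_called(self) -> int:
        return int(self.table["is_hit"].sum())

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.reset_index()
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(
        cls, path: str | Path, threshold: float = DEFAULT_THRESHOLD
    ) -> "HitTable":
        df = pd.read_csv(path, sep="\t", dtype={"construct_id": str}).set_index(
            "construct_id"
        )
        return cls(table=df, threshold=threshold)


def score_hits(
    enrichment: pd.Series,
    r_invasive: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
    r_control: pd.Series | None = None,
    exponents: tuple[float, float] = (1.0, 1.0),
) -> HitTable:
    """Combine enrichment and invasive abundance into the hit score
    S = E^a x R^b (a = b = 1 by default) and call hits at S > threshold."""
    enrichment = _as_series(enrichment, "E")
    r_invasive = _as_series(r_invasive, "R_invasive")
    if set(enrichment.index) != set(r_invasive.index):
        raise ValueError("construct sets differ between E and R_invasive")
    r_invasive = r_invasive.reindex(enrichment.index)
    a, b = exponents
    s = enrichment**a * r_invasive**b
    df = pd.DataFrame(
        {
            "R_invasive": r_invasive,
            "E": enrichment,
            "S": s,
            "is_hit": s > threshold,
        }
    )
    if r_control is not None:
        df.insert(0, "R_control", _as_series(r_control, "R_control").reindex(df.index))
    df.index.name = "construct_id"
    df = df.sort_values(["S", "construct_id"], ascending=[False, True], kind="mergesort")
    return HitTable(table=df, threshold=threshold)


def score_counts(
    counts: ReadCountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    threshold: float = DEFAULT_THRESHOLD,
    exponents: tuple[float, float] = (1.0, 1.0),
) -> HitTable:
    """Full scoring of a count table: scale both fractions, form E, score."""
    r_ctrl = scale_counts(counts.fraction_counts("control"), pseudocount)
    r_inv = scale_counts(counts.fraction_counts("invasive"), pseudocount)
    e = compute_enrichment(r_inv, r_ctrl)
    hits = score_hits(e, r_inv, threshold=threshold, r_control=r_ctrl,
                      exponents=exponents)
    hits.pseudocount = pseudocount
    return hits


@dataclass
class RecoveryReport:
    """Hit recovery against simulation ground truth."""

    recall: float | None
    precision: float | None
    n_called: int
    n_true: int
    recall_undefined: bool = False
    precision_undefined: bool = False


def evaluate_recovery(hits: HitTable, truth: ScreenTruth) -> RecoveryReport:
    """Recall and precision of the called hit set against ground truth.

    With zero true hits, recall is undefined (flagged), not 0; likewise
    precision with an empty call set.
    """
    missing = set(hits.table.index) - set(truth.is_hit)
    if missing:
        raise ValueError(f"truth does not cover constructs: {sorted(missing)[:5]}")
    called = set(hits.hit_ids)
    true_hits = {cid for cid in hits.table.index if truth.is_hit[cid]}
    tp = len(called & true_hits)
    recall = tp / len(true_hits) if true_hits else None
    precision = tp / len(called) if called else None
    return RecoveryReport(
        recall=recall,
        precision=precision,
        n_called=len(called),
        n_true=len(true_hits),
        recall_undefined=not true_hits,
        precision_undefined=not called,
    )
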