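"""Plate-level statistics for arrayed screens.

The workhorse is the B-score: Tukey median polish decomposes a plate of
readouts into overall + row + column effects + residuals, and each
residual is scaled by 1.4826 times the median absolute residual of the
plate.  Because medians drive both steps, single extreme wells barely
perturb the scores of their neighbours — the property that makes the
B-score the standard normalisation for 96-well screens with row/column
artefacts.

Also here: z-scores of sample wells against empty-vector control wells
(the "separated by more than three standard deviations" criterion),
Welch's two-tailed t-test for group comparisons, and selection of the
readout timepoint with the largest dynamic range before signal
saturation (for cumulative colorimetric assays such as MTS).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PlateGrid",
    "MedianPolishFit",
    "BScoreGrid",
    "TTestResult",
    "TimepointChoice",
    "median_polish",
    "b_score",
    "replicate_agreement",
    "z_score_vs_controls",
    "plate_z_scores",
    "welch_t_test",
    "select_mts_timepoint",
    "well_to_rc",
    "rc_to_well",
]

MAD_SCALE = 1.4826  # makes the MAD consistent with the SD under normality

ROLES = ("sample", "control", "blank")


def well_to_rc(well: str) -> tuple[int, int]:
    """'B03' -> (1, 2).  Row letters A.. ; columns are 1-based."""
    well = well.strip().upper()
    if len(well) < 2 or not well[0].isalpha() or not well[1:].isdigit():
        raise ValueError(f"malformed well name {well!r}")
    return ord(well[0]) - ord("A"), int(well[1:]) - 1


def rc_to_well(row: int, col: int) -> str:
    return f"{chr(ord('A') + row)}{col + 1:02d}"


@dataclass
class PlateGrid:
    """One plate readout with well roles and an inclusion mask."""

    values: np.ndarray
    mask: np.ndarray | None = None
    roles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError("plate must be a 2-D matrix of at least 2x2 wells")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.roles is None:
            self.roles = np.full(self.values.shape, "sample", dtype=object)
        else:
            self.roles = np.asarray(self.roles, dtype=object)
        if self.mask.shape != self.values.shape or self.roles.shape != self.values.shape:
            raise ValueError("mask/roles shape must match values")
        bad = set(np.unique(self.roles)) - set(ROLES)
        if bad:
            raise ValueError(f"unknown well roles {sorted(bad)}; expected {ROLES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def role_values(self, role: str, masked: bool = True) -> np.ndarray:
        sel = self.roles == role
        if masked:
            sel &= self.mask
        return self.values[sel]

    # -- CSV IO: rows labelled A.., columns 1..N, as plate readers export --

    def to_csv(self, path: str | Path, roles_path: str | Path | None = None) -> None:
        n_rows, n_cols = self.shape
        header = [""] + [str(c + 1) for c in range(n_cols)]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(header)
            for r in range(n_rows):
                w.writerow([chr(ord("A") + r)] + [repr(float(v)) for v in self.values[r]])
        if roles_path is not None:
            with open(roles_path, "w", newline="") as fh:
                w = csv.writer(fh, lineterminator="\n")
                w.writerow(header)
                for r in range(n_rows):
                    w.writerow(
                        [chr(ord("A") + r)]
                        + [
                            ("x" if not self.mask[r, c] else self.roles[r, c])
                            for c in range(n_cols)
                        ]
                    )

    @classmethod
    def from_csv(
        cls, path: str | Path, roles_path: str | Path | None = None
    ) -> "PlateGrid":
        def read_grid(p):
            with open(p, newline="") as fh:
                rows = [row for row in csv.reader(fh) if row]
            return [row[1:] for row in rows[1:]]

        cells = read_grid(path)
        values = np.array([[float(v) for v in row] for row in cells])
        mask = None
        roles = None
        if roles_path is not None:
            role_cells = read_grid(roles_path)
            roles = np.array(role_cells, dtype=object)
            if roles.shape != values.shape:
                raise ValueError("roles CSV shape does not match plate CSV")
            mask = roles != "x"
            roles = np.where(mask, roles, "sample").astype(object)
        return cls(values=values, mask=mask, roles=roles)


@dataclass
class MedianPolishFit:
    """Additive decomposition values = overall + row + col + residual."""

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iter: int
    converged: bool

    def fitted(self) -> np.ndarray:
        return self.overall + self.row_effects[:, None] + self.col_effects[None, :]


def median_polish(
    plate: PlateGrid | np.ndarray, max_iter: int = 100, tol: float = 1e-9
) -> MedianPolishFit:
    """Tukey's median polish with alternating row/column median sweeps.

    After each pair of sweeps the medians of the accumulated row and column
    effects are folded into the overall term (Tukey's centring convention).
    Masked wells are excluded from every median.  Converges when the
    largest absolute adjustment of a sweep drops below ``tol``.
    """
    if not isinstance(plate, PlateGrid):
        plate = PlateGrid(values=np.asarray(plate, dtype=float))
    r = plate.values.astype(float).copy()
    r[~plate.mask] = np.nan
    n_rows, n_cols = r.shape
    for i in range(n_rows):
        if np.count_nonzero(plate.mask[i]) < 2:
            raise ValueError(f"row {chr(ord('A') + i)} has fewer than 2 unmasked wells")
    for j in range(n_cols):
        if np.count_nonzero(plate.mask[:, j]) < 2:
            raise ValueError(f"column {j + 1} has fewer than 2 unmasked wells")

    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        rdelta = np.nanmedian(r, axis=1)
        r -= rdelta[:, None]
        row_eff += rdelta
        cshift = float(np.median(col_eff))
        col_eff -= cshift
        overall += cshift

        cdelta = np.nanmedian(r, axis=0)
        r -= cdelta[None, :]
        col_eff += cdelta
        rshift = float(np.median(row_eff))
        row_eff -= rshift
        overall += rshift

        step = max(
            float(np.max(np.abs(rdelta))),
            float(np.max(np.abs(cdelta))),
            abs(cshift),
            abs(rshift),
        )
        if step < tol:
            converged = True
            break
    residuals = r  # NaN at masked wells
    return MedianPolishFit(
        overall=overall,
        row_effects=row_eff,
        col_effects=col_eff,
        residuals=residuals,
        n_iter=n_iter,
        converged=converged,
    )


@dataclass
class BScoreGrid:
    """Median-polish residuals scaled by 1.4826 x median absolute residual."""

    b: np.ndarray
    mad: float
    degenerate: bool
    mask: np.ndarray
    roles: np.ndarray


def b_score(plate: PlateGrid, max_iter: int = 100, tol: float = 1e-9) -> BScoreGrid:
    """Compute per-well B-scores for one plate replicate.

    A plate whose residuals are (numerically) all zero — e.g. an exactly
    additive plate — has no resolvable spread; it is flagged degenerate and
    all B-scores are set to 0.
    """
    fit = median_polish(plate, max_iter=max_iter, tol=tol)
    resid = fit.residuals
    unmasked = plate.mask
    mad = MAD_SCALE * float(np.nanmedian(np.abs(resid[unmasked])))
    vrange = float(np.nanmax(plate.values[unmasked]) - np.nanmin(plate.values[unmasked]))
    if mad < 1e-12 * max(vrange, 1.0):
        warnings.warn("plate residual MAD is ~0; B-scores degenerate, set to 0")
        b = np.zeros_like(resid)
        b[~unmasked] = np.nan
        return BScoreGrid(b=b, mad=mad, degenerate=True, mask=unmasked, roles=plate.roles)
    b = resid / mad
    return BScoreGrid(b=b, mad=mad, degenerate=False, mask=unmasked, roles=plate.roles)


def replicate_agreement(b1: BScoreGrid, b2: BScoreGrid) -> dict[str, float]:
    """Pearson and Spearman correlation of duplicate B-scores over unmasked
    sample wells."""
    if b1.b.shape != b2.b.shape:
        raise ValueError("replicate plates have different shapes")
    if b1.degenerate or b2.degenerate:
        raise ValueError("cannot correlate degenerate B-score grids")
    sel = b1.mask & b2.mask & (b1.roles == "sample") & (b2.roles == "sample")
    x, y = b1.b[sel], b2.b[sel]
    if x.size < 3:
        raise ValueError(f"only {x.size} paired sample wells; need at least 3")
    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pearson.statistic),
        "spearman_rho": float(spearman.statistic),
        "n_wells": int(x.size),
    }


def z_score_vs_controls(
    sample_values: Sequence[float], control_values: Sequence[float]
) -> np.ndarray:
    """z_i = (x_i - mean(controls)) / sd(controls, ddof=1)."""
    x = np.asarray(sample_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if ctrl.size < 2:
        raise ValueError("need at least 2 control values")
    sd = float(ctrl.std(ddof=1))
    if sd == 0:
        raise ValueError("control values have zero variance")
    return (x - float(ctrl.mean())) / sd


def plate_z_scores(plate: PlateGrid) -> np.ndarray:
    """Per-well z-scores of a plate against its own control wells
    (NaN at masked wells)."""
    ctrl = plate.role_values("control")
    z = np.full(plate.shape, np.nan)
    z[plate.mask] = z_score_vs_controls(plate.values[plate.mask], ctrl)
    return z


@dataclass
class TTestResult:
    t: float
    df: float
    p_two_tailed: float
    note: str = ""


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Welch's unequal-variance two-tailed t-test with Satterthwaite df.

    Degenerate conventions: two constant groups with equal means give
    p = 1; constant groups with unequal means give the p -> 0 limit,
    flagged in ``note``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=float(a.size + b.size - 2), p_two_tailed=1.0,
                               note="both groups constant, equal means")
        return TTestResult(t=np.inf, df=float(a.size + b.size - 2), p_two_tailed=0.0,
                           note="both groups constant, unequal means; p is a 0-limit")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p_two_tailed=float(res.pvalue))


@dataclass
class TimepointChoice:
    index: int
    dynamic_range: float
    saturated_fallback: bool = False


def select_mts_timepoint(
    series: np.ndarray,
    saturation_limit: float,
    mask: np.ndarray | None = None,
) -> TimepointChoice:
    """Choose the readout timepoint with the highest dynamic range whose
    signal has not saturated.

    ``series`` is wells x timepoints.  Dynamic range is the 95th minus the
    5th percentile of well values at a timepoint (robust to single
    outliers); a timepoint is saturated when any unmasked well exceeds
    ``saturation_limit``.  If every timepoint saturates, the earliest
    timepoint at which fewer than half of the wells saturate is returned
    (earliest overall if none qualifies) and the choice is flagged.
    Ties in dynamic range go to the earliest timepoint.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be wells x timepoints")
    if saturation_limit <= 0:
        raise ValueError("saturation_limit must be positive")
    n_wells, n_time = series.shape
    if mask is None:
        mask = np.ones(n_wells, dtype=bool)
    vals = series[mask]
    if n_time == 1:
        warnings.warn("single timepoint; returning it trivially")
        dr = float(np.percentile(vals[:, 0], 95) - np.percentile(vals[:, 0], 5))
        return TimepointChoice(index=0, dynamic_range=dr)
    dyn = np.percentile(vals, 95, axis=0) - np.percentile(vals, 5, axis=0)
    saturated = (vals > saturation_limit).any(axis=0)
    if not saturated.all():
        candidates = np.flatnonzero(~saturated)
        best = candidates[int(np.argmax(dyn[candidates]))]
        # earliest on exact ties
        tied = candidates[dyn[candidates] == dyn[best]]
        best = int(tied.min())
        return TimepointChoice(index=best, dynamic_range=float(dyn[best]))
    frac_sat = (vals > saturation_limit).mean(axis=0)
    under_half = np.flatnonzero(frac_sat < 0.5)
    idx = int(under_half.min()) if under_half.size else 0
    warnings.warn("all timepoints saturate at least one well; falling back")
    return TimepointChoice(index=idx, dynamic_range=float(dyn[idx]), saturated_fallback=True)
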