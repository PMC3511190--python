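"""Cohort statistics: shift-table summaries, the low/high-motion group
comparison, and the bone-motion -> bifurcation-shift multiple regression.

The shift table holds one row per subject and one column per tracked
quantity: centroid-shift norms of C1-C4 and the mandible, and displacement
norms of the five carotid bifurcations vA-vE (all mm, all >= 0).  Summaries
are mean +/- sample SD (n-1 denominator) and max, reported at 2 decimals
(half-up) with full precision retained internally.

The regression models each bifurcation displacement component in the
standardized frame as a linear function of four vertebral parameters
representing head rotation and anteflexion::

    y_ij = b0 + b1 x1 + b2 x2 + b3 x3 + b4 x4,
    i in {vA..vE}, j in {dx', dy', dz'}

    x1 = C4 dx' - C2 dx'   x2 = C4 dy' - C2 dy'
    x3 = C4 dz' - C2 dz'   x4 = C4 dalpha' - C2 dalpha'

(x1-x3 in mm, x4 in degrees, deliberately unstandardized).  One ordinary
least-squares fit per (i, j) target, 15 fits in all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

from .frames import DisplacementRecord

BONE_COLUMNS = ("C1", "C2", "C3", "C4", "mandible")
VESSEL_COLUMNS = ("vA", "vB", "vC", "vD", "vE")
SHIFT_COLUMNS = BONE_COLUMNS + VESSEL_COLUMNS
VERTEBRA_COLUMNS = ("C1", "C2", "C3", "C4")
REGRESSOR_NAMES = ("x1", "x2", "x3", "x4")
COMPONENTS = ("dx", "dy", "dz")

#: published six-subject reference cohort: absolute centroid-shift norms of
#: C1-C4 and the mandible plus displacement norms of bifurcations vA-vE (mm),
#: between two CTA acquisitions, after fiducial (maxillofacial) alignment.
_REFERENCE_ROWS = [
    (1, "L", 1.99, 4.18, 8.31, 11.43, 0.95, 6.78, 3.75, 3.07, 4.62, 2.36),
    (2, "L", 0.13, 0.40, 0.72, 1.39, 7.34, 1.43, 1.94, 3.13, 4.23, 2.04),
    (3, "L", 0.32, 0.96, 1.86, 3.03, 0.50, 3.54, 2.50, 3.43, 2.56, 2.91),
    (4, "R", 1.16, 1.88, 3.17, 3.91, 1.01, 6.86, 4.96, 4.52, 3.93, 2.37),
    (5, "R", 2.19, 4.68, 9.83, 13.38, 0.48, 12.49, 10.04, 9.18, 8.03, 4.59),
    (6, "R", 0.35, 0.97, 1.61, 2.26, 0.20, 2.03, 0.91, 2.99, 3.51, 0.53),
]

#: the reference cohort's low-motion / high-motion split by cervical shift
GROUP_A_SUBJECTS = (2, 3, 6)
GROUP_B_SUBJECTS = (1, 4, 5)


class StatsError(ValueError):
    pass


def reference_shift_table() -> pd.DataFrame:
    """The built-in six-subject reference shift table (index = subject id)."""
    df = pd.DataFrame(_REFERENCE_ROWS, columns=("subject", "side") + SHIFT_COLUMNS)
    return df.set_index("subject")


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _shift_values(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHIFT_COLUMNS if c not in table.columns]
    if missing:
        raise StatsError(f"shift table is missing columns: {missing}")
    vals = table[list(SHIFT_COLUMNS)].astype(float)
    if (vals.values < 0).any():
        raise StatsError("shift norms must be non-negative")
    return vals


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column (mean, sample SD, max) of a shift table.

    Full precision; use ``round_report`` for the 2-decimal presentation.
    """
    vals = _shift_values(table)
    if len(vals) < 2:
        raise StatsError("need at least 2 rows to summarize")
    return pd.DataFrame({"mean": vals.mean(axis=0),
                         "sd": vals.std(axis=0, ddof=1),
                         "max": vals.max(axis=0)})


def round_report(summary: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    return summary.map(lambda x: round_half_up(x, decimals))


@dataclass(frozen=True)
class GroupComparison:
    bone_mean_a: float
    bone_mean_b: float
    vessel_mean_a: float
    vessel_mean_b: float


def group_compare(table: pd.DataFrame, group_a: Iterable, group_b: Iterable) -> GroupComparison:
    """Mean cervical (C1-C4, pooled entries) and bifurcation (vA-vE, pooled)
    shifts for two disjoint subject groups."""
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise StatsError("groups must be non-empty")
    if set(a) & set(b):
        raise StatsError(f"groups overlap: {sorted(set(a) & set(b))}")
    vals = _shift_values(table)
    unknown = [s for s in a + b if s not in table.index]
    if unknown:
        raise StatsError(f"unknown subject id(s): {unknown}")

    def pooled(rows, cols):
        return float(vals.loc[rows, list(cols)].values.mean())

    return GroupComparison(
        bone_mean_a=pooled(a, VERTEBRA_COLUMNS), bone_mean_b=pooled(b, VERTEBRA_COLUMNS),
        vessel_mean_a=pooled(a, VESSEL_COLUMNS), vessel_mean_b=pooled(b, VESSEL_COLUMNS))


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def build_regressors(records_by_subject: Dict) -> pd.DataFrame:
    """The four vertebral regressors per subject from SCS displacement
    records: componentwise C4 - C2 differences of (dx, dy, dz, dalpha).

    ``records_by_subject`` maps subject id -> {segment name ->
    :class:`DisplacementRecord`} with at least C2 and C4 present, in the
    standardized frame.
    """
    rows = {}
    for subject, records in records_by_subject.items():
        missing = [s for s in ("C2", "C4") if s not in records]
        if missing:
            raise StatsError(f"subject {subject}: missing record(s) for {missing}")
        c2, c4 = records["C2"], records["C4"]
        for rec in (c2, c4):
            if rec.frame != "SCS":
                raise StatsError(f"subject {subject}: regressors need SCS records, got {rec.frame}")
            if rec.dalpha is None:
                raise StatsError(f"subject {subject}: record for {rec.segment} lacks angles")
        rows[subject] = (c4.dx - c2.dx, c4.dy - c2.dy, c4.dz - c2.dz,
                         c4.dalpha - c2.dalpha)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(REGRESSOR_NAMES))


@dataclass
class RegressionFit:
    """OLS fit of one bifurcation displacement component.

    ``params`` is (b0, b1..b4); residuals are observed - calculated.
    """

    target: Tuple[str, str]
    params: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    r_squared: float

    def predict(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        return self.params[0] + x @ self.params[1:]

    def summary(self) -> str:
        b = self.params
        lines = [f"target {self.target[0]} {self.target[1]}:",
                 "  " + "  ".join(f"b{k}={b[k]: .4f}" for k in range(len(b))),
                 f"  R^2 = {self.r_squared:.4f}   n = {len(self.residuals)}"]
        return "\n".join(lines)


def fit_regression(x, y, target: Tuple[str, str] = ("", "")) -> RegressionFit:
    """Ordinary least squares of one target component on (x1..x4) with an
    intercept.  Warns on a saturated fit (n = 5); errors on rank deficiency.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float).ravel()
    if x.ndim != 2 or x.shape[1] != len(REGRESSOR_NAMES):
        raise StatsError(f"regressor matrix must be (n, {len(REGRESSOR_NAMES)})")
    n = len(y)
    if x.shape[0] != n:
        raise StatsError("regressors and response differ in length")
    if n < 5:
        raise StatsError("need at least 5 rows (intercept + 4 slopes)")
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise StatsError("design matrix is rank deficient; more subjects or "
                         "fewer regressors are needed")
    if n == design.shape[1]:
        warnings.warn("saturated fit: 5 observations for 5 parameters; residuals "
                      "are ~0 and the fit is not predictive", stacklevel=2)
    params, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ params
    resid = y - fitted
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if tss == 0 else 1.0 - float((resid ** 2).sum()) / tss
    return RegressionFit(target=target, params=params, fitted=fitted,
                         residuals=resid, r_squared=r2)


def fit_all_targets(x: pd.DataFrame, components: pd.DataFrame) -> Dict[Tuple[str, str], RegressionFit]:
    """One OLS fit per (bifurcation, component): 15 fits.

    ``components`` columns are named like ``vA_dx`` .. ``vE_dz``; rows are
    aligned with ``x`` by index.
    """
    fits = {}
    xa = x.loc[components.index, list(REGRESSOR_NAMES)].values
    for lab in VESSEL_COLUMNS:
        for comp in COMPONENTS:
            col = f"{lab}_{comp}"
            if col not in components.columns:
                raise StatsError(f"missing component column '{col}'")
            fits[(lab, comp)] = fit_regression(xa, components[col].values, target=(lab, comp))
    return fits


def regression_table(fits: Dict[Tuple[str, str], RegressionFit]) -> pd.DataFrame:
    rows = []
    for (lab, comp), fit in fits.items():
        rows.append({"bifurcation": lab, "component": comp,
                     **{f"b{k}": fit.params[k] for k in range(5)},
                     "r_squared": fit.r_squared})
    return pd.DataFrame(rows)


def recovery_experiment(n_subjects: int = 6, motion_scale: float = 1.0, seed: int = 0,
                        **kwargs):
    """Phantom-cohort ground-truth recovery over the full pipeline; see
    :func:`carotidshift.pipeline.recovery_experiment`."""
    from .pipeline import recovery_experiment as _run
    return _run(n_subjects=n_subjects, motion_scale=motion_scale, seed=seed, **kwargs)


def shift_table_from_records(per_subject: Dict) -> pd.DataFrame:
    """Assemble a shift table from measured per-subject norms.

    ``per_subject`` maps subject id -> {column name -> shift norm (mm)} over
    C1..C4, mandible, vA..vE.
    """
    df = pd.DataFrame.from_dict(per_subject, orient="index")
    df.index.name = "subject"
    df.insert(0, "side", "L")
    return df
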