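"""Clinical-parameter comparisons between carrier groups.

Patients are split by somatic-carrier status (read fraction above or below
the control-derived cut-off) and each laboratory parameter is compared
with a two-sample Student's t-test (pooled variance; Welch available
behind a flag).  Where a one-tailed test is requested the direction must
be given explicitly per parameter; the default direction vector encodes
the expected clinical picture of an active-disease subgroup: autoantibody
(anti-dsDNA) and disease-activity score up; complement C3/C4, white cells,
lymphocytes and platelets down.

Missing values are dropped per parameter (pairwise deletion), so each
comparison reports its own group sizes.  No multiplicity adjustment is
applied across parameters; the report is per-parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, InsufficientDataError
from .screen import ContingencyTable, fisher_exact_two_tailed

logger = logging.getLogger(__name__)

#: Expected direction of the carrier-group difference, per default parameter.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "anti_dsDNA": "greater",
    "C3": "less",
    "C4": "less",
    "WBC": "less",
    "lymphocytes": "less",
    "platelets": "less",
    "SLEDAI": "greater",
}

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class GroupComparison:
    """One parameter's carrier vs non-carrier comparison."""

    parameter: str
    n_low: int
    n_high: int
    mean_low: float
    mean_high: float
    t_statistic: float
    df: float
    tails: int
    p_value: float

    @property
    def stars(self) -> str:
        """Significance marker in the usual figure convention."""
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*" if self.tails == 2 else "§"
        return "ns"


def two_sample_t(
    x,
    y,
    tails: int = 2,
    direction: str = "greater",
    welch: bool = False,
    parameter: str = "",
) -> GroupComparison:
    """Student's two-sample t-test of x (carriers/high) against y (low).

    Pooled variance by default, df = n1 + n2 - 2; ``welch=True`` switches
    to the unequal-variance statistic with Welch-Satterthwaite df.  For a
    one-tailed test, ``direction`` states the alternative for the mean of
    ``x`` relative to ``y`` ("greater" or "less"); the one-tailed p is half
    the two-tailed p when the observed difference lies on the tested side
    and 1 minus half of it otherwise.
    """
    x = np.asarray([v for v in np.ravel(x) if not np.isnan(v)], dtype=float)
    y = np.asarray([v for v in np.ravel(y) if not np.isnan(v)], dtype=float)
    if tails not in (1, 2):
        raise InputError(f"tails must be 1 or 2, got {tails}")
    if direction not in ("greater", "less"):
        raise InputError(f"direction must be 'greater' or 'less', got {direction!r}")
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(
            f"each group needs >= 2 values, got {n1} and {n2}"
        )
    mx, my = float(x.mean()), float(y.mean())
    vx, vy = float(x.var(ddof=1)), float(y.var(ddof=1))
    if welch:
        se2 = vx / n1 + vy / n2
        df = se2**2 / ((vx / n1) ** 2 / (n1 - 1) + (vy / n2) ** 2 / (n2 - 1)) if se2 > 0 else float(n1 + n2 - 2)
    else:
        pooled = ((n1 - 1) * vx + (n2 - 1) * vy) / (n1 + n2 - 2)
        se2 = pooled * (1.0 / n1 + 1.0 / n2)
        df = float(n1 + n2 - 2)
    if se2 == 0.0:
        t = 0.0 if mx == my else math_inf_signed(mx - my)
    else:
        t = (mx - my) / np.sqrt(se2)
    p_two = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    if tails == 2:
        p = p_two
    else:
        on_side = (mx - my > 0) if direction == "greater" else (mx - my < 0)
        p = p_two / 2.0 if on_side else 1.0 - p_two / 2.0
    p = min(max(p, _TINY), 1.0)
    if t == 0.0 and tails == 2:
        p = 1.0
    return GroupComparison(
        parameter=parameter,
        n_low=n2,
        n_high=n1,
        mean_low=my,
        mean_high=mx,
        t_statistic=float(t),
        df=df,
        tails=tails,
        p_value=p,
    )


def math_inf_signed(delta: float) -> float:
    return float("inf") if delta > 0 else float("-inf")


def compare_clinical(
    clinical: pd.DataFrame,
    carrier_flags: pd.Series | dict[str, bool],
    tails: dict[str, int] | int = 2,
    directions: dict[str, str] | None = None,
    welch: bool = False,
) -> list[GroupComparison]:
    """Compare every clinical parameter between carriers and non-carriers.

    ``clinical`` holds one row per patient with an ``individual_id`` column
    and one column per parameter; ``carrier_flags`` maps patient IDs to
    carrier status.  Missing values are dropped per parameter; a parameter
    with fewer than two values in either group is skipped with a warning.
    """
    if isinstance(carrier_flags, dict):
        carrier_flags = pd.Series(carrier_flags)
    if "individual_id" not in clinical.columns:
        raise InputError("clinical table needs an individual_id column")
    ids = clinical["individual_id"]
    unknown = set(ids) - set(carrier_flags.index)
    if unknown:
        raise InputError(
            f"carrier flags missing for {len(unknown)} patients, e.g. {sorted(unknown)[:3]}"
        )
    flags = carrier_flags.loc[ids].to_numpy(dtype=bool)
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    results: list[GroupComparison] = []
    parameters = [c for c in clinical.columns if c != "individual_id"]
    for name in parameters:
        values = clinical[name].to_numpy(dtype=float)
        present = ~np.isnan(values)
        high = values[present & flags]
        low = values[present & ~flags]
        n_tails = tails.get(name, 2) if isinstance(tails, dict) else tails
        try:
            results.append(
                two_sample_t(
                    high,
                    low,
                    tails=n_tails,
                    direction=directions.get(name, "greater"),
                    welch=welch,
                    parameter=name,
                )
            )
        except InsufficientDataError as err:
            logger.warning("skipping parameter %s: %s", name, err)
    return results


def categorical_assoc(outcome_flags, carrier_flags) -> float:
    """Fisher exact p for a binary outcome against carrier status."""
    outcome = [bool(v) for v in outcome_flags]
    carrier = [bool(v) for v in carrier_flags]
    if len(outcome) != len(carrier):
        raise InputError(
            f"outcome ({len(outcome)}) and carrier ({len(carrier)}) flags are not aligned"
        )
    a = sum(1 for o, c in zip(outcome, carrier) if c and o)
    b = sum(1 for o, c in zip(outcome, carrier) if c and not o)
    c_ = sum(1 for o, c in zip(outcome, carrier) if not c and o)
    d = sum(1 for o, c in zip(outcome, carrier) if not c and not o)
    return fisher_exact_two_tailed(ContingencyTable(a, b, c_, d))
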