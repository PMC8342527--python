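"""Longitudinal change-change association testing.

For a variable observed at two timepoints the change score (delta) is
followup minus baseline per paired subject.  The association between an
exposure delta (e.g. change in weekly alcohol grams) and an outcome delta
(e.g. change in FVC, liters) is the Pearson correlation R of the deltas with

    df = n - 2,    t = |R| * sqrt(df) / sqrt(1 - R^2),

the two-tailed p-value from the t distribution with df degrees of freedom,
and the compound significance rule

    significant  <=>  p < 0.05  and  |R| > 0.05 ,

whose |R| floor guards against trivially small effects reaching nominal
significance at large n.  A least-squares trend line (outcome delta on
exposure delta) is fitted alongside.  Both thresholds are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import PairedCohort

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_R_THRESHOLD = 0.05


@dataclass(frozen=True)
class LongitudinalAssociation:
    """Change-change correlation with the full significance machinery."""

    exposure_delta: str
    outcome_delta: str
    n: int
    R: float
    df: int
    t: float
    p: float
    slope: float
    intercept: float
    significant: bool
    stratum: str = "all"

    def __post_init__(self) -> None:
        assert self.df == self.n - 2
        assert self.t >= 0 and 0 <= self.p <= 1


@dataclass(frozen=True)
class StratumSpec:
    """Named deterministic subject filter over a paired cohort.

    ``predicate`` receives the wide paired frame (columns ``<var>__baseline``
    and ``<var>__followup`` indexed by subject) and returns a boolean mask.
    """

    name: str
    predicate: Callable[[pd.DataFrame], pd.Series]


def stratum_all() -> StratumSpec:
    return StratumSpec("all", lambda wide: pd.Series(True, index=wide.index))


def stratum_baseline_equals(variable: str, value, name: str | None = None) -> StratumSpec:
    """Subjects whose baseline value of ``variable`` equals ``value`` (e.g. sex)."""
    label = name or f"{variable}={value}"
    return StratumSpec(label, lambda wide: wide[f"{variable}__baseline"] == value)


def stratum_unchanged(variable: str, name: str | None = None) -> StratumSpec:
    """Subjects whose value of ``variable`` is identical at both timepoints."""
    label = name or f"{variable} unchanged"

    def pred(wide: pd.DataFrame) -> pd.Series:
        b = wide[f"{variable}__baseline"]
        f = wide[f"{variable}__followup"]
        return (b == f) & b.notna() & f.notna()

    return StratumSpec(label, pred)


def compute_change_scores(
    paired: PairedCohort, variable: str
) -> tuple[pd.Series, int]:
    """Per-subject delta (followup - baseline); returns (deltas, n_dropped)."""
    if variable not in paired.baseline.variable_names:
        raise ValueError(f"variable {variable!r} absent from baseline")
    if variable not in paired.followup.variable_names:
        raise ValueError(f"variable {variable!r} absent from followup")
    ids = list(paired.paired_ids)
    b = pd.to_numeric(paired.baseline.data.loc[ids, variable])
    f = pd.to_numeric(paired.followup.data.loc[ids, variable])
    delta = f - b
    dropped = int(delta.isna().sum())
    return delta.dropna(), dropped


def change_correlation_test(
    x_deltas: Sequence[float],
    y_deltas: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    stratum: str = "all",
) -> LongitudinalAssociation:
    """Correlation test of paired change scores with the compound rule."""
    x = np.asarray(x_deltas, dtype=float)
    y = np.asarray(y_deltas, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("deltas must be 1-d arrays of equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 4:
        raise ValueError(f"change correlation needs n >= 4 paired deltas, got {n}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in a delta series")
    R = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    df = n - 2
    one_minus = 1.0 - R * R
    if one_minus <= 0:
        t = float("inf")
        p = 0.0
    else:
        t = abs(R) * np.sqrt(df) / np.sqrt(one_minus)
        p = float(2.0 * stats.t.sf(t, df))
    slope = R * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return LongitudinalAssociation(
        exposure_delta=x_name,
        outcome_delta=y_name,
        n=int(n),
        R=R,
        df=int(df),
        t=float(t),
        p=min(p, 1.0),
        slope=float(slope),
        intercept=intercept,
        significant=bool(p < p_threshold and abs(R) > r_threshold),
        stratum=stratum,
    )


def stratified_association(
    paired: PairedCohort,
    exposure: str,
    outcome: str,
    stratum: StratumSpec | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r_threshold: float = DEFAULT_R_THRESHOLD,
) -> LongitudinalAssociation:
    """Change-change test of exposure vs outcome within a stratum.

    With ``stratum=None`` (or the vacuous "all" stratum) this is the plain
    unstratified analysis.
    """
    spec = stratum or stratum_all()
    wide = paired.wide()
    mask = spec.predicate(wide).astype(bool)
    ids = [sid for sid, keep in zip(wide.index, mask) if keep]
    if len(ids) < 4:
        raise ValueError(f"stratum {spec.name!r} has n = {len(ids)} < 4 subjects")
    sub = PairedCohort(paired.baseline, paired.followup, tuple(ids))
    dx, _ = compute_change_scores(sub, exposure)
    dy, _ = compute_change_scores(sub, outcome)
    common = dx.index.intersection(dy.index)
    return change_correlation_test(
        dx.loc[common].to_numpy(),
        dy.loc[common].to_numpy(),
        x_name=f"d_{exposure}",
        y_name=f"d_{outcome}",
        p_threshold=p_threshold,
        r_threshold=r_threshold,
        stratum=spec.name,
    )


def change_bins(
    deltas: Sequence[float], small_cutoff: float = 100.0
) -> pd.Series:
    """Descriptive binning of exposure deltas: no change / small / large.

    Mirrors the reporting convention of no change, change below the cutoff,
    and change of at least the cutoff (default 100 g/week for alcohol).
    """
    d = pd.Series(deltas, dtype=float)
    out = pd.Series(index=d.index, dtype=object)
    out[d == 0] = "no_change"
    out[(d != 0) & (d.abs() < small_cutoff)] = f"<{small_cutoff:g}"
    out[d.abs() >= small_cutoff] = f">={small_cutoff:g}"
    out[d.isna()] = np.nan
    return out


def association_frame(assocs: Sequence[LongitudinalAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "exposure": a.exposure_delta,
                "outcome": a.outcome_delta,
                "stratum": a.stratum,
                "n": a.n,
                "R": a.R,
                "t": a.t,
                "df": a.df,
                "p": a.p,
                "slope": a.slope,
                "intercept": a.intercept,
                "significant": a.significant,
            }
            for a in assocs
        ]
    )
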