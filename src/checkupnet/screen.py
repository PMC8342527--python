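"""Pairwise association screen: correlation matrix and ANOVA effect sizes.

Every encodable variable enters one Pearson product-moment correlation matrix
computed over pairwise-complete observations (per-pair sample sizes are
retained, matching per-analysis exclusion of missing records rather than
listwise deletion).  Categorical exposures are additionally screened against
continuous outcomes with the correlation ratio eta = sqrt(SS_between /
SS_total), the effect size of a one-way ANOVA across answer categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import CohortTable
from .questionnaire import encode_table

logger = logging.getLogger(__name__)

DEFAULT_MIN_PAIR_N = 30


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise Pearson matrix with per-pair complete counts.

    Entries that are unavailable (fewer than ``min_pair_n`` complete pairs, or
    zero variance on the pairwise-complete subset) are NaN.
    """

    variable_names: tuple[str, ...]
    r: np.ndarray
    n_pair: np.ndarray
    method: str = "pearson"

    def __post_init__(self) -> None:
        self.variable_names = tuple(self.variable_names)
        p = len(self.variable_names)
        if self.r.shape != (p, p) or self.n_pair.shape != (p, p):
            raise ValueError("matrix shapes do not match variable names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.r, index=self.variable_names, columns=self.variable_names
        )

    def entry(self, a: str, b: str) -> float:
        i = self.variable_names.index(a)
        j = self.variable_names.index(b)
        return float(self.r[i, j])


def pairwise_correlation_matrix(
    table: CohortTable | pd.DataFrame,
    min_pair_n: int = DEFAULT_MIN_PAIR_N,
    exclude: tuple[str, ...] = (),
) -> CorrelationMatrix:
    """Pearson correlations over pairwise-complete subjects.

    Accepts a cohort table (encoded via the questionnaire rules) or an
    already-numeric DataFrame.  Zero-variance and under-sampled entries are
    flagged unavailable (NaN), never raised.
    """
    if min_pair_n < 3:
        raise ValueError("min_pair_n must be at least 3")
    if isinstance(table, CohortTable):
        df = encode_table(table, exclude=exclude)
    else:
        df = table.drop(columns=list(exclude), errors="ignore").astype(float)
    names = tuple(df.columns)
    notna = df.notna().to_numpy()
    n_pair = notna.T.astype(np.int64) @ notna.astype(np.int64)
    r = df.corr(method="pearson", min_periods=min_pair_n).to_numpy()
    p = len(names)
    r[np.diag_indices(p)] = 1.0
    unavailable = np.isnan(r)
    off = ~np.eye(p, dtype=bool)
    if (unavailable & off).any():
        bad = int((unavailable & off).sum() // 2)
        logger.info("%d pairwise correlations unavailable (low n or zero variance)", bad)
    return CorrelationMatrix(names, r, n_pair)


def correlation_ratio(groups: Sequence[np.ndarray]) -> float:
    """eta = sqrt(between-group SS / total SS) over outcome values per category.

    Zero total variance yields eta = 0 (logged) rather than an error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    arrays = [a for a in arrays if a.size > 0]
    if len(arrays) < 2:
        raise ValueError("correlation ratio needs at least 2 non-empty groups")
    total = np.concatenate(arrays)
    if total.size < 3:
        raise ValueError("correlation ratio needs total n >= 3")
    grand = total.mean()
    ss_total = float(((total - grand) ** 2).sum())
    if ss_total == 0.0:
        logger.info("correlation ratio: zero total sum of squares, eta defined as 0")
        return 0.0
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    return float(np.sqrt(ss_between / ss_total))


def pair_screen(
    table: CohortTable,
    exposures: Sequence[str],
    outcomes: Sequence[str],
    min_pair_n: int = DEFAULT_MIN_PAIR_N,
    include_self: bool = False,
) -> pd.DataFrame:
    """Screen every exposure x outcome pair by r and (where defined) eta.

    eta is reported when the exposure is a categorical kind (outcome grouped
    by its raw answer levels); rows are sorted by \\|r\\| descending.
    """
    for name in list(exposures) + list(outcomes):
        if name not in table.variable_names:
            raise ValueError(f"variable {name!r} not in table")
    cm = pairwise_correlation_matrix(table, min_pair_n=min_pair_n)
    rows = []
    for e in exposures:
        e_desc = table.descriptor(e)
        for o in outcomes:
            if e == o and not include_self:
                continue
            i = cm.variable_names.index(e)
            j = cm.variable_names.index(o)
            eta = np.nan
            if e_desc.is_categorical and not table.descriptor(o).is_categorical:
                raw = table.data[[e, o]].dropna()
                groups = [
                    raw.loc[raw[e] == lev, o].to_numpy(dtype=float)
                    for lev in e_desc.ordinal_levels
                ]
                groups = [g for g in groups if g.size]
                if len(groups) >= 2:
                    eta = correlation_ratio(groups)
            rows.append(
                {
                    "var1": e,
                    "var2": o,
                    "r": float(cm.r[i, j]),
                    "n_pair": int(cm.n_pair[i, j]),
                    "eta": eta,
                }
            )
    df = pd.DataFrame(rows, columns=["var1", "var2", "r", "n_pair", "eta"])
    df["abs_r"] = df["r"].abs()
    df = df.sort_values(
        ["abs_r", "var1", "var2"], ascending=[False, True, True], kind="mergesort"
    ).drop(columns="abs_r")
    return df.reset_index(drop=True)


def write_matrix(cm: CorrelationMatrix, path: str | Path) -> None:
    """Square TSV with variable names as header row and first column."""
    cm.to_frame().to_csv(path, sep="\t", float_format="%.10f", lineterminator="\n")


def read_matrix(path: str | Path) -> CorrelationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    names = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != names:
        raise ValueError("matrix file rows and columns disagree")
    r = df.to_numpy(dtype=float)
    n = np.full_like(r, fill_value=-1, dtype=np.int64)  # counts unknown after round trip
    return CorrelationMatrix(names, r, n)
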