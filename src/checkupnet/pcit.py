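"""Partial correlation and information theory (PCIT) edge elimination.

For every unordered variable pair (x, y) and every third variable z the three
first-order partial correlations are computed,

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

(and the two rotations), together with the trio's tolerance

    eps = ( r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz ) / 3 ,

the average ratio of partial to direct correlation.  The x-y connection is
discarded whenever

    |r_xy| <= |eps * r_xz|   and   |r_xy| <= |eps * r_yz|

for some z; an edge surviving all p - 2 trios is declared significant.  The
tolerance is *local*: a pair is judged relative to the strength of its trio,
not against a global correlation cutoff, which is what lets PCIT keep weak
but independent associations while removing confounder-induced ones.

Degenerate-input policy (the printed formulas divide by r and sqrt(1 - r^2)
with no guard): direct correlations with magnitude below 1e-12 are clamped to
1e-12 with sign preserved in ratio denominators, and 1 - r^2 is clamped below
at 1e-12.  Because the discard test compares against |eps * r|, a true-zero
flanking correlation still cannot discard a nonzero edge.  Comparisons use
``<=`` at double precision, exactly as specified.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .screen import CorrelationMatrix

logger = logging.getLogger(__name__)

_CLAMP = 1e-12


@dataclass(frozen=True)
class PcitTrio:
    """Diagnostics for a single (x, y, z) trio."""

    r_xy: float
    r_xz: float
    r_yz: float
    r_xy_z: float
    r_xz_y: float
    r_yz_x: float
    epsilon: float
    discard_xy: bool


@dataclass(frozen=True)
class PcitDecision:
    """Significance verdict for one unordered pair."""

    var_x: str
    var_y: str
    r_xy: float
    significant: bool
    eliminating_z: str | None
    trios_evaluated: int


def _safe_denominator(r):
    """Sign-preserving clamp of a direct correlation used as ratio denominator."""
    r = np.asarray(r, dtype=float)
    sign = np.where(r >= 0, 1.0, -1.0)
    return sign * np.maximum(np.abs(r), _CLAMP)


def partial_correlation(r_xy, r_xz, r_yz):
    """First-order partial correlation of x and y given z (vectorized)."""
    r_xy = np.asarray(r_xy, dtype=float)
    r_xz = np.asarray(r_xz, dtype=float)
    r_yz = np.asarray(r_yz, dtype=float)
    den = np.sqrt(
        np.maximum(1.0 - r_xz**2, _CLAMP) * np.maximum(1.0 - r_yz**2, _CLAMP)
    )
    out = (r_xy - r_xz * r_yz) / den
    return out if out.ndim else float(out)


def trio_tolerance(r_xy, r_xz, r_yz):
    """Tolerance eps: the trio's average partial-to-direct correlation ratio."""
    p_xy = partial_correlation(r_xy, r_xz, r_yz)
    p_xz = partial_correlation(r_xz, r_xy, r_yz)
    p_yz = partial_correlation(r_yz, r_xy, r_xz)
    eps = (
        p_xy / _safe_denominator(r_xy)
        + p_xz / _safe_denominator(r_xz)
        + p_yz / _safe_denominator(r_yz)
    ) / 3.0
    return eps if np.ndim(eps) else float(eps)


def evaluate_trio(r_xy: float, r_xz: float, r_yz: float) -> PcitTrio:
    """Full diagnostics for one trio, including the x-y discard verdict."""
    p_xy = partial_correlation(r_xy, r_xz, r_yz)
    p_xz = partial_correlation(r_xz, r_xy, r_yz)
    p_yz = partial_correlation(r_yz, r_xy, r_xz)
    eps = float(trio_tolerance(r_xy, r_xz, r_yz))
    discard = abs(r_xy) <= abs(eps * r_xz) and abs(r_xy) <= abs(eps * r_yz)
    return PcitTrio(r_xy, r_xz, r_yz, p_xy, p_xz, p_yz, eps, discard)


def _matrix_and_names(
    matrix: CorrelationMatrix | np.ndarray,
    names: Sequence[str] | None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(matrix, CorrelationMatrix):
        R = np.array(matrix.r, dtype=float)
        nm = matrix.variable_names
    else:
        R = np.array(matrix, dtype=float)
        nm = tuple(names) if names is not None else tuple(
            f"v{i}" for i in range(R.shape[0])
        )
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    # variables with unavailable entries cannot enter any trio fairly: drop them
    off = ~np.eye(R.shape[0], dtype=bool)
    bad = np.isnan(np.where(off, R, 0.0)).any(axis=1)
    if bad.any():
        dropped = [nm[i] for i in np.where(bad)[0]]
        logger.warning("dropping variables with unavailable correlations: %s", dropped)
        keep = ~bad
        R = R[np.ix_(keep, keep)]
        nm = tuple(n for n, k in zip(nm, keep) if k)
    if R.shape[0] < 3:
        raise ValueError("PCIT needs at least 3 variables (no trios otherwise)")
    return R, nm


def pcit_edge_decisions(
    matrix: CorrelationMatrix | np.ndarray,
    names: Sequence[str] | None = None,
) -> list[PcitDecision]:
    """Apply the elimination rule over all trios (vectorized over pairs per z).

    An edge is significant iff no z discards it; the first discarding z in
    variable order is recorded.  O(p^3) with p the variable count.
    """
    R, nm = _matrix_and_names(matrix, names)
    p = R.shape[0]
    absR = np.abs(R)
    significant = np.ones((p, p), dtype=bool)
    eliminator = np.full((p, p), -1, dtype=np.int64)
    dR = np.maximum(1.0 - R**2, _CLAMP)
    safe_R = _safe_denominator(R)
    for z in range(p):
        a = R[:, z]
        da = np.maximum(1.0 - a**2, _CLAMP)
        safe_a = _safe_denominator(a)
        p1 = (R - np.outer(a, a)) / np.sqrt(np.outer(da, da))          # r_xy.z
        p2 = (a[:, None] - R * a[None, :]) / np.sqrt(dR * da[None, :])  # r_xz.y
        p3 = (a[None, :] - R * a[:, None]) / np.sqrt(dR * da[:, None])  # r_yz.x
        eps = (p1 / safe_R + p2 / safe_a[:, None] + p3 / safe_a[None, :]) / 3.0
        discard = (absR <= np.abs(eps * a[:, None])) & (absR <= np.abs(eps * a[None, :]))
        discard[z, :] = False
        discard[:, z] = False
        np.fill_diagonal(discard, False)
        newly = discard & (eliminator == -1)
        eliminator[newly] = z
        significant &= ~discard
    decisions = []
    for x in range(p):
        for y in range(x + 1, p):
            z = int(eliminator[x, y])
            decisions.append(
                PcitDecision(
                    var_x=nm[x],
                    var_y=nm[y],
                    r_xy=float(R[x, y]),
                    significant=bool(significant[x, y]),
                    eliminating_z=nm[z] if z >= 0 else None,
                    trios_evaluated=p - 2,
                )
            )
    return decisions


def pcit_brute_oracle(
    matrix: CorrelationMatrix | np.ndarray,
    names: Sequence[str] | None = None,
) -> list[PcitDecision]:
    """Literal, unoptimized transcription of the elimination rule.

    A scalar triple loop over (x, y, z) writing out the partial-correlation
    and tolerance formulas inline.  Exists solely as an independent reference
    for equivalence testing against :func:`pcit_edge_decisions`.
    """
    R, nm = _matrix_and_names(matrix, names)
    p = R.shape[0]

    def clamp_den(v: float) -> float:
        return math.copysign(max(abs(v), _CLAMP), v if v != 0 else 1.0)

    decisions = []
    for x in range(p):
        for y in range(x + 1, p):
            r_xy = R[x, y]
            significant = True
            eliminating = None
            for z in range(p):
                if z == x or z == y:
                    continue
                r_xz = R[x, z]
                r_yz = R[y, z]
                d1 = math.sqrt(max(1 - r_xz * r_xz, _CLAMP) * max(1 - r_yz * r_yz, _CLAMP))
                d2 = math.sqrt(max(1 - r_xy * r_xy, _CLAMP) * max(1 - r_yz * r_yz, _CLAMP))
                d3 = math.sqrt(max(1 - r_xy * r_xy, _CLAMP) * max(1 - r_xz * r_xz, _CLAMP))
                r_xy_z = (r_xy - r_xz * r_yz) / d1
                r_xz_y = (r_xz - r_xy * r_yz) / d2
                r_yz_x = (r_yz - r_xy * r_xz) / d3
                eps = (
                    r_xy_z / clamp_den(r_xy)
                    + r_xz_y / clamp_den(r_xz)
                    + r_yz_x / clamp_den(r_yz)
                ) / 3.0
                if abs(r_xy) <= abs(eps * r_xz) and abs(r_xy) <= abs(eps * r_yz):
                    significant = False
                    if eliminating is None:
                        eliminating = nm[z]
            decisions.append(
                PcitDecision(nm[x], nm[y], float(r_xy), significant, eliminating, p - 2)
            )
    return decisions


def decisions_to_frame(decisions: Sequence[PcitDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "var1": d.var_x,
                "var2": d.var_y,
                "r": d.r_xy,
                "significant": d.significant,
                "eliminating_z": d.eliminating_z or "",
            }
            for d in decisions
        ],
        columns=["var1", "var2", "r", "significant", "eliminating_z"],
    )


def frame_to_decisions(df: pd.DataFrame) -> list[PcitDecision]:
    out = []
    for row in df.itertuples(index=False):
        elim = getattr(row, "eliminating_z", "")
        if isinstance(elim, float) and np.isnan(elim):
            elim = ""
        sig = row.significant
        if isinstance(sig, str):
            sig = sig.lower() == "true"
        out.append(
            PcitDecision(
                str(row.var1), str(row.var2), float(row.r), bool(sig),
                str(elim) or None, getattr(row, "trios_evaluated", -1),
            )
        )
    return out
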