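"""SIA, back-calculated actual corneal astigmatism, and prediction error.

The analysis back-computes each eye's "actual" preoperative corneal
astigmatism from postoperative observables, all expressed at the corneal
plane:

* **SIA** (surgically induced astigmatism): vector difference between the
  postoperative and preoperative total corneal astigmatism measured with
  the same analysis mode.
* **Actual corneal astigmatism**: signed double-angle composition of the
  corneal-plane residual astigmatism, the SIA and the effective toric IOL
  cylinder (oriented at the recorded postoperative IOL axis).  The default
  signs (+1, −1, +1) are the optically consistent back-solve
  (preop = postop − SIA, with postop = residual + toric correction); the
  literal unsigned-sum composition (+1, +1, +1) is selectable for fidelity
  comparisons but does not close the noiseless pipeline when SIA ≠ 0 — a
  discrepancy surfaced via :func:`composition_closes`.
* **Prediction error**: vector difference between the actual astigmatism
  and the preoperative measurement of one analysis mode; summarized per
  mode as mean ± SD and median (IQR) of the absolute error plus the
  centroid error.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import (
    Astigmatism,
    absolute_error_stats,
    centroid,
    vector_add,
    vector_diff,
    negate,
)
from .modes import ALL_MODES, ModeSpec

__all__ = [
    "SIGNS_CONSISTENT",
    "SIGNS_LITERAL",
    "OutcomeDecomposition",
    "compute_sia",
    "actual_corneal_astigmatism",
    "prediction_error",
    "summarize_modes",
    "composition_closes",
]

#: Optically consistent composition: residual − SIA + toric.
SIGNS_CONSISTENT: tuple[int, int, int] = (1, -1, 1)
#: Literal unsigned "vector sum": residual + SIA + toric.
SIGNS_LITERAL: tuple[int, int, int] = (1, 1, 1)


@dataclass(frozen=True)
class OutcomeDecomposition:
    """Per-eye vector decomposition feeding the prediction error."""

    residual_corneal: Astigmatism
    sia: Astigmatism
    toric_effective: Astigmatism
    actual: Astigmatism
    signs: tuple[int, int, int] = SIGNS_CONSISTENT


def compute_sia(pre_total: Astigmatism, post_total: Astigmatism) -> Astigmatism:
    """Vector difference postop − preop total corneal astigmatism."""
    return vector_diff(post_total, pre_total)


def _signed(a: Astigmatism, sign: int) -> Astigmatism:
    if sign == 1:
        return a
    if sign == -1:
        return negate(a)
    raise ValueError(f"composition signs must be ±1, got {sign}")


def actual_corneal_astigmatism(
    residual_corneal: Astigmatism,
    sia: Astigmatism,
    toric_effective: Astigmatism,
    signs: tuple[int, int, int] = SIGNS_CONSISTENT,
) -> Astigmatism:
    """Signed double-angle sum s_r·residual + s_sia·SIA + s_t·toric.

    ``toric_effective`` must already be oriented at the recorded
    postoperative IOL axis and expressed at the corneal plane.
    """
    s_r, s_s, s_t = signs
    out = vector_add(_signed(residual_corneal, s_r), _signed(sia, s_s))
    return vector_add(out, _signed(toric_effective, s_t))


def prediction_error(actual: Astigmatism, measured: Astigmatism) -> Astigmatism:
    """Vector difference between actual and measured (preop) astigmatism."""
    return vector_diff(actual, measured)


def decompose(
    residual_corneal: Astigmatism,
    sia: Astigmatism,
    toric_effective: Astigmatism,
    signs: tuple[int, int, int] = SIGNS_CONSISTENT,
) -> OutcomeDecomposition:
    return OutcomeDecomposition(
        residual_corneal=residual_corneal,
        sia=sia,
        toric_effective=toric_effective,
        actual=actual_corneal_astigmatism(residual_corneal, sia, toric_effective, signs),
        signs=signs,
    )


def composition_closes(
    truth_preop: Astigmatism,
    decomp: OutcomeDecomposition,
    tol: float = 1e-6,
) -> bool:
    """Does the composition recover the known preop truth to ``tol`` D?

    Diagnostic for the sign-configuration audit: the literal (+,+,+)
    composition fails this whenever SIA ≠ 0.
    """
    return prediction_error(decomp.actual, truth_preop).magnitude <= tol


def summarize_modes(errors: pd.DataFrame) -> pd.DataFrame:
    """Per-mode summary of prediction errors, one row per analysis mode.

    ``errors`` is a long table with columns ``mode`` (the 16 mode keys,
    e.g. ``zone_apex_3mm``), ``error_magnitude`` (D) and ``error_axis``
    (degrees).  Output columns: n, mean, sd, median, q1, q3 of the
    absolute error, and centroid magnitude/axis.
    """
    required = {"mode", "error_magnitude", "error_axis"}
    missing_cols = required - set(errors.columns)
    if missing_cols:
        raise ValueError(f"errors table missing columns: {sorted(missing_cols)}")
    present = set(errors["mode"].unique())
    missing_modes = [m.key for m in ALL_MODES if m.key not in present]
    if missing_modes:
        raise ValueError(f"errors table missing analysis modes: {missing_modes}")

    rows = []
    for spec in ALL_MODES:
        sub = errors.loc[errors["mode"] == spec.key]
        vs = [
            Astigmatism(m, a)
            for m, a in zip(sub["error_magnitude"], sub["error_axis"])
        ]
        stats = absolute_error_stats(vs)
        cent = centroid(vs)
        rows.append(
            {
                "mode": spec.key,
                "geometry": spec.geometry,
                "center": spec.center,
                "diameter_mm": spec.diameter_mm,
                "n": stats.n,
                "abs_mean": stats.mean,
                "abs_sd": stats.sd,
                "abs_median": stats.median,
                "abs_q1": stats.q1,
                "abs_q3": stats.q3,
                "centroid_magnitude": cent.magnitude,
                "centroid_axis": cent.axis,
            }
        )
    return pd.DataFrame(rows)
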