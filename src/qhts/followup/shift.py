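"""Pharmacological IC50-shift analysis.

A competitive antagonist loses apparent potency as the agonist
concentration rises: its inhibition curve shifts right.  Each co-treatment
condition's titration is fitted independently with the 4PL Hill model and
the ratio of the largest to smallest fitted IC50 across conditions is the
fold shift.  A shift strictly greater than 2-fold is called
receptor-dependent antagonism; anything else (including surfactant-like or
cytotoxic false positives, whose curves do not move) is not.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..hillfit import ConcentrationResponse, fit_hill, HillFit

__all__ = ["ShiftResult", "shift_analysis"]

SHIFT_FOLD_THRESHOLD = 2.0


@dataclass(frozen=True)
class ShiftResult:
    compound_id: str
    fits: dict  # condition label -> HillFit
    max_fold_shift: float | None  # None when any fit failed
    pxr_dependent: bool | None  # None = indeterminate
    indeterminate: bool


def shift_analysis(series: dict[str, ConcentrationResponse] | dict[float, ConcentrationResponse]) -> ShiftResult:
    """Fit each co-treatment condition and flag a >2-fold potency shift.

    ``series`` maps a condition label (e.g. agonist concentration in µM) to
    the titration measured under that condition.  Any non-converged fit
    makes the result indeterminate rather than silently passing.
    """
    if len(series) < 2:
        raise ValueError("need at least two co-treatment conditions")
    fits: dict = {}
    cid = None
    for label, cr in series.items():
        cid = cid or cr.compound_id
        fits[label] = fit_hill(cr)
    if any(not f.converged for f in fits.values()):
        return ShiftResult(cid or "", fits, None, None, True)
    ks = [f.k for f in fits.values()]
    fold = max(ks) / min(ks)
    return ShiftResult(cid or "", fits, fold, fold > SHIFT_FOLD_THRESHOLD, False)
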