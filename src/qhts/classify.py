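"""qHTS curve classification, curve rank, and activity calling.

Each fitted titration is placed into a curve class: 1 (complete sigmoid,
both asymptotes observed), 2 (incomplete, lower asymptote only), 3 (a
single concentration shows activity, no curve support), 4 (inactive).
Classes 1 and 2 split into high-quality (.1: efficacy magnitude >= 80% and
r^2 >= 0.9) and lower-quality (.2) subclasses.  The class sign follows the
direction of the response: negative for inhibition.

Class and efficacy combine into a curve rank, an integer score in [-9, 9]
where -9 is a high-quality full-efficacy inhibitor and 0 is inactive.  The
activity outcome joins the antagonist readout with the viability
counter-screen: a compound is *active* only if it is a ranked, efficacious
inhibitor (rank < -1, efficacy < -50%) and either shows no cytotoxicity or
is at least 6-fold more potent in the antagonist readout than in the
viability readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hillfit import NO_FIT, ConcentrationResponse, HillFit, fit_hill

__all__ = [
    "CurveCall",
    "assign_class",
    "curve_rank",
    "activity_outcome",
    "call_compound",
    "call_screen",
    "select_confirmation",
    "select_followup",
    "confirmation_rate",
]

# Subclass quality cut-offs (overridable via keyword arguments).
HIGH_EFF_THRESHOLD = 80.0  # |efficacy| % for the .1 subclass and for top-of-class rank
R2_THRESHOLD = 0.9

# rank magnitudes per |class|: (base, top); top applies at |efficacy| >= HIGH_EFF_THRESHOLD
_RANK_TABLE = {1.1: (8, 9), 1.2: (6, 7), 2.1: (4, 5), 2.2: (2, 3), 3.0: (1, 2), 4.0: (0, 0)}


@dataclass(frozen=True)
class CurveCall:
    """Per-compound classification joining both readouts."""

    compound_id: str
    curve_class: float  # signed: e.g. -1.1 for a high-quality inhibition curve
    curve_rank: int
    efficacy: float
    ic50_um: float
    r_squared: float
    viability_class: float
    viability_ic50_um: float
    potency_separation: float | None  # viability IC50 / activity IC50
    outcome: str  # active | inactive | inconclusive


def assign_class(
    fit: HillFit,
    cr: ConcentrationResponse,
    noise_band: float,
    high_eff_threshold: float = HIGH_EFF_THRESHOLD,
    r2_threshold: float = R2_THRESHOLD,
) -> float:
    """Assign a signed curve class from a fit and its masked series.

    ``noise_band`` is the half-width (in % activity) of the band around 0
    inside which a response is indistinguishable from vehicle noise,
    conventionally 3 SDs of the vehicle-well % activity.
    """
    a = cr.response[cr.mask]
    if a.size == 0:
        return 4.0
    outside = np.abs(a) > noise_band
    n_out = int(outside.sum())
    if n_out == 0:
        return 4.0

    sign = -1.0 if a[outside].mean() < 0 else 1.0
    fit_support = fit.converged and np.isfinite(fit.k) and fit.efficacy != 0
    if n_out == 1 or not fit_support:
        return sign * 3.0
    sign = -1.0 if fit.efficacy < 0 else 1.0

    # asymptote checks against the fitted plateaus at the observed extremes;
    # a claimed upper plateau needs the two highest points on it
    lower_asym = abs(a[0] - fit.a0) <= noise_band
    upper_asym = (
        a.size >= 2
        and abs(a[-1] - fit.a_inf) <= noise_band
        and abs(a[-2] - fit.a_inf) <= noise_band
        and abs(fit.efficacy) > noise_band
    )
    if lower_asym and upper_asym:
        base = 1.0
    elif lower_asym:
        base = 2.0
    else:
        return sign * 3.0
    sub = 0.1 if (abs(fit.efficacy) >= high_eff_threshold and fit.r_squared >= r2_threshold) else 0.2
    return sign * (base + sub)


def curve_rank(curve_class: float, efficacy: float) -> int:
    """Map a signed curve class plus efficacy to the integer rank in [-9, 9].

    Within each class the more efficacious curves get the larger magnitude;
    class 4 is always rank 0; the sign follows the class sign.
    """
    key = round(abs(curve_class), 1)
    if key not in _RANK_TABLE:
        raise ValueError(f"unknown curve class {curve_class}")
    base, top = _RANK_TABLE[key]
    mag = top if abs(efficacy) >= HIGH_EFF_THRESHOLD else base
    if key == 4.0:
        return 0
    return int(np.sign(curve_class) * mag)


def activity_outcome(
    rank: int,
    efficacy: float,
    viability_active: bool,
    potency_separation: float | None,
) -> str:
    """Combine the antagonist call with the viability counter-screen.

    active      : rank < -1 AND efficacy < -50% AND (no cytotoxicity OR the
                  antagonist readout is >= 6-fold more potent than viability)
    inactive    : |rank| < 1
    inconclusive: everything else
    """
    passes_counter = (not viability_active) or (
        potency_separation is not None and potency_separation >= 6.0
    )
    if rank < -1 and efficacy < -50.0 and passes_counter:
        return "active"
    if abs(rank) < 1:
        return "inactive"
    return "inconclusive"


def _maybe_fit(cr: ConcentrationResponse, noise_band: float) -> HillFit:
    # class-4 fast path: a series entirely inside the noise band needs no fit
    a = cr.response[cr.mask]
    if a.size == 0 or np.all(np.abs(a) <= noise_band):
        return NO_FIT
    return fit_hill(cr)


def call_compound(
    activity: ConcentrationResponse,
    viability: ConcentrationResponse | None,
    noise_band: float,
) -> CurveCall:
    """Fit, classify and produce the activity outcome for one compound."""
    afit = _maybe_fit(activity, noise_band)
    acls = assign_class(afit, activity, noise_band)
    arank = curve_rank(acls, afit.efficacy)
    if viability is not None:
        vfit = _maybe_fit(viability, noise_band)
        vcls = assign_class(vfit, viability, noise_band)
        vrank = curve_rank(vcls, vfit.efficacy)
    else:
        vfit, vcls, vrank = NO_FIT, 4.0, 0  # absent counter-screen = viability-inactive
    viability_active = vrank != 0
    sep = None
    if np.isfinite(afit.k) and np.isfinite(vfit.k) and viability_active and abs(acls) != 4.0:
        sep = float(vfit.k / afit.k)
    return CurveCall(
        compound_id=activity.compound_id,
        curve_class=acls,
        curve_rank=arank,
        efficacy=afit.efficacy,
        ic50_um=afit.k,
        r_squared=afit.r_squared,
        viability_class=vcls,
        viability_ic50_um=vfit.k,
        potency_separation=sep,
        outcome=activity_outcome(arank, afit.efficacy, viability_active, sep),
    )


def call_screen(responses: pd.DataFrame, noise_band: float) -> pd.DataFrame:
    """Call every compound in a long-format response table.

    ``responses`` has columns compound_id, readout ('activity'/'viability'),
    concentration_um, percent_activity.  Returns the calls table.
    """
    rows = []
    for cid, grp in responses.groupby("compound_id", sort=True):
        series = {}
        for readout, sub in grp.groupby("readout"):
            sub = sub.sort_values("concentration_um")
            series[readout] = ConcentrationResponse(
                compound_id=str(cid),
                concentration=sub["concentration_um"].to_numpy(),
                response=sub["percent_activity"].to_numpy(),
                readout=str(readout),
            )
        if "activity" not in series:
            continue
        call = call_compound(series["activity"], series.get("viability"), noise_band)
        rows.append(vars(call))
    return pd.DataFrame(rows)


def _toxicity_ok(calls: pd.DataFrame) -> pd.Series:
    no_tox = calls["viability_class"].abs() == 4.0
    sep = calls["potency_separation"].astype(float)
    return no_tox | (sep.notna() & (sep >= 6.0))


def select_confirmation(calls: pd.DataFrame, extra_ids: list[str] | None = None) -> list[str]:
    """Confirmation-screen pick: E < -50%, IC50 < 10 µM, no apparent toxicity
    (viability-inactive or >= 6-fold potency separation).  ``extra_ids``
    appends explicitly chosen compounds such as negative controls."""
    m = (calls["efficacy"] < -50.0) & (calls["ic50_um"] < 10.0) & _toxicity_ok(calls)
    ids = calls.loc[m, "compound_id"].tolist()
    for e in extra_ids or []:
        if e not in ids:
            ids.append(e)
    return ids


def select_followup(calls: pd.DataFrame) -> list[str]:
    """Follow-up pick with the tighter efficacy bound: E < -75%, IC50 < 10 µM,
    and no toxicity."""
    m = (calls["efficacy"] < -75.0) & (calls["ic50_um"] < 10.0) & _toxicity_ok(calls)
    return calls.loc[m, "compound_id"].tolist()


def confirmation_rate(primary_actives: int, confirmed: int) -> float:
    """Percent of primary actives that reconfirmed, to one decimal."""
    if primary_actives <= 0:
        raise ValueError("primary_actives must be positive")
    if confirmed > primary_actives:
        raise ValueError("confirmed cannot exceed primary_actives")
    return round(100.0 * confirmed / primary_actives, 1)
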