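"""Plate normalization, DMSO-plate pattern correction, and plate QC.

Raw signals are converted to % activity with vehicle wells at 0% and the
full-effect positive control at -100%:

    % activity = (V_compound - V_DMSO) / (V_DMSO - V_pos) * 100

where V_DMSO and V_pos are the *medians* of the vehicle and positive
control wells.  The luminescence channel is normalized against the
antagonist positive control; the fluorescence (viability) channel against
the cytotoxicity control.  Plate quality is summarized by the vehicle-well
CV, the signal-to-background ratio, and the Z'-factor, all on raw signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import VEHICLE_COLS, PlateRead

__all__ = [
    "NormalizedPlate",
    "PlateQC",
    "percent_activity",
    "normalize_plate",
    "pattern_correct",
    "plate_qc",
    "responses_from_plates",
]


@dataclass
class NormalizedPlate:
    """A plate in % units: percent_activity (reporter) and percent_viability."""

    plate_id: str
    wells: pd.DataFrame  # adds percent_activity, percent_viability columns
    v_dmso: float  # median vehicle luminescence
    v_pos: float  # median positive-control luminescence

    def copy(self) -> "NormalizedPlate":
        return NormalizedPlate(self.plate_id, self.wells.copy(), self.v_dmso, self.v_pos)


@dataclass(frozen=True)
class PlateQC:
    cv: float  # vehicle-well CV, %
    s_b: float  # signal-to-background ratio
    z_prime: float


def percent_activity(v_compound, v_dmso: float, v_pos: float):
    """Normalize a signal to the 0%/-100% control scale.

    Vehicle (v_dmso) maps to 0 and the positive control (v_pos) to -100.
    Raises on degenerate controls (v_dmso == v_pos).
    """
    if v_dmso == v_pos:
        raise ValueError("degenerate controls: vehicle and positive medians coincide")
    return (np.asarray(v_compound, dtype=float) - v_dmso) / (v_dmso - v_pos) * 100.0


def normalize_plate(plate: PlateRead) -> NormalizedPlate:
    """Convert both channels of a raw plate to % scale using control medians."""
    w = plate.wells
    veh = w.loc[w["role"] == "vehicle_control"]
    if not (w["role"] == "compound").any():
        # DMSO-only plate: anchor on the designated vehicle columns so the
        # compound field carries any background pattern instead of setting
        # the baseline
        veh = veh.loc[veh["col"].isin(VEHICLE_COLS)]
    pos = w.loc[w["role"] == "positive_control"]
    cyt = w.loc[w["role"] == "cytotox_control"]
    if len(veh) < 2 or len(pos) < 2:
        raise ValueError(f"plate {plate.plate_id}: need >=2 vehicle and positive-control wells")
    v_dmso = float(veh["lum"].median())
    v_pos = float(pos["lum"].median())
    out = w.copy()
    out["percent_activity"] = percent_activity(w["lum"].to_numpy(), v_dmso, v_pos)
    f_dmso = float(veh["fluor"].median())
    # viability scale: dead cytotox-control wells define -100%
    f_dead = float(cyt["fluor"].median()) if len(cyt) >= 2 else 0.0
    out["percent_viability"] = percent_activity(w["fluor"].to_numpy(), f_dmso, f_dead)
    empty = (out["role"] == "empty").to_numpy()
    out.loc[empty, ["percent_activity", "percent_viability"]] = np.nan
    return NormalizedPlate(plate.plate_id, out, v_dmso, v_pos)


def pattern_correct(
    plates: list[NormalizedPlate], dmso_plates: list[NormalizedPlate]
) -> list[NormalizedPlate]:
    """Subtract the per-well median background of DMSO-only plates.

    The DMSO-only plates flanking the compound stack estimate any spatial
    pattern on the normalized-activity scale; their per-well median is
    removed from every compound plate at the same well position.
    """
    if not dmso_plates:
        raise ValueError("need at least one DMSO-only plate")
    ref = dmso_plates[0].wells[["row", "col"]]
    stacked = []
    for d in dmso_plates:
        w = d.wells
        if not (w["row"].to_numpy() == ref["row"].to_numpy()).all() or not (
            w["col"].to_numpy() == ref["col"].to_numpy()
        ).all():
            raise ValueError("DMSO plate layout mismatch")
        stacked.append(w["percent_activity"].to_numpy())
    background = np.median(np.vstack(stacked), axis=0)
    # only positions reading vehicle on the DMSO plates carry background
    # information; control columns (which hold controls there too) pass through
    is_vehicle = (dmso_plates[0].wells["role"] == "vehicle_control").to_numpy()
    background = np.where(is_vehicle, background, 0.0)
    bg = pd.DataFrame({"row": ref["row"], "col": ref["col"], "bg": background})
    out = []
    for p in plates:
        q = p.copy()
        merged = q.wells.merge(bg, on=["row", "col"], how="left", validate="one_to_one")
        if merged["bg"].isna().any():
            raise ValueError(f"plate {p.plate_id}: layout mismatch with DMSO plates")
        q.wells["percent_activity"] = q.wells["percent_activity"].to_numpy() - merged["bg"].to_numpy()
        out.append(q)
    return out


def plate_qc(plate: PlateRead | NormalizedPlate) -> PlateQC:
    """Plate quality metrics on raw luminescence.

    CV = SD/mean of vehicle wells x100; S/B = mean vehicle / mean positive
    control; Z' = 1 - 3(sigma_pos + sigma_veh)/|mu_veh - mu_pos|.
    """
    w = plate.wells
    veh = w.loc[w["role"] == "vehicle_control", "lum"].to_numpy()
    pos = w.loc[w["role"] == "positive_control", "lum"].to_numpy()
    if len(veh) < 2 or len(pos) < 2:
        raise ValueError("control wells missing")
    mu_v, mu_p = veh.mean(), pos.mean()
    if mu_v == mu_p:
        raise ValueError("degenerate controls")
    sd_v, sd_p = veh.std(ddof=1), pos.std(ddof=1)
    return PlateQC(
        cv=float(sd_v / mu_v * 100.0),
        s_b=float(mu_v / mu_p),
        z_prime=float(1.0 - 3.0 * (sd_p + sd_v) / abs(mu_v - mu_p)),
    )


def qc_table(plates: list[PlateRead | NormalizedPlate]) -> pd.DataFrame:
    rows = [{"plate_id": p.plate_id, **vars(plate_qc(p))} for p in plates]
    return pd.DataFrame(rows)


def responses_from_plates(plates: list[NormalizedPlate]) -> pd.DataFrame:
    """Collect per-compound titration series from normalized plates.

    Returns the long-format table (compound_id, readout, concentration_um,
    percent_activity) consumed by the curve fitter, with one 'activity' and
    one 'viability' series per compound.
    """
    frames = []
    for p in plates:
        w = p.wells
        comp = w.loc[w["role"] == "compound", ["compound_id", "concentration_um", "percent_activity", "percent_viability"]]
        frames.append(comp)
    allw = pd.concat(frames, ignore_index=True)
    act = allw[["compound_id", "concentration_um", "percent_activity"]].copy()
    act["readout"] = "activity"
    via = allw[["compound_id", "concentration_um", "percent_viability"]].rename(
        columns={"percent_viability": "percent_activity"}
    )
    via["readout"] = "viability"
    out = pd.concat([act, via], ignore_index=True)
    return out[["compound_id", "readout", "concentration_um", "percent_activity"]].sort_values(
        ["compound_id", "readout", "concentration_um"], ignore_index=True
    )
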