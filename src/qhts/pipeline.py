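"""End-to-end screen analysis: normalize -> fit -> call -> enrich."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify, enrichment, normalize
from .synthetic import PlateRead, ScreenConfig, generate_dmso_plates, generate_screen

__all__ = ["vehicle_noise_band", "analyze_plates", "run_synthetic_screen"]


def vehicle_noise_band(plates: list[normalize.NormalizedPlate], n_sd: float = 3.0) -> float:
    """Noise band (in % activity) as n_sd SDs of pooled vehicle-well activity."""
    vals = np.concatenate(
        [
            p.wells.loc[p.wells["role"] == "vehicle_control", "percent_activity"].to_numpy()
            for p in plates
        ]
    )
    return float(n_sd * vals.std(ddof=1))


def analyze_plates(
    plates: list[PlateRead],
    dmso_plates: list[PlateRead] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize raw plates (with optional pattern correction) and call compounds.

    Returns (calls table, plate QC table).
    """
    norm = [normalize.normalize_plate(p) for p in plates]
    if dmso_plates:
        norm_dmso = [normalize.normalize_plate(p) for p in dmso_plates]
        norm = normalize.pattern_correct(norm, norm_dmso)
    band = vehicle_noise_band(norm)
    responses = normalize.responses_from_plates(norm)
    calls = classify.call_screen(responses, noise_band=band)
    qc = normalize.qc_table(plates)
    return calls, qc


def run_synthetic_screen(
    config: ScreenConfig, alpha: float = 0.05
) -> dict:
    """Generate a synthetic screen and run the full analysis against its truth.

    Returns a dict with the calls table, QC table, enrichment table (on the
    planted cluster labels), the ground truth, and recall/precision of the
    'active' outcome against planted antagonists.
    """
    plates, truth = generate_screen(config)
    dmso = generate_dmso_plates(config)
    calls, qc = analyze_plates(plates, dmso)
    merged = calls.merge(truth, on="compound_id", how="left")
    is_true = (merged["true_role"] == "antagonist").to_numpy()
    is_called = (merged["outcome"] == "active").to_numpy()
    tp = int((is_true & is_called).sum())
    recall = tp / is_true.sum() if is_true.sum() else float("nan")
    precision = tp / is_called.sum() if is_called.sum() else float("nan")
    flags = pd.DataFrame({"compound_id": merged["compound_id"], "active": is_called})
    enr = enrichment.cluster_enrichment(
        truth[["compound_id", "cluster_id"]], flags, alpha=alpha
    )
    return {
        "calls": calls,
        "qc": qc,
        "enrichment": enr,
        "truth": truth,
        "recall": float(recall),
        "precision": float(precision),
    }
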