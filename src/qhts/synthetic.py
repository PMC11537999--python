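"""Synthetic 1536-well antagonist-screen generator.

Emulates a cell-based reporter screen read out in two channels: a
luminescence (reporter activity) channel and a fluorescence (cell
viability) channel.  Each plate carries vehicle (DMSO) control wells, a
full-inhibition positive-control column, a cytotoxicity control column and
compound wells.  Compounds are titrated across plates: one plate per
concentration of a geometric dilution series, the same well holding the
same compound at every level (the standard qHTS inter-plate titration).

Planted ground truth (which compounds are antagonists, which are
cytotoxic, their potencies and efficacies, and structural cluster labels)
is returned alongside the plates so downstream stages can be scored
against it.

Noise is multiplicative Gaussian per well, consistent with plate quality
being quoted as a coefficient of variation.  Cytotoxicity couples into the
luminescence channel: a dying well loses reporter signal in proportion to
its viability, which is what makes the potency-separation rule of the
counter-screen meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hillfit import ConcentrationResponse

__all__ = [
    "ScreenConfig",
    "PlateRead",
    "generate_screen",
    "generate_dmso_plates",
    "inject_spatial_artifact",
    "simulate_titration",
    "plate_concentrations",
    "POSITIVE_CONTROL_IC50_UM",
    "POSITIVE_CONTROL_HILL_N",
]

# Ground truth for the positive-control antagonist titration (SPA70-like):
# full-inhibition reference with sub-micromolar potency.
POSITIVE_CONTROL_IC50_UM = 0.169
POSITIVE_CONTROL_HILL_N = 1.2

# Raw-signal scale (arbitrary instrument units).
LUM_VEHICLE_MEAN = 10_000.0
FLUOR_VEHICLE_MEAN = 5_000.0
FLUOR_SIGNAL_TO_BACKGROUND = 10.0

N_ROWS, N_COLS = 32, 48
VEHICLE_COLS = (0, 1)
POSITIVE_COL = 2
CYTOTOX_COL = 3
FIRST_COMPOUND_COL = 4


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of the emulated screen.

    Defaults reproduce the plate statistics of the assay being modeled:
    vehicle-well CV 7.04%, signal-to-background 3.54, and a positive-control
    CV derived so that the Z'-factor identity gives 0.572.  The dilution
    series is exactly geometric between the printed endpoints (46 µM down
    to 1.5 nM in 7 points, ~5.6-fold spacing).
    """

    n_compounds: int = 1408
    n_concentrations: int = 7
    conc_top: float = 46.0  # µM
    conc_bottom: float = 0.0015  # µM
    plate_format: int = 1536
    dmso_cv: float = 0.0704
    signal_to_background: float = 3.54
    pos_control_cv: float | None = None  # derived from z_prime_target if None
    z_prime_target: float = 0.572
    fraction_true_antagonists: float = 0.05
    fraction_cytotoxic: float = 0.03
    spatial_artifact_amplitude: float = 0.0
    n_clusters: int = 50
    n_enriched_clusters: int = 2
    enriched_cluster_weight: float = 0.6
    rng_seed: int = 0

    def __post_init__(self):
        if not self.conc_top > self.conc_bottom > 0:
            raise ValueError("need conc_top > conc_bottom > 0")
        if self.n_concentrations < 2:
            raise ValueError("need at least 2 concentrations")
        for name in ("dmso_cv", "fraction_true_antagonists", "fraction_cytotoxic"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.plate_format != N_ROWS * N_COLS:
            raise ValueError("only the 1536-well (32x48) format is supported")

    @property
    def derived_pos_control_cv(self) -> float:
        """Positive-control CV solving the Z' identity.

        Z' = 1 - 3(sigma_pos + sigma_veh)/|mu_veh - mu_pos| with
        mu_veh/mu_pos = S/B fixes sigma_pos once Z', S/B and the vehicle CV
        are chosen; expressed as a CV of the positive-control mean.
        """
        if self.pos_control_cv is not None:
            return self.pos_control_cv
        sb = self.signal_to_background
        sigma = (1.0 - self.z_prime_target) * (sb - 1.0) / 3.0 - self.dmso_cv * sb
        if sigma <= 0:
            raise ValueError("z_prime_target unreachable at this dmso_cv and S/B")
        return sigma


@dataclass
class PlateRead:
    """One raw plate: well table with roles, compound ids and both channels."""

    plate_id: str
    wells: pd.DataFrame  # row, col, role, compound_id, concentration_um, lum, fluor

    def copy(self) -> "PlateRead":
        return PlateRead(self.plate_id, self.wells.copy())


def plate_concentrations(config: ScreenConfig) -> np.ndarray:
    """The geometric dilution series, low to high, in µM."""
    return np.geomspace(config.conc_bottom, config.conc_top, config.n_concentrations)


def _hill_response(c, ic50, efficacy, n):
    """Noise-free % response at concentration c (baseline 0)."""
    c = np.asarray(c, dtype=float)
    return efficacy * c**n / (ic50**n + c**n)


def _sample_truth(config: ScreenConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_compounds
    ids = [f"C{i:05d}" for i in range(n)]
    n_ant = int(round(config.fraction_true_antagonists * n))
    n_cyt = int(round(config.fraction_cytotoxic * n))
    if n_ant + n_cyt > n:
        raise ValueError("antagonist and cytotoxic fractions exceed the library")
    role = np.array(["inactive"] * n, dtype=object)
    perm = rng.permutation(n)
    ant_idx, cyt_idx = perm[:n_ant], perm[n_ant : n_ant + n_cyt]
    role[ant_idx] = "antagonist"
    role[cyt_idx] = "cytotoxic"

    true_ic50 = np.full(n, np.nan)
    true_eff = np.zeros(n)
    true_n = np.ones(n)
    cyto_ic50 = np.full(n, np.nan)
    true_ic50[ant_idx] = np.exp(rng.uniform(np.log(0.01), np.log(5.0), n_ant))
    true_eff[ant_idx] = rng.uniform(-100.0, -70.0, n_ant)
    true_n[ant_idx] = rng.uniform(0.8, 2.5, n_ant)
    cyto_ic50[cyt_idx] = np.exp(rng.uniform(np.log(1.0), np.log(20.0), n_cyt))

    # Structural clusters: planted actives pile into a few clusters so that
    # enrichment is genuinely present; everything else is uniform.
    k, ke, w = config.n_clusters, config.n_enriched_clusters, config.enriched_cluster_weight
    cluster = rng.integers(0, k, n)
    if ke > 0:
        enriched = rng.random(n_ant) < w
        cluster[ant_idx[enriched]] = rng.integers(0, ke, int(enriched.sum()))
    return pd.DataFrame(
        {
            "compound_id": ids,
            "true_role": role,
            "true_ic50": true_ic50,
            "true_efficacy": true_eff,
            "true_hill_n": true_n,
            "cytotoxic_ic50": cyto_ic50,
            "cluster_id": [f"k{c}" for c in cluster],
        }
    )


def _layout_frame() -> pd.DataFrame:
    rows, cols = np.divmod(np.arange(N_ROWS * N_COLS), N_COLS)
    role = np.array(["compound"] * (N_ROWS * N_COLS), dtype=object)
    role[np.isin(cols, VEHICLE_COLS)] = "vehicle_control"
    role[cols == POSITIVE_COL] = "positive_control"
    role[cols == CYTOTOX_COL] = "cytotox_control"
    return pd.DataFrame({"row": rows, "col": cols, "role": role})


def _noisy(mean, cv, rng):
    return mean * (1.0 + rng.normal(0.0, cv, np.shape(mean)))


def _fill_plate(config, rng, layout, compound_ids, conc, truth_lookup) -> pd.DataFrame:
    """One plate at a single concentration level of the titration."""
    df = layout.copy()
    mu_veh = LUM_VEHICLE_MEAN
    mu_pos = mu_veh / config.signal_to_background
    phi_veh = FLUOR_VEHICLE_MEAN
    phi_pos = phi_veh / FLUOR_SIGNAL_TO_BACKGROUND

    df["compound_id"] = None
    df["concentration_um"] = np.nan
    lum_mean = np.full(len(df), mu_veh)
    fluor_mean = np.full(len(df), phi_veh)

    is_pos = (df["role"] == "positive_control").to_numpy()
    is_cyt = (df["role"] == "cytotox_control").to_numpy()
    lum_mean[is_pos] = mu_pos
    fluor_mean[is_cyt] = phi_pos
    # a dead cytotox-control well also loses reporter signal
    lum_mean[is_cyt] = mu_pos

    comp_all = np.flatnonzero((df["role"] == "compound").to_numpy())
    if len(compound_ids) > len(comp_all):
        raise ValueError("plate too small for the requested compounds")
    comp_wells = comp_all[: len(compound_ids)]
    df.iloc[comp_all[len(compound_ids) :], df.columns.get_loc("role")] = "empty"

    act = np.zeros(len(comp_wells))
    via = np.zeros(len(comp_wells))
    for j, cid in enumerate(compound_ids):
        t = truth_lookup[cid]
        if t["true_role"] == "antagonist":
            act[j] = _hill_response(conc, t["true_ic50"], t["true_efficacy"], t["true_hill_n"])
        if np.isfinite(t["cytotoxic_ic50"]):
            via[j] = _hill_response(conc, t["cytotoxic_ic50"], -100.0, 1.5)
    viability_frac = 1.0 + via / 100.0
    lum_mean[comp_wells] = (mu_veh + act / 100.0 * (mu_veh - mu_pos)) * viability_frac
    fluor_mean[comp_wells] = phi_veh + via / 100.0 * (phi_veh - phi_pos)

    df.iloc[comp_wells, df.columns.get_loc("compound_id")] = list(compound_ids)
    df.iloc[comp_wells, df.columns.get_loc("concentration_um")] = conc

    lum = _noisy(lum_mean, config.dmso_cv, rng)
    lum[is_pos] = _noisy(lum_mean[is_pos], config.derived_pos_control_cv, rng)
    lum[is_cyt] = _noisy(lum_mean[is_cyt], config.derived_pos_control_cv, rng)
    fluor = _noisy(fluor_mean, config.dmso_cv, rng)
    df["lum"] = lum
    df["fluor"] = fluor
    empty = (df["role"] == "empty").to_numpy()
    df.loc[empty, ["lum", "fluor"]] = 0.0
    return df


def generate_screen(config: ScreenConfig) -> tuple[list[PlateRead], pd.DataFrame]:
    """Generate the full screen: titration plates plus a ground-truth table.

    Compounds are packed into plate stacks of up to 1408 compound wells;
    each stack yields one plate per concentration.  Deterministic for a
    fixed ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    truth = _sample_truth(config, rng)
    truth_lookup = truth.set_index("compound_id").to_dict("index")
    layout = _layout_frame()
    n_comp_wells = int((layout["role"] == "compound").sum())
    concs = plate_concentrations(config)

    plates: list[PlateRead] = []
    ids = truth["compound_id"].tolist()
    for stack, start in enumerate(range(0, len(ids), n_comp_wells)):
        chunk = ids[start : start + n_comp_wells]
        for level, conc in enumerate(concs):
            wells = _fill_plate(config, rng, layout, chunk, conc, truth_lookup)
            wells.insert(0, "plate_id", f"S{stack}_L{level}")
            plates.append(PlateRead(f"S{stack}_L{level}", wells))
    return plates, truth


def generate_dmso_plates(config: ScreenConfig, n_plates: int = 2, seed: int | None = None) -> list[PlateRead]:
    """DMSO-only plates (every non-control well holds vehicle) for pattern correction."""
    rng = np.random.default_rng(config.rng_seed + 7_000_001 if seed is None else seed)
    layout = _layout_frame()
    plates = []
    for i in range(n_plates):
        df = layout.copy()
        df.loc[df["role"] == "compound", "role"] = "vehicle_control"
        mu_veh = LUM_VEHICLE_MEAN
        mu_pos = mu_veh / config.signal_to_background
        lum_mean = np.where(df["role"] == "vehicle_control", mu_veh, mu_pos)
        cv = np.where(df["role"] == "vehicle_control", config.dmso_cv, config.derived_pos_control_cv)
        df["compound_id"] = None
        df["concentration_um"] = np.nan
        df["lum"] = lum_mean * (1.0 + rng.normal(0.0, 1.0, len(df)) * cv)
        df["fluor"] = _noisy(np.full(len(df), FLUOR_VEHICLE_MEAN), config.dmso_cv, rng)
        df.loc[df["role"] == "cytotox_control", "fluor"] = _noisy(
            np.full(int((df["role"] == "cytotox_control").sum()), FLUOR_VEHICLE_MEAN / FLUOR_SIGNAL_TO_BACKGROUND),
            config.derived_pos_control_cv,
            rng,
        )
        df.insert(0, "plate_id", f"DMSO_{i}")
        plates.append(PlateRead(f"DMSO_{i}", df))
    return plates


def inject_spatial_artifact(plates: list[PlateRead], pattern: np.ndarray) -> list[PlateRead]:
    """Add a per-well offset (raw luminescence units) to every plate.

    ``pattern`` must be an (n_rows, n_cols) array.  The inputs are left
    unmodified; offset copies are returned.
    """
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != (N_ROWS, N_COLS):
        raise ValueError(f"pattern must have shape {(N_ROWS, N_COLS)}")
    out = []
    for p in plates:
        q = p.copy()
        offs = pattern[q.wells["row"].to_numpy(), q.wells["col"].to_numpy()]
        live = (q.wells["role"] != "empty").to_numpy()
        q.wells.loc[live, "lum"] = q.wells.loc[live, "lum"] + offs[live]
        out.append(q)
    return out


def simulate_titration(
    config: ScreenConfig,
    rng: np.random.Generator,
    ic50: float = POSITIVE_CONTROL_IC50_UM,
    efficacy: float = -100.0,
    hill_n: float = POSITIVE_CONTROL_HILL_N,
    compound_id: str = "POSCTRL",
) -> ConcentrationResponse:
    """One noisy % activity titration series at the configured noise level.

    The noise-free response is pushed through the raw-signal model
    (multiplicative CV on the well signal) and re-normalized, mirroring
    what plate normalization does to a real titration.
    """
    concs = plate_concentrations(config)
    act = _hill_response(concs, ic50, efficacy, hill_n)
    mu_veh = LUM_VEHICLE_MEAN
    mu_pos = mu_veh / config.signal_to_background
    lum = _noisy(mu_veh + act / 100.0 * (mu_veh - mu_pos), config.dmso_cv, rng)
    pct = (lum - mu_veh) / (mu_veh - mu_pos) * 100.0
    return ConcentrationResponse(compound_id=compound_id, concentration=concs, response=pct)


def write_plates(plates: list[PlateRead], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for p in plates:
        p.wells.to_csv(out_dir / f"{p.plate_id}.csv", index=False)


def read_plates(in_dir: str | Path) -> list[PlateRead]:
    plates = []
    for f in sorted(Path(in_dir).glob("*.csv")):
        wells = pd.read_csv(f)
        plates.append(PlateRead(str(wells["plate_id"].iloc[0]), wells))
    return plates
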