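"""qPCR relative-quantification (2^-ΔΔCt) and many-to-one group testing.

Fold change of a target transcript relative to a housekeeping gene and a
control group:

    ΔCt   = Ct_target - Ct_housekeeping          (per sample)
    ΔΔCt  = ΔCt_treated - ΔCt_control
    fold  = 2^(-ΔΔCt)

Fold is computed per replicate and then summarized (mean ± SD of the
replicate folds), not by error propagation on mean Ct.  Group differences
are assessed by one-way ANOVA followed by Dunnett's many-to-one
comparisons against the control, with the conventional star labels at
p < 0.05 (*), p < 0.01 (**), p < 0.001 (***).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ddct_fold", "fold_table", "dunnett_anova", "stars"]


def ddct_fold(
    ct_target_treated: float,
    ct_house_treated: float,
    ct_target_control: float,
    ct_house_control: float,
) -> float:
    """Fold change 2^-ΔΔCt from four cycle-threshold values."""
    ddct = (ct_target_treated - ct_house_treated) - (ct_target_control - ct_house_control)
    return float(2.0 ** (-ddct))


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def fold_table(
    records: pd.DataFrame,
    control_group: str,
    target_gene: str,
    housekeeping_gene: str,
) -> pd.DataFrame:
    """Per-replicate fold changes from a long Ct table.

    ``records`` has columns group, gene, replicate, ct.  The control ΔCt is
    the mean ΔCt of the control group's replicates; each replicate of every
    group (including the control) then gets fold = 2^-(ΔCt - ΔCt_control),
    so the control group's folds scatter around 1.
    """
    need = {"group", "gene", "replicate", "ct"}
    if not need <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(need)}")
    wide = records.pivot_table(index=["group", "replicate"], columns="gene", values="ct").reset_index()
    for g in (target_gene, housekeeping_gene):
        if g not in wide.columns:
            raise ValueError(f"gene {g!r} missing from records")
    wide["delta_ct"] = wide[target_gene] - wide[housekeeping_gene]
    ctrl = wide.loc[wide["group"] == control_group, "delta_ct"]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} not found")
    ref = float(ctrl.mean())
    wide["delta_delta_ct"] = wide["delta_ct"] - ref
    wide["fold"] = 2.0 ** (-wide["delta_delta_ct"])
    return wide[["group", "replicate", "delta_ct", "delta_delta_ct", "fold"]]


def dunnett_anova(
    groups: dict[str, np.ndarray], control: str, random_state: int | None = 0
) -> pd.DataFrame:
    """One-way ANOVA plus Dunnett's test of every group against the control.

    ``groups`` maps group label -> replicate values (e.g. fold changes).
    Returns one row per non-control group with the Dunnett-adjusted
    two-sided p-value and its star label; the ANOVA F and p are attached
    as DataFrame attrs.
    """
    labels = [g for g in groups if g != control]
    if control not in groups or not labels:
        raise ValueError("need a control group and at least one treatment group")
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    ctrl = np.asarray(groups[control], dtype=float)
    if any(len(s) < 2 for s in samples) or len(ctrl) < 2:
        raise ValueError("need >=2 replicates per group")
    pooled = np.concatenate([ctrl] + samples)
    if np.allclose(pooled, pooled[0]):
        raise ValueError("degenerate data: zero variance everywhere")
    f_stat, f_p = stats.f_oneway(ctrl, *samples)
    # the multivariate-t tail probability is evaluated by randomized
    # quadrature; fixing the state keeps reruns identical
    res = stats.dunnett(*samples, control=ctrl, random_state=random_state)
    out = pd.DataFrame(
        {
            "group": labels,
            "statistic": res.statistic,
            "p_value": res.pvalue,
            "significance": [stars(p) for p in res.pvalue],
        }
    )
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(f_p)
    return out
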