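"""Structural clustering and active-antagonist enrichment statistics.

Compounds are grouped into structural clusters — either supplied directly
as labels (e.g. from an external fingerprinting pipeline) or computed here
by a self-organizing map (SOM) over fingerprint vectors — and each cluster
is tested for enrichment of active compounds against the library average
with a one-sided Fisher's exact test on the 2x2 table

    [[actives in cluster, non-actives in cluster],
     [actives elsewhere,  non-actives elsewhere]].

No multiple-testing correction is applied by default; clusters with
p < alpha are flagged as enriched.  An optional Benjamini-Hochberg
correction can be switched on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, false_discovery_control

__all__ = ["cluster_compounds", "cluster_enrichment", "som_fit"]


def som_fit(
    x: np.ndarray,
    grid: tuple[int, int] = (10, 10),
    n_epochs: int = 20,
    seed: int = 0,
    learning_rate: float = 0.5,
    sigma: float | None = None,
) -> np.ndarray:
    """Train a rectangular SOM; returns the (n_units, n_features) codebook.

    Standard online update: units are laid out on a ``grid[0] x grid[1]``
    lattice; for each sample the best-matching unit and its lattice
    neighbourhood move toward the sample, with the learning rate and
    Gaussian neighbourhood radius decaying linearly over epochs.  Fully
    deterministic for a fixed seed.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or len(x) == 0:
        raise ValueError("need a non-empty 2-D sample matrix")
    rng = np.random.default_rng(seed)
    n_units = grid[0] * grid[1]
    gi, gj = np.divmod(np.arange(n_units), grid[1])
    coords = np.column_stack([gi, gj]).astype(float)
    w = x[rng.integers(0, len(x), n_units)] + rng.normal(0, 1e-3, (n_units, x.shape[1]))
    sigma0 = sigma if sigma is not None else max(grid) / 2.0
    total = n_epochs * len(x)
    t = 0
    for _ in range(n_epochs):
        for i in rng.permutation(len(x)):
            frac = t / total
            lr = learning_rate * (1.0 - frac)
            sig = max(sigma0 * (1.0 - frac), 0.5)
            d2 = np.sum((w - x[i]) ** 2, axis=1)
            bmu = int(np.argmin(d2))
            lat2 = np.sum((coords - coords[bmu]) ** 2, axis=1)
            h = np.exp(-lat2 / (2.0 * sig**2))
            w += (lr * h)[:, None] * (x[i] - w)
            t += 1
    return w


def cluster_compounds(
    fingerprints: np.ndarray,
    compound_ids: list[str] | None = None,
    grid: tuple[int, int] = (10, 10),
    seed: int = 0,
    n_epochs: int = 20,
) -> pd.DataFrame:
    """Assign every compound to one SOM grid cell.

    ``fingerprints`` is an (n_compounds, n_bits) array of equal-length
    bit/count vectors.  Returns a table (compound_id, cluster_id) with
    cluster ids ``k<row>.<col>``; cells with no assigned compound are
    simply absent.
    """
    x = np.asarray(fingerprints, dtype=float)
    if x.ndim != 2 or len(x) == 0:
        raise ValueError("empty fingerprint matrix")
    w = som_fit(x, grid=grid, n_epochs=n_epochs, seed=seed)
    d2 = ((x[:, None, :] - w[None, :, :]) ** 2).sum(axis=2) if x.size < 5e6 else None
    if d2 is not None:
        bmu = d2.argmin(axis=1)
    else:  # chunked for large inputs
        bmu = np.empty(len(x), dtype=int)
        for s in range(0, len(x), 1024):
            blk = x[s : s + 1024]
            bmu[s : s + len(blk)] = ((blk[:, None, :] - w[None, :, :]) ** 2).sum(axis=2).argmin(axis=1)
    ri, ci = np.divmod(bmu, grid[1])
    ids = compound_ids if compound_ids is not None else [f"C{i:05d}" for i in range(len(x))]
    return pd.DataFrame({"compound_id": ids, "cluster_id": [f"k{r}.{c}" for r, c in zip(ri, ci)]})


def cluster_enrichment(
    assignments: pd.DataFrame,
    active_flags: pd.DataFrame | dict,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-cluster one-sided Fisher's exact enrichment of actives.

    ``assignments`` maps compound_id -> cluster_id; ``active_flags`` maps
    compound_id -> bool (table with columns compound_id/active, or a dict).
    Every assigned compound must have a flag.
    """
    if isinstance(active_flags, dict):
        flags = pd.Series(active_flags)
    else:
        flags = active_flags.set_index("compound_id")["active"]
    df = assignments.copy()
    missing = ~df["compound_id"].isin(flags.index)
    if missing.any():
        raise ValueError(f"{int(missing.sum())} compounds lack an activity flag")
    df["active"] = flags.loc[df["compound_id"]].to_numpy().astype(bool)

    n_total = len(df)
    n_active = int(df["active"].sum())
    rows = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        m, a = len(grp), int(grp["active"].sum())
        table = [[a, m - a], [n_active - a, (n_total - m) - (n_active - a)]]
        p = float(fisher_exact(table, alternative="greater").pvalue)
        rows.append(
            {
                "cluster_id": cid,
                "n_members": m,
                "n_active": a,
                "library_size": n_total,
                "library_active": n_active,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    pcol = out["p_value"].to_numpy()
    if fdr:
        pcol = false_discovery_control(pcol, method="bh")
        out["p_adjusted"] = pcol
    out["enriched"] = pcol < alpha
    return out
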