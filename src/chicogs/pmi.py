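"""Proxy-based p-value densification ("poor man's imputation").

GWAS studies reporting only genotyped variants leave the reference panel
sparsely covered, which biases fragment-level enrichment comparisons.  PMI
fills each unobserved panel variant with the p-value of its nearest
observed proxy in LD (r² strictly above a threshold, default 0.6); panel
variants with no qualifying proxy are left out, and observed variants that
do not map to the panel are discarded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_model import PairwiseR2

__all__ = ["pmi_impute"]


def pmi_impute(
    observed: pd.DataFrame,
    panel: pd.DataFrame,
    r2: PairwiseR2,
    r2_min: float = 0.6,
    nearest: str = "bp",
) -> pd.DataFrame:
    """Densify observed GWAS p-values onto a reference variant panel.

    Parameters
    ----------
    observed
        GWAS table (variant_id, chrom, pos, p, ...).
    panel
        Reference panel table (variant_id, chrom, pos, ...).
    r2
        Pairwise r² lookup defined between panel variants.
    r2_min
        Strict lower bound on proxy r² (default 0.6).
    nearest
        Proxy choice among qualifying candidates: ``"bp"`` (smallest
        base-pair distance; ties broken by higher r², then lexicographic
        variant id) or ``"r2"`` (highest r²; ties by distance, then id).

    Returns
    -------
    DataFrame in the GWAS dialect with a ``source`` column: ``observed``
    rows are panel-mapped input records (never overwritten), ``pmi`` rows
    carry the proxy's p-value at the panel variant's position.
    """
    if not 0 < r2_min < 1:
        raise ValueError("r2_min must lie in (0, 1)")
    if nearest not in ("bp", "r2"):
        raise ValueError("nearest must be 'bp' or 'r2'")

    panel_ids = set(panel["variant_id"].astype(str))
    obs = observed[observed["variant_id"].astype(str).isin(panel_ids)].copy()
    obs["source"] = "observed"

    obs_index = obs.set_index(obs["variant_id"].astype(str))
    observed_ids = set(obs_index.index)
    missing = panel[~panel["variant_id"].astype(str).isin(observed_ids)]

    imputed_rows = []
    for row in missing.itertuples():
        vid = str(row.variant_id)
        proxies = {
            u: s for u, s in r2.proxies(vid, r2_min=r2_min).items() if u in observed_ids
        }
        if not proxies:
            continue
        items = []
        for u, s in proxies.items():
            dist = abs(int(obs_index.at[u, "pos"]) - int(row.pos))
            items.append((u, s, dist))
        if nearest == "bp":
            items.sort(key=lambda t: (t[2], -t[1], t[0]))
        else:
            items.sort(key=lambda t: (-t[1], t[2], t[0]))
        best = items[0][0]
        src = obs_index.loc[best]
        rec = {c: getattr(row, c, np.nan) for c in ("variant_id", "chrom", "pos")}
        rec["p"] = float(src["p"])
        if "z" in obs.columns:
            rec["z"] = src["z"]
        if "maf" in panel.columns:
            rec["maf"] = getattr(row, "maf", np.nan)
        rec["source"] = "pmi"
        imputed_rows.append(rec)

    if imputed_rows:
        out = pd.concat([obs, pd.DataFrame(imputed_rows)], ignore_index=True)
    else:
        out = obs.reset_index(drop=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
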