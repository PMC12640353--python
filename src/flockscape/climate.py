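"""Breed-level climate change between two periods and its correlation with
per-SNP temporal differentiation.

The climate contract is tabular: per-farm values of each variable in each
of two periods (for yearly records, the within-period median per farm is
taken first, matching the two-twenty-year-median design).  The breed delta
for a variable is the mean over the breed's farms of the farm-level
(period2 - period1) differences.

The scan then asks, SNP by SNP, whether temporal Fst across breeds tracks
the climate shift those breeds experienced: Pearson r between the per-breed
Fst value of the SNP and the per-breed delta of each variable, a two-sided
p-value from the t transform with (breeds used - 2) degrees of freedom, and
BH correction across SNPs within each variable.  Candidate SNPs are those
significant for at least one variable that also sit in the top-Fst set of
at least one breed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import bh_adjust

__all__ = ["breed_climate_delta", "fst_climate_scan"]


def breed_climate_delta(records: pd.DataFrame,
                        period1: str = "period1",
                        period2: str = "period2") -> pd.DataFrame:
    """Breed x variable deltas from per-farm records
    (columns: breed, farm_id, variable, period, value).

    Farms missing either period for a variable are excluded for that
    variable.  Returns breed, variable, mean_period1, mean_period2, delta
    (delta = mean over farms of the farm-level difference of within-period
    medians).
    """
    med = (records.groupby(["breed", "farm_id", "variable", "period"])
           ["value"].median().unstack("period"))
    for p in (period1, period2):
        if p not in med.columns:
            raise ValueError(f"no records for period {p!r}")
    complete = med.dropna(subset=[period1, period2])
    farm_delta = complete[period2] - complete[period1]
    out = complete.assign(_delta=farm_delta).groupby(["breed", "variable"]).agg(
        mean_period1=(period1, "mean"), mean_period2=(period2, "mean"),
        delta=("_delta", "mean")).reset_index()
    return out


def _pearson_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p from the t transform with n-2 df (NaN where undefined)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        df = n - 2
        t = r * np.sqrt(df / np.clip(1.0 - r ** 2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    return np.where(df >= 1, p, np.nan)


def fst_climate_scan(fst_by_breed: pd.DataFrame, deltas: pd.DataFrame,
                     top_fst_sets: dict | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Correlate per-SNP temporal Fst with per-breed climate deltas.

    ``fst_by_breed``: DataFrame indexed by snp_id with one column per breed
    (NaN where the SNP is undefined in that breed — those breeds are
    pairwise-dropped for the SNP).  ``deltas``: output of
    :func:`breed_climate_delta`.  ``top_fst_sets``: breed -> iterable of
    top-Fst snp_ids; when given, the candidate flag additionally requires
    membership in at least one breed's set.

    Returns a long table (snp_id, variable, r, p, p_adj, n_breeds,
    significant, candidate).  Zero-variance Fst or delta vectors give
    undefined r and are excluded from BH.
    """
    breeds = [b for b in fst_by_breed.columns]
    if len(breeds) < 4:
        raise ValueError("need Fst for at least 4 breeds")
    delta_wide = deltas.pivot(index="variable", columns="breed",
                              values="delta")
    common = [b for b in breeds if b in delta_wide.columns]
    if len(common) < 4:
        raise ValueError("need at least 4 breeds with both Fst and deltas")
    F = fst_by_breed[common].to_numpy(dtype=float)        # snps x breeds
    snp_ids = fst_by_breed.index.to_numpy()
    if top_fst_sets is None:
        in_top = np.ones(len(snp_ids), dtype=bool)
    else:
        union = set().union(*map(set, top_fst_sets.values())) \
            if top_fst_sets else set()
        in_top = np.array([s in union for s in snp_ids])

    frames = []
    for var in delta_wide.index:
        d = delta_wide.loc[var, common].to_numpy(dtype=float)
        r = np.full(len(snp_ids), np.nan)
        nb = np.zeros(len(snp_ids))
        for i in range(len(snp_ids)):
            ok = ~np.isnan(F[i]) & ~np.isnan(d)
            if ok.sum() < 3:
                continue
            x, y = F[i, ok], d[ok]
            if x.std() == 0 or y.std() == 0:
                continue
            r[i] = np.corrcoef(x, y)[0, 1]
            nb[i] = ok.sum()
        p = _pearson_p(r, nb)
        defined = ~np.isnan(p)
        p_adj = np.full(len(snp_ids), np.nan)
        if defined.any():
            p_adj[defined] = bh_adjust(p[defined])
        frames.append(pd.DataFrame({
            "snp_id": snp_ids, "variable": var, "r": r, "p": p,
            "p_adj": p_adj, "n_breeds": nb.astype(int),
            "significant": p_adj < alpha}))
    out = pd.concat(frames, ignore_index=True)
    sig_any = out.groupby("snp_id")["significant"].transform("any")
    top_lookup = dict(zip(snp_ids, in_top))
    out["candidate"] = sig_any & out["snp_id"].map(top_lookup).astype(bool)
    return out
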