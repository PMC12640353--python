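"""Panel preparation: call-rate and MAF filters, LD pruning, relative
flagging, IBS-based classical MDS, and k-means breed-size balancing.

Filter order mirrors PLINK's mind/geno/maf sequence: individuals first,
then SNP call rate, then MAF recomputed on the retained samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genio import MISSING, GenotypePanel

__all__ = ["QcParams", "filter_panel", "ld_prune", "flag_relatives",
           "ibs_mds", "balance_breeds"]


@dataclass
class QcParams:
    ind_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.001            # 0.1%
    ld_window_snps: int = 50
    ld_step_snps: int = 10
    ld_r2_max: float = 0.5
    min_breed_n: int = 10
    max_breed_n: int = 30
    opposing_hom_max: float = 0.02    # parent-offspring-like screen
    ibs_dup_min: float = 0.95         # duplicate screen (IBS2 fraction)
    n_mds_dims: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ind_call_rate_min", "snp_call_rate_min", "maf_min",
                     "ld_r2_max", "opposing_hom_max", "ibs_dup_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.ld_window_snps >= self.ld_step_snps >= 1:
            raise ValueError("need ld_window_snps >= ld_step_snps >= 1")


def _obs(genotypes: np.ndarray) -> np.ndarray:
    return genotypes != MISSING


def allele_freq(genotypes: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency per SNP over non-missing calls
    (NaN when all missing)."""
    obs = _obs(genotypes)
    g = np.where(obs, genotypes, 0).astype(float)
    denom = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, g.sum(axis=0) / denom, np.nan)


def minor_allele_freq(genotypes: np.ndarray) -> np.ndarray:
    p = allele_freq(genotypes)
    return np.minimum(p, 1.0 - p)


def filter_panel(panel: GenotypePanel, params: QcParams
                 ) -> tuple[GenotypePanel, pd.DataFrame]:
    """Drop low-call-rate individuals, then low-call-rate SNPs, then
    low-MAF SNPs; returns the filtered panel and a removal report."""
    if panel.n_samples == 0 or panel.n_snps == 0:
        raise ValueError("empty panel")
    report_rows = []
    obs = _obs(panel.genotypes)

    ind_cr = obs.mean(axis=1)
    keep_ind = ind_cr >= params.ind_call_rate_min
    for i in np.flatnonzero(~keep_ind):
        report_rows.append(("sample", panel.samples["sample_id"].iloc[i],
                            "call_rate", ind_cr[i]))
    panel = panel.take_samples(np.flatnonzero(keep_ind))

    obs = _obs(panel.genotypes)
    snp_cr = obs.mean(axis=0) if panel.n_samples else np.zeros(panel.n_snps)
    keep_snp = snp_cr >= params.snp_call_rate_min
    for j in np.flatnonzero(~keep_snp):
        report_rows.append(("snp", panel.snp_map["snp_id"].iloc[j],
                            "call_rate", snp_cr[j]))
    panel = panel.take_snps(np.flatnonzero(keep_snp))

    maf = minor_allele_freq(panel.genotypes)
    keep_maf = ~(maf < params.maf_min)   # NaN (all-missing) already dropped
    for j in np.flatnonzero(~keep_maf):
        report_rows.append(("snp", panel.snp_map["snp_id"].iloc[j],
                            "maf", maf[j]))
    panel = panel.take_snps(np.flatnonzero(keep_maf))

    if panel.n_samples == 0 or panel.n_snps == 0:
        raise ValueError("panel empty after filtering")
    report = pd.DataFrame(report_rows,
                          columns=["kind", "id", "reason", "value"])
    return panel, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, missing calls
    pairwise-deleted; 0 when undefined."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(panel: GenotypePanel, params: QcParams) -> list:
    """Greedy windowed LD pruning (PLINK ``indep-pairwise`` semantics).

    Within each window of ``ld_window_snps`` consecutive retained SNPs on a
    chromosome, while any retained pair has r^2 above the cutoff, the member
    with the lower MAF is removed (tie: the later map position); the window
    then advances by ``ld_step_snps``.  The result depends only on map
    order, not sample order.
    """
    maf = minor_allele_freq(panel.genotypes)
    retained = np.ones(panel.n_snps, dtype=bool)
    chrom = panel.snp_map["chrom"].to_numpy()
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < len(idx):
            window = idx[start:start + params.ld_window_snps]
            live = [j for j in window if retained[j]]
            if len(live) >= 2:
                changed = True
                while changed:
                    changed = False
                    live = [j for j in live if retained[j]]
                    for a in range(len(live)):
                        for b in range(a + 1, len(live)):
                            ja, jb = live[a], live[b]
                            if not (retained[ja] and retained[jb]):
                                continue
                            r2 = _pairwise_r2(panel.genotypes[:, ja],
                                              panel.genotypes[:, jb])
                            if r2 > params.ld_r2_max:
                                if maf[ja] < maf[jb]:
                                    drop = ja
                                elif maf[jb] < maf[ja]:
                                    drop = jb
                                else:
                                    drop = max(ja, jb)  # tie: later position
                                retained[drop] = False
                                changed = True
                    if changed:
                        continue
            start += params.ld_step_snps
    return panel.snp_map["snp_id"].iloc[np.flatnonzero(retained)].tolist()


# ---------------------------------------------------------------------------
# relatives
# ---------------------------------------------------------------------------

def flag_relatives(panel: GenotypePanel, params: QcParams) -> pd.DataFrame:
    """Flag within-breed duplicate and parent-offspring-like pairs.

    Without pedigrees, Mendelian-inconsistency screening reduces to the
    opposing-homozygote rate: a true parent-offspring pair can never be
    homozygous for different alleles at the same locus (barring genotyping
    error), while unrelated pairs are at a rate set by allele frequencies.
    Duplicates are called on the IBS2 fraction.  One member per flagged pair
    is marked for exclusion: the one with more missing calls (tie: the
    second by sample id order).
    """
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples")
    g = panel.genotypes
    obs = _obs(g)
    n_missing = (~obs).sum(axis=1)
    rows = []
    breeds = panel.samples["breed"].to_numpy()
    ids = panel.samples["sample_id"].to_numpy()
    for b in pd.unique(breeds):
        members = np.flatnonzero(breeds == b)
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                i, j = members[ai], members[bi]
                ok = obs[i] & obs[j]
                n_ok = ok.sum()
                if n_ok == 0:
                    continue
                gi, gj = g[i, ok], g[j, ok]
                ibs2 = float((gi == gj).mean())
                opp = float(((gi == 0) & (gj == 2)).sum()
                            + ((gi == 2) & (gj == 0)).sum()) / n_ok
                flag = None
                if ibs2 >= params.ibs_dup_min:
                    flag = "duplicate"
                elif opp <= params.opposing_hom_max:
                    flag = "parent_offspring_like"
                if flag is not None:
                    if n_missing[i] < n_missing[j] or (
                            n_missing[i] == n_missing[j]):
                        keep, excl = ids[i], ids[j]
                    else:
                        keep, excl = ids[j], ids[i]
                    rows.append((ids[i], ids[j], b, flag, ibs2, opp, excl))
    return pd.DataFrame(rows, columns=["id1", "id2", "breed", "flag",
                                       "ibs2_fraction", "opposing_hom_rate",
                                       "exclude"])


# ---------------------------------------------------------------------------
# IBS distances and classical MDS
# ---------------------------------------------------------------------------

def ibs_distance_matrix(panel: GenotypePanel) -> np.ndarray:
    """D_ij = 1 - mean(IBS_ij / 2) over SNPs non-missing in both samples."""
    g = panel.genotypes.astype(float)
    obs = _obs(panel.genotypes)
    n = panel.n_samples
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[i] - g)                    # |gi - gj| in {0,1,2}
        shared = obs[i] & obs
        counts = shared.sum(axis=1)
        if (counts == 0).any():
            j = int(np.flatnonzero(counts == 0)[0])
            if j != i:
                raise ValueError(
                    f"samples {panel.samples['sample_id'].iloc[i]} and "
                    f"{panel.samples['sample_id'].iloc[j]} share no called SNPs")
        ibs = 2.0 - np.where(shared, diff, 0).sum(axis=1) / counts
        D[i] = 1.0 - ibs / 2.0
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def classical_mds(D: np.ndarray, n_dims: int) -> np.ndarray:
    """Classical (Torgerson) MDS: eigendecomposition of the double-centred
    -D^2/2 matrix, dimensions ordered by eigenvalue, first nonzero loading
    of each dimension made positive."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(n_dims, n)
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0.0, None))
    for d in range(coords.shape[1]):
        nz = np.flatnonzero(np.abs(coords[:, d]) > 1e-12)
        if len(nz) and coords[nz[0], d] < 0:
            coords[:, d] = -coords[:, d]
    return coords


def ibs_mds(panel: GenotypePanel, n_dims: int = 10) -> pd.DataFrame:
    """Per-sample classical-MDS coordinates from IBS distances."""
    if panel.n_samples < 3:
        raise ValueError("need at least 3 samples for MDS")
    coords = classical_mds(ibs_distance_matrix(panel), n_dims)
    out = pd.DataFrame(coords,
                       columns=[f"C{d + 1}" for d in range(coords.shape[1])])
    out.insert(0, "sample_id", panel.samples["sample_id"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# breed-size balancing
# ---------------------------------------------------------------------------

def balance_breeds(panel: GenotypePanel, coords: pd.DataFrame,
                   params: QcParams) -> list:
    """Cap breeds at ``max_breed_n`` by k-means on the first 10 MDS
    dimensions (keeping the sample nearest each centroid; tie: smallest id)
    and drop breeds under ``min_breed_n``."""
    coord_cols = [c for c in coords.columns if c.startswith("C")][:10]
    X = coords.set_index("sample_id")[coord_cols]
    retained = []
    for b, grp in panel.samples.groupby("breed", sort=False):
        ids = grp["sample_id"].tolist()
        if len(ids) < params.min_breed_n:
            continue
        if len(ids) <= params.max_breed_n:
            retained.extend(ids)
            continue
        Xb = X.loc[ids].to_numpy()
        km = KMeans(n_clusters=params.max_breed_n, init="k-means++",
                    n_init=50, random_state=params.seed).fit(Xb)
        chosen = set()
        for centroid in km.cluster_centers_:
            d = np.linalg.norm(Xb - centroid, axis=1)
            best = np.flatnonzero(d == d.min())
            # tie -> smallest sample id
            pick = min((ids[i] for i in best))
            chosen.add(pick)
        retained.extend(i for i in ids if i in chosen)
    return retained
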