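"""Per-breed heterozygosity, sliding-window ROH detection (PLINK
semantics), and the McQuillan ROH-based inbreeding coefficient.

ROH detection follows PLINK's ``--homozyg`` algorithm: windows of
``window_snp`` consecutive SNPs slide along each chromosome (only full
windows are formed, as PLINK does); a window is a *hit* for an individual
when it contains at most ``window_het_max`` heterozygous and at most
``window_missing_max`` missing calls; each SNP's hit fraction is the number
of hit windows covering it divided by the windows that cover it at all
(SNPs near chromosome ends are covered by fewer windows and use their
actual coverage as denominator); SNPs with hit fraction above
``snp_hit_fraction`` are in-run; maximal in-run stretches are split where
consecutive SNPs are more than ``max_gap_kb`` apart; and surviving
candidates must contain at least ``min_snp`` SNPs, span at least ``min_kb``
kb, and be no sparser than ``max_kb_per_snp`` kb per SNP.  Segment
coordinates are the outermost in-run SNP positions.

The default parameter block is the chip-density-tuned setting for a ~50k
ovine array: window and minimum run of 49 SNPs, zero hets and up to two
missing calls per window, 1 Mb minimum length, 500 kb maximum gap, 73 kb
per SNP maximum density.

F_ROH divides total ROH length by the SNP-covered autosomal span (sum over
chromosomes of last minus first marker position) — the genome the chip can
actually survey — optionally by total assembly length if supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypePanel

__all__ = ["RohParams", "het_summary", "detect_roh", "froh",
           "DEFAULT_LENGTH_CLASSES_MB"]

#: ROH length classes in Mb: (1-2], (2-4], (4-8], (8-16], >16, with the
#: first bin closed at 1 so every segment >= min_kb is binned.
DEFAULT_LENGTH_CLASSES_MB = (1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass
class RohParams:
    window_snp: int = 49
    window_het_max: int = 0
    window_missing_max: int = 2
    snp_hit_fraction: float = 0.05
    min_snp: int = 49
    min_kb: float = 1000.0
    max_gap_kb: float = 500.0
    max_kb_per_snp: float = 73.0

    def __post_init__(self) -> None:
        if self.min_snp < 1 or self.window_snp < 1:
            raise ValueError("window_snp and min_snp must be >= 1")
        for name in ("snp_hit_fraction", "min_kb", "max_gap_kb",
                     "max_kb_per_snp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def het_summary(panel: GenotypePanel) -> pd.DataFrame:
    """Per-breed observed and expected heterozygosity.

    Per SNP within a breed, Ho is the heterozygote fraction among
    non-missing calls and He = 2 p (1 - p) with p estimated from the same
    calls; breed values are means over the full post-QC SNP universe
    (monomorphic SNPs contribute zeros; SNPs with no calls in a breed are
    skipped for that breed).
    """
    rows = []
    g = panel.genotypes
    for b, grp in panel.samples.groupby("breed", sort=True):
        idx = grp.index.to_numpy()
        sub = g[idx]
        obs = sub != MISSING
        n_obs = obs.sum(axis=0)
        ok = n_obs > 0
        het = ((sub == 1) & obs).sum(axis=0)
        alt = np.where(obs, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = np.where(ok, het / np.maximum(n_obs, 1), np.nan)
            p = np.where(ok, alt / np.maximum(2 * n_obs, 1), np.nan)
        he = 2.0 * p * (1.0 - p)
        rows.append((b, len(idx), float(np.nanmean(ho)), float(np.nanmean(he))))
    return pd.DataFrame(rows, columns=["breed", "n", "ho", "he"])


# ---------------------------------------------------------------------------
# ROH detection
# ---------------------------------------------------------------------------

def _call_chromosome(geno: np.ndarray, bp: np.ndarray,
                     params: RohParams) -> list[tuple[int, int, int]]:
    """ROH calls for one individual on one chromosome; returns
    (start_index, end_index, n_snps) into the chromosome's SNP order."""
    m = len(bp)
    w = params.window_snp
    if m < w:
        return []
    het = geno == 1
    miss = geno == MISSING
    # full windows j..j+w-1 for j in 0..m-w
    cum_het = np.concatenate([[0], np.cumsum(het)])
    cum_mis = np.concatenate([[0], np.cumsum(miss)])
    starts = np.arange(m - w + 1)
    hits = ((cum_het[starts + w] - cum_het[starts] <= params.window_het_max)
            & (cum_mis[starts + w] - cum_mis[starts]
               <= params.window_missing_max))
    # windows covering SNP i start in [max(0, i-w+1), min(i, m-w)]
    lo = np.maximum(0, np.arange(m) - w + 1)
    hi = np.minimum(np.arange(m), m - w)
    cum_hits = np.concatenate([[0], np.cumsum(hits)])
    n_hit = cum_hits[hi + 1] - cum_hits[lo]
    n_cov = hi - lo + 1
    in_run = n_hit / n_cov > params.snp_hit_fraction
    # maximal in-run stretches, split at large gaps
    calls = []
    i = 0
    while i < m:
        if not in_run[i]:
            i += 1
            continue
        j = i
        while (j + 1 < m and in_run[j + 1]
               and (bp[j + 1] - bp[j]) / 1000.0 <= params.max_gap_kb):
            j += 1
        n_snps = j - i + 1
        length_kb = (bp[j] - bp[i] + 1) / 1000.0
        if (n_snps >= params.min_snp and length_kb >= params.min_kb
                and length_kb / n_snps <= params.max_kb_per_snp):
            calls.append((i, j, n_snps))
        i = j + 1
    return calls


def detect_roh(panel: GenotypePanel,
               params: RohParams | None = None) -> pd.DataFrame:
    """Detect runs of homozygosity for every individual.

    Returns a table with PLINK ``.hom``-style columns: sample_id, chrom,
    start_bp, end_bp, n_snps, length_kb.  Chromosomes with fewer SNPs than
    the window produce no calls.
    """
    params = params or RohParams()
    sm = panel.snp_map
    chrom_arr = sm["chrom"].to_numpy()
    bp_arr = sm["bp"].to_numpy()
    rows = []
    for c in np.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == c)
        bp = bp_arr[idx]
        for i in range(panel.n_samples):
            geno = panel.genotypes[i, idx]
            for s, e, n_snps in _call_chromosome(geno, bp, params):
                start, end = int(bp[s]), int(bp[e])
                rows.append((panel.samples["sample_id"].iloc[i], int(c),
                             start, end, n_snps, (end - start + 1) / 1000.0))
    out = pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp",
                                      "end_bp", "n_snps", "length_kb"])
    return out.sort_values(["sample_id", "chrom", "start_bp"],
                           kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# F_ROH
# ---------------------------------------------------------------------------

def covered_autosome_kb(snp_map: pd.DataFrame) -> float:
    """Sum over chromosomes of (last - first marker position), in kb."""
    if snp_map.empty:
        raise ValueError("empty snp map")
    span = snp_map.groupby("chrom")["bp"].agg(["min", "max"])
    return float((span["max"] - span["min"]).sum()) / 1000.0


def froh(segments: pd.DataFrame, snp_map: pd.DataFrame,
         sample_ids=None,
         classes_mb: tuple = DEFAULT_LENGTH_CLASSES_MB,
         genome_kb: float | None = None) -> pd.DataFrame:
    """Per-individual F_ROH, total and by length class (McQuillan: summed
    ROH length over surveyed autosomal length).

    ``classes_mb`` gives ascending class edges; bins are (edge, next] with
    the first bin closed below and the last open above.  ``genome_kb``
    overrides the SNP-covered-span denominator (e.g. assembly length).
    """
    L = genome_kb if genome_kb is not None else covered_autosome_kb(snp_map)
    edges_kb = [e * 1000.0 for e in classes_mb]
    labels = []
    for k, e in enumerate(classes_mb):
        if k + 1 < len(classes_mb):
            labels.append(f"froh_{e:g}_{classes_mb[k + 1]:g}mb")
        else:
            labels.append(f"froh_gt{e:g}mb")

    if sample_ids is None:
        sample_ids = sorted(segments["sample_id"].unique())
    rows = []
    for sid in sample_ids:
        sub = segments[segments["sample_id"] == sid]
        lengths = sub["length_kb"].to_numpy(dtype=float)
        total = lengths.sum() / L
        by_class = []
        for k, lo in enumerate(edges_kb):
            hi = edges_kb[k + 1] if k + 1 < len(edges_kb) else np.inf
            if k == 0:
                mask = (lengths >= lo) & (lengths <= hi)
            else:
                mask = (lengths > lo) & (lengths <= hi)
            by_class.append(lengths[mask].sum() / L)
        rows.append([sid, total, *by_class])
    return pd.DataFrame(rows, columns=["sample_id", "froh_total", *labels])
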