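"""Summaries of local-ancestry dosage matrices for introgressed breeds.

The local-ancestry HMM itself is upstream; this module consumes its
per-individual, per-SNP, per-source dosage output (values in [0, 2] summing
to 2 over sources) and reports: per-SNP mean ancestry proportions per
source, per-individual genome-wide means, the cohort mean +- sd (sample sd
over per-individual means), and the set of highly introgressed SNPs — those
at or above the 99th percentile of a source's per-SNP mean proportion
distribution (genome-wide, ties included).  The flagged set feeds the
annotation module (+-20 kb windows, gene/QTL overlap, enrichment).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import AncestryDosage

__all__ = ["AncestrySummary", "ancestry_summary", "call_high_introgression"]


@dataclass
class AncestrySummary:
    sources: list
    snp_ids: list
    sample_ids: list
    per_snp_mean: pd.DataFrame       # snp_id x source mean proportion
    per_individual_mean: pd.DataFrame  # sample_id x source genome-wide mean
    cohort_mean: pd.Series           # per source
    cohort_sd: pd.Series             # sample sd (n-1) over individuals
    per_snp_sd: pd.DataFrame         # sd across individuals, per SNP


def ancestry_summary(dosage: AncestryDosage) -> AncestrySummary:
    """Mean ancestry proportions at SNP, individual and cohort level."""
    if dosage.dosages.size == 0:
        raise ValueError("empty dosage matrix")
    prop = dosage.dosages / 2.0                       # (n, m, k)
    per_snp = pd.DataFrame(prop.mean(axis=0), index=dosage.snp_ids,
                           columns=dosage.sources)
    per_snp_sd = pd.DataFrame(prop.std(axis=0, ddof=1) if prop.shape[0] > 1
                              else np.zeros(prop.shape[1:]),
                              index=dosage.snp_ids, columns=dosage.sources)
    per_ind = pd.DataFrame(prop.mean(axis=1), index=dosage.sample_ids,
                           columns=dosage.sources)
    cohort_mean = per_ind.mean(axis=0)
    cohort_sd = per_ind.std(axis=0, ddof=1) if len(per_ind) > 1 \
        else per_ind.iloc[0] * 0.0
    return AncestrySummary(list(dosage.sources), list(dosage.snp_ids),
                           list(dosage.sample_ids), per_snp, per_ind,
                           cohort_mean, cohort_sd, per_snp_sd)


def call_high_introgression(summary: AncestrySummary, source,
                            quantile: float = 0.99) -> list:
    """SNPs whose per-SNP mean proportion for ``source`` is at or above the
    given quantile of that source's distribution (ties included).

    With distinct values the call set has ceil((1 - quantile) * m) SNPs.
    The calls do not depend on SNP or individual order, and raising the
    quantile never enlarges the set.
    """
    values = summary.per_snp_mean[source]
    m = len(values)
    if m < 100:
        warnings.warn(f"only {m} SNPs: the {quantile:.0%} threshold is "
                      "unstable", stacklevel=2)
    # threshold at the order statistic so exactly ceil((1-q)*m) SNPs pass
    # absent ties, with ties at the threshold all included; the small
    # offset guards the floor against binary-fraction noise in q*m
    n_target = m - int(math.floor(quantile * m + 1e-9))
    threshold = np.sort(values.to_numpy())[m - n_target] if n_target else np.inf
    return values.index[values >= threshold].tolist()
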