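"""Synthetic two-timepoint multi-breed SNP panel generator with known truth.

Emulates the study design the analysis modules assume: a set of breeds each
sampled in two cohorts roughly seven generations apart, genotyped on a
medium-density chip.  Between cohorts, allele frequencies drift by
Wright-Fisher binomial resampling of 2*Ne allele copies per generation;
genotypes are drawn from Hardy-Weinberg proportions at the cohort
frequencies.  Optional devices plant known signal for downstream power
tests: adaptive SNPs whose frequencies receive a directional push coupled to
a per-breed climate trend, donor-introgression tracts in the current cohort
of one breed, and homozygous-by-descent runs (ROH) overwritten into chosen
individuals.  Every generated object is accompanied by a ``SimTruth``
sidecar recording the generating values.

Reproducibility: one global seed; each consumer of randomness derives a
module-scoped substream from a fixed label, so adding a feature never
reorders existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genio import (MISSING, AncestryDosage, FeatureTable, GenotypePanel,
                    write_ancestry_dosage, write_ped_map)

__all__ = [
    "SimConfig", "SimTruth", "IntrogressionPlan", "RohPlan", "ClimatePlan",
    "CensusPlan", "simulate_panel", "simulate_census", "simulate_climate",
    "simulate_features", "simulate_ancestry_dosage", "write_outputs",
]


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named substream of the global seed."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


@dataclass
class IntrogressionPlan:
    target_breed: str
    donor_breed: str
    genome_fraction: float = 0.1       # fraction of genome covered by tracts
    tract_length_mb: float = 5.0
    alpha: float = 0.5                 # donor admixture proportion inside tracts


@dataclass
class RohPlan:
    n_individuals: int = 5             # per breed, current cohort
    segments_per_individual: int = 2
    length_mb_range: tuple = (2.0, 10.0)


@dataclass
class ClimatePlan:
    n_variables: int = 20
    trend_mean: float = 1.0            # directional climate change between periods
    trend_sd: float = 1.0              # breed-to-breed spread of the change
    farm_noise_sd: float = 0.5
    n_adaptive_snps: int = 0
    coupling: float = 0.0              # per-generation frequency push per trend unit


@dataclass
class CensusPlan:
    initial_animals: int = 2000
    initial_farms: int = 40
    growth: float = 1.0                # yearly multiplicative growth
    noise_sd: float = 0.0              # lognormal sd on the yearly factor
    female_fraction: float = 0.9       # of breeding animals
    breeding_fraction: float = 0.5     # of animals that are breeders
    years: tuple = (2010, 2024)


@dataclass
class SimConfig:
    """Generating conditions for the synthetic study.

    Defaults mirror the study design the analyses target: 34 breeds of
    10-30 animals per cohort, 26 sheep autosomes, ~45k SNPs at ~50 kb
    spacing, cohorts 7 generations (~20 years) apart, founder frequencies
    uniform on (0.05, 0.95), 2% missing calls.
    """

    seed: int = 0
    n_breeds: int = 34
    samples_per_breed_per_cohort: int = 20
    ne_per_breed: Optional[list] = None        # default: 150 for every breed
    generations_between_cohorts: int = 7
    breed_divergence_generations: int = 50     # founder drift from shared base
    n_chrom: int = 26
    snps_per_chrom: int = 1750
    mean_spacing_kb: float = 50.0
    founder_freq_lo: float = 0.05
    founder_freq_hi: float = 0.95
    missing_rate: float = 0.02
    farms_per_breed: int = 10
    introgression: Optional[IntrogressionPlan] = None
    roh_plan: Optional[RohPlan] = None
    climate_plan: ClimatePlan = field(default_factory=ClimatePlan)
    census_plan: CensusPlan = field(default_factory=CensusPlan)

    def __post_init__(self) -> None:
        if self.ne_per_breed is None:
            self.ne_per_breed = [150] * self.n_breeds
        if len(self.ne_per_breed) != self.n_breeds:
            raise ValueError("ne_per_breed length != n_breeds")
        if any(ne < 2 for ne in self.ne_per_breed):
            raise ValueError("every Ne must be >= 2")
        if self.generations_between_cohorts < 1:
            raise ValueError("generations_between_cohorts must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def breeds(self) -> list:
        return [f"B{i:02d}" for i in range(self.n_breeds)]

    @property
    def chrom_length_bp(self) -> int:
        return int(self.snps_per_chrom * self.mean_spacing_kb * 1000)


@dataclass
class SimTruth:
    """Generating values behind a simulated panel (truth sidecar)."""

    snp_map: pd.DataFrame
    founder_freqs: dict                 # breed -> array of historical freqs
    current_freqs: dict                 # breed -> array after drift/devices
    tracts: pd.DataFrame                # introgression tract intervals
    roh_segments: pd.DataFrame          # planted ROH (sample, chrom, start, end)
    adaptive: pd.DataFrame              # snp_id, variable it is coupled to
    breed_trends: pd.DataFrame          # breed, variable, trend (period2-period1)
    enriched_qtl_category: Optional[str] = None


# ---------------------------------------------------------------------------
# core frequency machinery
# ---------------------------------------------------------------------------

def wright_fisher_drift(p: np.ndarray, ne: int, generations: int,
                        rng: np.random.Generator,
                        push: Optional[np.ndarray] = None) -> np.ndarray:
    """Drift frequencies `generations` steps by binomial resampling of 2*Ne
    allele copies, optionally adding a fixed per-generation push."""
    p = np.asarray(p, dtype=float).copy()
    two_ne = 2 * int(ne)
    for _ in range(int(generations)):
        p = rng.binomial(two_ne, p) / two_ne
        if push is not None:
            p = np.clip(p + push, 0.0, 1.0)
    return p


def _make_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c in range(1, config.n_chrom + 1):
        bp = np.sort(rng.choice(
            np.arange(1, config.chrom_length_bp + 1),
            size=config.snps_per_chrom, replace=False))
        for k, pos in enumerate(bp):
            rows.append((f"snp_{c}_{k}", c, int(pos)))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "bp"])


def _breed_trends(config: SimConfig) -> pd.DataFrame:
    rng = substream(config.seed, "climate-trends")
    cp = config.climate_plan
    rows = [(b, f"VAR{v:02d}", rng.normal(cp.trend_mean, cp.trend_sd))
            for b in config.breeds for v in range(cp.n_variables)]
    return pd.DataFrame(rows, columns=["breed", "variable", "trend"])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_panel(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Generate the two-cohort genotype panel and its truth sidecar."""
    cp = config.climate_plan
    snp_map = _make_map(config, substream(config.seed, "map"))
    m = len(snp_map)
    rng_base = substream(config.seed, "base-freqs")
    p_base = rng_base.uniform(config.founder_freq_lo, config.founder_freq_hi, m)

    trends = _breed_trends(config)
    rng_ad = substream(config.seed, "adaptive")
    if cp.n_adaptive_snps:
        idx = np.sort(rng_ad.choice(m, size=cp.n_adaptive_snps, replace=False))
        variables = rng_ad.choice(sorted(trends["variable"].unique()),
                                  size=cp.n_adaptive_snps)
        adaptive = pd.DataFrame({"snp_id": snp_map["snp_id"].to_numpy()[idx],
                                 "snp_index": idx, "variable": variables})
    else:
        adaptive = pd.DataFrame(columns=["snp_id", "snp_index", "variable"])

    founder, current = {}, {}
    tract_rows = []
    chrom_arr = snp_map["chrom"].to_numpy()
    bp_arr = snp_map["bp"].to_numpy()
    trend_lookup = trends.set_index(["breed", "variable"])["trend"]

    for b, ne in zip(config.breeds, config.ne_per_breed):
        rng_b = substream(config.seed, f"breed-{b}")
        p0 = wright_fisher_drift(p_base, ne,
                                 config.breed_divergence_generations, rng_b)
        lo = 1.0 / (4 * ne)
        p0 = np.clip(p0, lo, 1.0 - lo)   # limit fixation at founding
        founder[b] = p0

        push = None
        if len(adaptive):
            push = np.zeros(m)
            for row in adaptive.itertuples(index=False):
                push[row.snp_index] = cp.coupling * trend_lookup[(b, row.variable)]
        pt = wright_fisher_drift(p0, ne, config.generations_between_cohorts,
                                 rng_b, push=push)
        current[b] = pt

    intro = config.introgression
    if intro is not None:
        tract_bp = int(intro.tract_length_mb * 1e6)
        if tract_bp > config.chrom_length_bp:
            raise ValueError(
                f"tract length {intro.tract_length_mb} Mb exceeds chromosome "
                f"length {config.chrom_length_bp / 1e6:.1f} Mb")
        rng_t = substream(config.seed, "introgression")
        n_tracts = max(1, int(round(
            intro.genome_fraction * config.n_chrom * config.chrom_length_bp
            / tract_bp)))
        pt = current[intro.target_breed].copy()
        pd_donor = current[intro.donor_breed]
        for _ in range(n_tracts):
            c = int(rng_t.integers(1, config.n_chrom + 1))
            start = int(rng_t.integers(1, config.chrom_length_bp - tract_bp + 2))
            end = start + tract_bp - 1
            inside = (chrom_arr == c) & (bp_arr >= start) & (bp_arr <= end)
            pt[inside] = (intro.alpha * pd_donor[inside]
                          + (1 - intro.alpha) * pt[inside])
            tract_rows.append((intro.target_breed, c, start, end))
        current[intro.target_breed] = pt
    tracts = pd.DataFrame(tract_rows,
                          columns=["breed", "chrom", "start_bp", "end_bp"])

    # genotypes
    rng_g = substream(config.seed, "genotypes")
    n_per = config.samples_per_breed_per_cohort
    sample_rows, geno_blocks = [], []
    for b in config.breeds:
        for cohort, freqs in (("historical", founder[b]), ("current", current[b])):
            geno_blocks.append(rng_g.binomial(2, freqs, size=(n_per, m)))
            for k in range(n_per):
                farm = f"{b}_f{k % config.farms_per_breed}"
                sample_rows.append((f"{b}_{cohort[:4]}_{k:03d}", b, cohort, farm))
    genotypes = np.concatenate(geno_blocks, axis=0).astype(np.int8)
    samples = pd.DataFrame(sample_rows,
                           columns=["sample_id", "breed", "cohort", "farm"])

    # planted ROH: overwrite segments with a single sampled haplotype, doubled
    roh_rows = []
    if config.roh_plan is not None:
        rp = config.roh_plan
        rng_r = substream(config.seed, "roh")
        for b in config.breeds:
            cur = samples.index[(samples["breed"] == b)
                                & (samples["cohort"] == "current")].to_numpy()
            chosen = cur[:rp.n_individuals]
            for i in chosen:
                for _ in range(rp.segments_per_individual):
                    length = int(rng_r.uniform(*rp.length_mb_range) * 1e6)
                    length = min(length, config.chrom_length_bp)
                    c = int(rng_r.integers(1, config.n_chrom + 1))
                    start = int(rng_r.integers(
                        1, config.chrom_length_bp - length + 2))
                    end = start + length - 1
                    inside = np.flatnonzero((chrom_arr == c) & (bp_arr >= start)
                                            & (bp_arr <= end))
                    hap = rng_r.binomial(1, current[b][inside])
                    genotypes[i, inside] = (2 * hap).astype(np.int8)
                    roh_rows.append((samples["sample_id"].iloc[i], c, start, end))
    roh_segments = pd.DataFrame(
        roh_rows, columns=["sample_id", "chrom", "start_bp", "end_bp"])

    if config.missing_rate > 0:
        rng_m = substream(config.seed, "missing")
        mask = rng_m.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = MISSING

    panel = GenotypePanel(samples, genotypes, snp_map)
    truth = SimTruth(snp_map=snp_map, founder_freqs=founder,
                     current_freqs=current, tracts=tracts,
                     roh_segments=roh_segments, adaptive=adaptive,
                     breed_trends=trends)
    return panel, truth


def simulate_census(config: SimConfig) -> pd.DataFrame:
    """Yearly census per breed: geometric growth with multiplicative noise."""
    rng = substream(config.seed, "census")
    cp = config.census_plan
    y0, y1 = cp.years
    rows = []
    for b in config.breeds:
        animals = float(cp.initial_animals)
        farms = float(cp.initial_farms)
        for year in range(y0, y1 + 1):
            if year > y0:
                factor = cp.growth * np.exp(rng.normal(0.0, cp.noise_sd)) \
                    if cp.noise_sd > 0 else cp.growth
                animals *= factor
                farms *= factor
            n_animals = int(round(animals))
            breeders = n_animals * cp.breeding_fraction
            n_f = int(round(breeders * cp.female_fraction))
            n_m = int(round(breeders * (1 - cp.female_fraction)))
            rows.append((b, year, n_animals, max(int(round(farms)), 0),
                         n_m, n_f))
    return pd.DataFrame(rows, columns=["breed", "year", "n_animals",
                                       "n_farms", "n_males", "n_females"])


def simulate_climate(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Per-farm climate values for the two periods.

    Farm values are the breed baseline plus farm noise; period-2 values add
    the breed x variable trend recorded in the truth sidecar, so the
    breed-level delta equals the configured trend up to farm noise.
    """
    rng = substream(config.seed, "climate-farms")
    cp = config.climate_plan
    rows = []
    for (b, var), trend in truth.breed_trends.set_index(
            ["breed", "variable"])["trend"].items():
        base = rng.normal(10.0, 2.0)
        for f in range(config.farms_per_breed):
            farm = f"{b}_f{f}"
            v1 = base + (rng.normal(0.0, cp.farm_noise_sd)
                         if cp.farm_noise_sd > 0 else 0.0)
            v2 = v1 + trend + (rng.normal(0.0, cp.farm_noise_sd)
                               if cp.farm_noise_sd > 0 else 0.0)
            rows.append((b, farm, var, "period1", v1))
            rows.append((b, farm, var, "period2", v2))
    return pd.DataFrame(rows, columns=["breed", "farm_id", "variable",
                                       "period", "value"])


def simulate_features(config: SimConfig, truth: SimTruth,
                      n_genes: int = 500, n_qtl: int = 200,
                      qtl_categories: tuple = ("qtl:milk", "qtl:wool",
                                               "qtl:parasite", "qtl:fertility"),
                      enriched_category: Optional[str] = None,
                      enriched_flank_bp: int = 10000) -> FeatureTable:
    """Gene and QTL intervals; one category optionally planted around the
    adaptive SNPs to give enrichment tests real signal."""
    rng = substream(config.seed, "features")
    rows = []
    L = config.chrom_length_bp
    # genes tiled with gaps across chromosomes
    for g in range(n_genes):
        c = int(rng.integers(1, config.n_chrom + 1))
        start = int(rng.integers(1, max(2, L - 50000)))
        end = min(start + int(rng.integers(5000, 50000)), L)
        rows.append((f"gene_{g}", c, start, end, "gene"))
    for q in range(n_qtl):
        cat = qtl_categories[q % len(qtl_categories)]
        c = int(rng.integers(1, config.n_chrom + 1))
        start = int(rng.integers(1, max(2, L - 200000)))
        end = min(start + int(rng.integers(20000, 200000)), L)
        rows.append((f"qtl_{q}", c, start, end, cat))
    if enriched_category is not None and len(truth.adaptive):
        chrom = truth.snp_map["chrom"].to_numpy()
        bp = truth.snp_map["bp"].to_numpy()
        for k, row in enumerate(truth.adaptive.itertuples(index=False)):
            j = row.snp_index
            start = max(1, int(bp[j]) - enriched_flank_bp)
            end = min(int(bp[j]) + enriched_flank_bp, L)
            rows.append((f"qtl_enriched_{k}", int(chrom[j]), start, end,
                         enriched_category))
        truth.enriched_qtl_category = enriched_category
    df = pd.DataFrame(rows, columns=["feature_id", "chrom", "start_bp",
                                     "end_bp", "category"])
    return FeatureTable(df)


def simulate_ancestry_dosage(config: SimConfig, truth: SimTruth,
                             target_breed: Optional[str] = None,
                             noise_conc: float = 50.0) -> AncestryDosage:
    """Dosage matrix emulating local-ancestry output for the introgressed
    breed: inside donor tracts the donor dosage centres on 2*alpha, outside
    on a small background; beta noise at concentration ``noise_conc``."""
    if config.introgression is None:
        raise ValueError("config has no introgression plan")
    intro = config.introgression
    target_breed = target_breed or intro.target_breed
    rng = substream(config.seed, "dosage")
    chrom = truth.snp_map["chrom"].to_numpy()
    bp = truth.snp_map["bp"].to_numpy()
    m = len(truth.snp_map)
    inside = np.zeros(m, dtype=bool)
    for t in truth.tracts.itertuples(index=False):
        inside |= (chrom == t.chrom) & (bp >= t.start_bp) & (bp <= t.end_bp)
    mean_donor = np.where(inside, intro.alpha, 0.05)
    n = config.samples_per_breed_per_cohort
    a = mean_donor * noise_conc
    b = (1 - mean_donor) * noise_conc
    donor_prop = rng.beta(a, b, size=(n, m))
    dosages = np.stack([2 * donor_prop, 2 * (1 - donor_prop)], axis=2)
    sample_ids = [f"{target_breed}_curr_{k:03d}" for k in range(n)]
    return AncestryDosage(sample_ids, truth.snp_map["snp_id"].tolist(),
                          [intro.donor_breed, f"{target_breed}_past"], dosages)


def write_outputs(config: SimConfig, out_dir) -> dict:
    """Simulate everything and write PED/MAP per cohort plus truth sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, truth = simulate_panel(config)
    paths = {}
    for cohort in ("historical", "current"):
        idx = panel.samples.index[panel.samples["cohort"] == cohort].to_numpy()
        sub = panel.take_samples(idx)
        ped, mp = write_ped_map(sub, out / cohort)
        paths[f"{cohort}_ped"], paths[f"{cohort}_map"] = str(ped), str(mp)
    census = simulate_census(config)
    census.to_csv(out / "census.tsv", sep="\t", index=False,
                  lineterminator="\n")
    climate = simulate_climate(config, truth)
    climate.to_csv(out / "climate.tsv", sep="\t", index=False,
                   lineterminator="\n")
    truth.breed_trends.to_csv(out / "truth_trends.tsv", sep="\t", index=False,
                              lineterminator="\n")
    truth.tracts.to_csv(out / "truth_tracts.tsv", sep="\t", index=False,
                        lineterminator="\n")
    truth.roh_segments.to_csv(out / "truth_roh.tsv", sep="\t", index=False,
                              lineterminator="\n")
    truth.adaptive.to_csv(out / "truth_adaptive.tsv", sep="\t", index=False,
                          lineterminator="\n")
    paths.update(census=str(out / "census.tsv"), climate=str(out / "climate.tsv"))
    return paths
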