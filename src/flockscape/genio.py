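"""Shared data model and readers/writers for external text formats.

The package moves genotype data around as :class:`GenotypePanel`: a diploid
genotype matrix coded as counts of the alternate allele (0/1/2, with a
dedicated missing sentinel) plus per-sample metadata (breed, sampling cohort,
farm) and an ordered autosomal marker map.  External formats are the PLINK
text dialect (PED/MAP), tab-separated feature/census/climate tables with
headers, a plain-matrix local-ancestry dosage format with sidecar manifests,
and Newick trees.  All writers emit LF line endings.

Allele polarity: PED files carry no REF/ALT designation, so the alternate
allele is defined as the *minor* allele at read time, with ties broken by
taking the lexicographically later allele.  A panel written with a major
alternate allele is therefore re-read with flipped polarity for that column;
every downstream statistic in this package (MAF, heterozygosity, r-squared,
Fst, Reynolds distance, ROH) is invariant under that flip.

Coordinates are 1-based inclusive everywhere (PLINK/MAP convention).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: dedicated missing-genotype sentinel (never used in arithmetic)
MISSING: int = -1

COHORTS = ("current", "historical")


class ParseError(ValueError):
    """A malformed external file (names the offending line where known)."""


class ValidationError(ValueError):
    """Data violating a documented invariant of the data model."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

def _as_snp_map(df: pd.DataFrame) -> pd.DataFrame:
    required = {"snp_id", "chrom", "bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"snp map missing columns: {sorted(missing)}")
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValidationError(f"duplicated snp_id(s): {dups[:5]}")
    if (df["chrom"] <= 0).any() or (df["bp"] <= 0).any():
        raise ValidationError("chrom and bp must be positive (autosomes, 1-based)")
    order = np.lexsort((df["bp"].to_numpy(), df["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(df))):
        raise ValidationError("snp map must be sorted by (chrom, bp)")
    return df.reset_index(drop=True)


@dataclass
class GenotypePanel:
    """Diploid genotype matrix with sample metadata and marker map.

    ``genotypes[i, j]`` is the alternate-allele count of sample *i* at SNP
    *j*: 0, 1, 2 or :data:`MISSING`.  ``samples`` has columns
    ``sample_id, breed, cohort, farm``; ``snp_map`` has
    ``snp_id, chrom, bp`` and optionally ``ref, alt`` allele letters.
    """

    samples: pd.DataFrame
    genotypes: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.snp_map = _as_snp_map(self.snp_map)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotypes must be 2-D (samples x snps)")
        n, m = self.genotypes.shape
        if n != len(self.samples):
            raise ValidationError(
                f"{n} genotype rows vs {len(self.samples)} sample rows")
        if m != len(self.snp_map):
            raise ValidationError(
                f"{m} genotype columns vs {len(self.snp_map)} map rows")
        if self.samples["sample_id"].duplicated().any():
            raise ValidationError("sample_ids not unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError(
                f"genotype values outside {{0,1,2,{MISSING}}} at "
                f"{np.argwhere(bad)[:3].tolist()}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def take_samples(self, index) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(self.samples.iloc[index], self.genotypes[index],
                             self.snp_map)

    def take_snps(self, index) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(self.samples, self.genotypes[:, index],
                             self.snp_map.iloc[index])

    def breed_of(self) -> pd.Series:
        return self.samples["breed"]


@dataclass
class FeatureTable:
    """Genomic intervals (genes, QTL categories), 1-based inclusive."""

    df: pd.DataFrame  # feature_id, chrom, start_bp, end_bp, category

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        required = {"feature_id", "chrom", "start_bp", "end_bp", "category"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"feature table missing columns: {sorted(missing)}")
        bad = df["start_bp"] > df["end_bp"]
        if bad.any():
            raise ValidationError(
                "start_bp > end_bp for rows: "
                f"{df.index[bad].tolist()[:10]}")
        if df["feature_id"].duplicated().any():
            dups = df.loc[df["feature_id"].duplicated(), "feature_id"]
            raise ValidationError(f"duplicated feature_id(s): {dups.tolist()[:5]}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class AncestryDosage:
    """Per-individual, per-SNP, per-source local-ancestry dosages in [0, 2].

    ``dosages`` has shape (n_samples, n_snps, n_sources); for every
    sample x SNP the dosages over sources sum to 2 (the two haplotypes).
    """

    sample_ids: list
    snp_ids: list
    sources: list
    dosages: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        expected = (len(self.sample_ids), len(self.snp_ids), len(self.sources))
        if d.shape != expected:
            raise ValidationError(f"dosage shape {d.shape} != {expected}")
        if d.size:
            sums = d.sum(axis=2)
            off = np.abs(sums - 2.0)
            if off.max() > 1e-6:
                i, j = np.unravel_index(np.argmax(off), off.shape)
                raise ValidationError(
                    f"dosages at sample {self.sample_ids[i]}, snp {self.snp_ids[j]} "
                    f"sum to {sums[i, j]:.6g}, not 2")
            d = np.clip(d, 0.0, 2.0)
        self.dosages = d


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 columns, "
                                 f"got {len(parts)}")
            chrom, snp_id, _cm, bp = parts
            rows.append((snp_id, int(chrom), int(bp)))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "bp"])


def read_ped_map(ped_path, map_path, cohort: str = "current") -> GenotypePanel:
    """Read a PLINK text PED/MAP pair, recoding to minor-allele counts.

    PED metadata columns are FID IID PAT MAT SEX PHENO; FID is taken as the
    breed code.  A "0" allele marks a missing call; a genotype with either
    allele missing is missing.
    """
    snp_map = read_map(map_path)
    m = len(snp_map)
    sample_rows = []
    allele_a = []  # first allele letter per sample per snp ("" = missing)
    allele_b = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"({m} SNPs), got {len(parts)}")
            fid, iid = parts[0], parts[1]
            sample_rows.append((iid, fid, cohort, None))
            alleles = parts[6:]
            allele_a.append(alleles[0::2])
            allele_b.append(alleles[1::2])
    n = len(sample_rows)
    samples = pd.DataFrame(sample_rows,
                           columns=["sample_id", "breed", "cohort", "farm"])
    a = np.array(allele_a, dtype=object).reshape(n, m)
    b = np.array(allele_b, dtype=object).reshape(n, m)
    geno = np.full((n, m), MISSING, dtype=np.int8)
    refs, alts = [], []
    for j in range(m):
        col_a, col_b = a[:, j], b[:, j]
        ok = (col_a != "0") & (col_b != "0")
        letters, counts = np.unique(
            np.concatenate([col_a[ok], col_b[ok]]), return_counts=True)
        if len(letters) > 2:
            raise ParseError(
                f"{ped_path}: SNP {snp_map['snp_id'][j]} has "
                f"{len(letters)} alleles: {letters.tolist()}")
        if len(letters) == 0:          # all missing
            ref, alt = "0", "0"
        elif len(letters) == 1:        # monomorphic: observed allele is ref
            ref, alt = letters[0], "0"
        else:
            # minor allele = alternate; tie -> lexicographically later letter
            if counts[0] == counts[1]:
                ref, alt = sorted(letters)
            elif counts[0] < counts[1]:
                ref, alt = letters[1], letters[0]
            else:
                ref, alt = letters[0], letters[1]
        refs.append(ref)
        alts.append(alt)
        dose = (col_a == alt).astype(np.int8) + (col_b == alt).astype(np.int8)
        geno[ok, j] = dose[ok]
    snp_map["ref"] = refs
    snp_map["alt"] = alts
    return GenotypePanel(samples, geno, snp_map)


def write_ped_map(panel: GenotypePanel, prefix) -> tuple[Path, Path]:
    """Write ``prefix``.ped / ``prefix``.map re-readable by :func:`read_ped_map`.

    Allele letters come from the map's ``ref``/``alt`` columns when present,
    else the deterministic assignment ref="A", alt="B".
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    sm = panel.snp_map
    ref = sm["ref"].to_numpy() if "ref" in sm else np.full(panel.n_snps, "A")
    alt = sm["alt"].to_numpy() if "alt" in sm else np.full(panel.n_snps, "B")
    alt = np.where(alt == "0", "B", alt)   # unobserved alt: any letter, unused
    with open(map_path, "w", newline="\n") as fh:
        for row in sm.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.bp}\n")
    pair = {0: lambda r, a: f"{r} {r}", 1: lambda r, a: f"{r} {a}",
            2: lambda r, a: f"{a} {a}", MISSING: lambda r, a: "0 0"}
    with open(ped_path, "w", newline="\n") as fh:
        for i, srow in enumerate(panel.samples.itertuples(index=False)):
            fields = [str(srow.breed), str(srow.sample_id), "0", "0", "0", "-9"]
            g = panel.genotypes[i]
            fields.extend(pair[int(g[j])](ref[j], alt[j])
                          for j in range(panel.n_snps))
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# tab-separated tables
# ---------------------------------------------------------------------------

def read_feature_table(path) -> FeatureTable:
    """Read a tab-separated feature table with header
    (feature_id, chrom, start_bp, end_bp, category)."""
    df = pd.read_csv(path, sep="\t")
    try:
        return FeatureTable(df)
    except ValidationError:
        raise
    except Exception as exc:  # missing columns, bad dtypes
        raise ParseError(f"{path}: {exc}") from exc


def write_feature_table(table: FeatureTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_census_table(path) -> pd.DataFrame:
    """Yearly herd-book census: breed, year, n_animals, n_farms, n_males,
    n_females (long format, one row per breed x year)."""
    df = pd.read_csv(path, sep="\t")
    required = {"breed", "year", "n_animals", "n_farms", "n_males", "n_females"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: census table missing columns {sorted(missing)}")
    return df


def read_climate_table(path) -> pd.DataFrame:
    """Per-farm climate values: breed, farm_id, variable, period, value."""
    df = pd.read_csv(path, sep="\t")
    required = {"breed", "farm_id", "variable", "period", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: climate table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# ancestry dosages (plain matrix + sidecar manifests)
# ---------------------------------------------------------------------------

def read_ancestry_dosage(path, sources, sample_ids=None,
                         snp_ids=None) -> AncestryDosage:
    """Read a whitespace-delimited dosage matrix: one row per individual,
    n_snps x n_sources columns grouped by SNP.

    Sidecar manifests ``<path>.samples`` and ``<path>.snps`` (one id per
    line) are used when ``sample_ids``/``snp_ids`` are not given.
    """
    path = Path(path)
    mat = np.loadtxt(path, ndmin=2, dtype=float)
    k = len(sources)
    if mat.shape[1] % k:
        raise ParseError(f"{path}: {mat.shape[1]} columns not divisible by "
                         f"{k} sources")
    m = mat.shape[1] // k
    if sample_ids is None:
        sidecar = path.with_suffix(path.suffix + ".samples")
        sample_ids = sidecar.read_text().split() if sidecar.exists() \
            else [f"ind{i}" for i in range(mat.shape[0])]
    if snp_ids is None:
        sidecar = path.with_suffix(path.suffix + ".snps")
        snp_ids = sidecar.read_text().split() if sidecar.exists() \
            else [f"snp{j}" for j in range(m)]
    dosages = mat.reshape(mat.shape[0], m, k)
    return AncestryDosage(list(sample_ids), list(snp_ids), list(sources), dosages)


def write_ancestry_dosage(dosage: AncestryDosage, path) -> None:
    path = Path(path)
    n, m, k = dosage.dosages.shape
    np.savetxt(path, dosage.dosages.reshape(n, m * k), fmt="%.6f")
    path.with_suffix(path.suffix + ".samples").write_text(
        "\n".join(map(str, dosage.sample_ids)) + "\n")
    path.with_suffix(path.suffix + ".snps").write_text(
        "\n".join(map(str, dosage.snp_ids)) + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree) -> str:
    """Serialize a tree to Newick, node supports as internal labels.

    ``tree`` is a :class:`skbio.TreeNode` (or any object with ``children``,
    ``name``, ``length`` and an optional ``support`` attribute).  Leaf order
    follows the input structure.  Branch lengths are omitted where ``None``
    and formatted with repr-shortest floats otherwise.
    """
    seen: set[int] = set()

    def fmt_len(node) -> str:
        if getattr(node, "length", None) is None:
            return ""
        return f":{format(float(node.length), 'g')}"

    def render(node) -> str:
        if id(node) in seen:
            raise ValidationError("cyclic tree structure")
        seen.add(id(node))
        children = list(getattr(node, "children", []) or [])
        if not children:
            return f"{node.name}{fmt_len(node)}"
        inner = ",".join(render(c) for c in children)
        support = getattr(node, "support", None)
        label = node.name if node.name is not None else ""
        if support is not None:
            label = format(float(support), "g")
        return f"({inner}){label}{fmt_len(node)}"

    return render(tree) + ";"
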