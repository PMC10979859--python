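"""Domain types and file I/O for the resistance-association workflow.

Conventions
-----------
* VCF positions are 1-based; BED intervals and all internal genomic
  intervals are 0-based, half-open.
* Genotypes are stored as alt-allele dosage in {0, 1, 2}; missing calls
  use the sentinel :data:`MISSING` (= -1), never a dosage value.
* Haplotypes are phased 0/1 allele columns, two per sample, with no
  missing values: only fully phased, fully called records enter a
  :class:`HaplotypeSet`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid genotype call. Distinct from any dosage.
MISSING: int = -1

COVERAGE_WINDOW_BP: int = 300

PHENOTYPES = ("resistant", "susceptible")


class DataError(ValueError):
    """Raised when an input file violates a type invariant."""


@dataclass(frozen=True)
class SiteInfo:
    """A biallelic SNP site (VCF-style 1-based position)."""

    contig: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "T"


@dataclass(frozen=True)
class GeneRegion:
    """A named genomic interval, 0-based half-open."""

    name: str
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise DataError(
                f"region {self.name}: start {self.start} >= end {self.end}"
            )

    def contains_pos(self, contig: str, pos_1based: int) -> bool:
        return contig == self.contig and self.start <= pos_1based - 1 < self.end


@dataclass(frozen=True)
class SNPWindow:
    """A window over consecutive SNP indices (inclusive bounds)."""

    contig: str
    first_index: int
    last_index: int
    first_pos: int
    last_pos: int

    @property
    def n_snps(self) -> int:
        return self.last_index - self.first_index + 1

    @property
    def indices(self) -> slice:
        return slice(self.first_index, self.last_index + 1)


@dataclass
class GenotypeSet:
    """Diploid genotypes: ``calls[site, sample]`` is alt dosage or MISSING."""

    sites: list[SiteInfo]
    samples: list[str]
    calls: np.ndarray  # int8, shape (n_sites, n_samples)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise DataError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError("genotype calls must be 0, 1, 2 or MISSING")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def allele_counts(self, sample_idx: Optional[Sequence[int]] = None) -> np.ndarray:
        """Per-site (ref, alt) allele counts over non-missing calls."""
        calls = self.calls if sample_idx is None else self.calls[:, list(sample_idx)]
        called = calls != MISSING
        alt = np.where(called, calls, 0).sum(axis=1)
        total = 2 * called.sum(axis=1)
        return np.stack([total - alt, alt], axis=1)

    def take_sites(self, idx: Sequence[int] | np.ndarray) -> "GenotypeSet":
        idx = np.asarray(idx)
        return GenotypeSet(
            sites=[self.sites[i] for i in idx],
            samples=list(self.samples),
            calls=self.calls[idx],
        )

    def take_samples(self, ids: Sequence[str]) -> "GenotypeSet":
        lookup = {s: i for i, s in enumerate(self.samples)}
        cols = [lookup[s] for s in ids]
        return GenotypeSet(self.sites, list(ids), self.calls[:, cols])


@dataclass
class HaplotypeSet:
    """Phased haploid alleles: ``alleles[site, hap]`` in {0, 1}.

    ``haplotypes`` lists (sample id, phase index) column labels; every
    sample contributes exactly two columns.
    """

    sites: list[SiteInfo]
    haplotypes: list[tuple[str, int]]
    alleles: np.ndarray  # int8, shape (n_sites, n_haplotypes)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.sites), len(self.haplotypes)):
            raise DataError("allele matrix shape inconsistent with labels")
        if not np.isin(self.alleles, (0, 1)).all():
            raise DataError("haplotype alleles must be 0/1 with no missing")
        counts: dict[str, int] = {}
        for sample, _ in self.haplotypes:
            counts[sample] = counts.get(sample, 0) + 1
        if any(c != 2 for c in counts.values()):
            raise DataError("each sample must contribute exactly 2 haplotypes")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def samples(self) -> list[str]:
        seen: list[str] = []
        for sample, phase in self.haplotypes:
            if phase == 0:
                seen.append(sample)
        return seen

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def sample_columns(self, sample: str) -> list[int]:
        return [i for i, (s, _) in enumerate(self.haplotypes) if s == sample]

    def take_sites(self, idx: Sequence[int] | np.ndarray) -> "HaplotypeSet":
        idx = np.asarray(idx)
        return HaplotypeSet(
            [self.sites[i] for i in idx], list(self.haplotypes), self.alleles[idx]
        )

    def take_samples(self, ids: Sequence[str]) -> "HaplotypeSet":
        cols: list[int] = []
        labels: list[tuple[str, int]] = []
        for s in ids:
            for c in self.sample_columns(s):
                cols.append(c)
                labels.append(self.haplotypes[c])
        return HaplotypeSet(list(self.sites), labels, self.alleles[:, cols])


def to_genotype_set(h: HaplotypeSet) -> GenotypeSet:
    """Collapse phased haplotypes to diploid dosages (no missingness)."""
    samples = h.samples
    calls = np.empty((h.n_sites, len(samples)), dtype=np.int8)
    for j, s in enumerate(samples):
        cols = h.sample_columns(s)
        calls[:, j] = h.alleles[:, cols].sum(axis=1)
    return GenotypeSet(list(h.sites), samples, calls)


@dataclass
class SampleTable:
    """Per-sample metadata; wraps a DataFrame indexed by sample id."""

    df: pd.DataFrame

    REQUIRED = ("sample_id", "location", "insecticide", "phenotype", "contamination")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise DataError(f"sample table missing required columns: {missing}")
        if self.df["sample_id"].duplicated().any():
            dupes = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"]
            raise DataError(f"duplicate sample ids: {sorted(set(dupes))}")
        bad_pheno = set(self.df["phenotype"].dropna()) - set(PHENOTYPES)
        if bad_pheno:
            raise DataError(f"unknown phenotype labels: {sorted(bad_pheno)}")
        contam = self.df["contamination"].astype(float)
        if ((contam < 0) | (contam > 1)).any():
            raise DataError("contamination fractions must lie in [0, 1]")
        if "sib_group" not in self.df.columns:
            self.df = self.df.assign(sib_group=pd.NA)
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def phenotype_binary(self, ids: Optional[Sequence[str]] = None) -> np.ndarray:
        """resistant -> 1, susceptible -> 0, ordered as ``ids``."""
        sub = self.df.set_index("sample_id")
        ids = self.sample_ids if ids is None else list(ids)
        pheno = sub.loc[ids, "phenotype"]
        if pheno.isna().any():
            raise DataError("phenotype undefined for samples used in association")
        return (pheno == "resistant").to_numpy(dtype=np.int8)

    def group_ids(self, column: str, value: str) -> list[str]:
        return list(self.df.loc[self.df[column] == value, "sample_id"])

    def contamination(self, ids: Optional[Sequence[str]] = None) -> np.ndarray:
        sub = self.df.set_index("sample_id")
        ids = self.sample_ids if ids is None else list(ids)
        return sub.loc[ids, "contamination"].to_numpy(dtype=float)

    def subset(self, ids: Sequence[str]) -> "SampleTable":
        sub = self.df.set_index("sample_id").loc[list(ids)].reset_index()
        return SampleTable(sub)


@dataclass
class CoverageMatrix:
    """Normalised coverage in fixed 300-bp windows; diploid expectation 2.0."""

    contig: str
    starts: np.ndarray  # int64, 0-based window starts
    samples: list[str]
    values: np.ndarray  # float64, shape (n_samples, n_windows)
    window_bp: int = COVERAGE_WINDOW_BP

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.starts)):
            raise DataError("coverage matrix shape inconsistent")
        if len(self.starts) > 1:
            gaps = np.diff(self.starts)
            if (gaps < self.window_bp).any():
                raise DataError("coverage windows overlap or are unsorted")
        if (self.values < 0).any():
            raise DataError("normalised coverage must be non-negative")

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.window_bp

    def sample_track(self, sample: str) -> np.ndarray:
        return self.values[self.samples.index(sample)]

    def windows_overlapping(self, region: GeneRegion) -> np.ndarray:
        if region.contig != self.contig:
            return np.zeros(0, dtype=np.int64)
        mask = (self.starts < region.end) & (self.ends > region.start)
        return np.flatnonzero(mask)

    def windows_within(self, region: GeneRegion) -> np.ndarray:
        if region.contig != self.contig:
            return np.zeros(0, dtype=np.int64)
        mask = (self.starts >= region.start) & (self.ends <= region.end)
        return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_vcf(path: str, region: Optional[str] = None) -> tuple[GenotypeSet, HaplotypeSet]:
    """Read biallelic SNPs from a VCF into genotype and haplotype sets.

    Multiallelic and non-SNP records are skipped (counted in the log).
    The haplotype set contains only fully phased, fully called records,
    so its site list may be a subset of the genotype set's.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise DataError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    sites: list[SiteInfo] = []
    rows: list[np.ndarray] = []
    phased_ok: list[bool] = []
    hap_rows: list[np.ndarray] = []
    n_skipped = 0
    iterator = vcf(region) if region else vcf
    for var in iterator:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gts = np.asarray(var.genotypes, dtype=object)  # rows [a0, a1, phased]
        a0 = np.array([g[0] for g in gts], dtype=np.int16)
        a1 = np.array([g[1] for g in gts], dtype=np.int16)
        phased = np.array([bool(g[2]) for g in gts])
        called = (a0 >= 0) & (a1 >= 0)
        dose = np.where(called, a0 + a1, MISSING).astype(np.int8)
        sites.append(SiteInfo(var.CHROM, var.POS, var.REF, var.ALT[0]))
        rows.append(dose)
        fully_phased = bool(called.all() and phased.all())
        phased_ok.append(fully_phased)
        if fully_phased:
            hap_rows.append(np.stack([a0, a1], axis=1).reshape(-1).astype(np.int8))
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    calls = np.array(rows, dtype=np.int8).reshape(len(sites), len(samples))
    g = GenotypeSet(sites, samples, calls)
    hap_sites = [s for s, ok in zip(sites, phased_ok) if ok]
    hap_labels = [(s, p) for s in samples for p in (0, 1)]
    alleles = (
        np.array(hap_rows, dtype=np.int8).reshape(len(hap_sites), 2 * len(samples))
        if hap_rows
        else np.zeros((0, 2 * len(samples)), dtype=np.int8)
    )
    h = HaplotypeSet(hap_sites, hap_labels, alleles)
    return g, h


def write_vcf(path: str, g: GenotypeSet, h: Optional[HaplotypeSet] = None) -> None:
    """Write a minimal GT-only VCF; phased pipes where ``h`` covers a site."""
    hap_index = {}
    if h is not None:
        hap_index = {(s.contig, s.pos): i for i, s in enumerate(h.sites)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        contigs = sorted({s.contig for s in g.sites}, key=str)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for i, site in enumerate(g.sites):
            key = (site.contig, site.pos)
            fields = [
                site.contig,
                str(site.pos),
                ".",
                site.ref_allele,
                site.alt_allele,
                ".",
                "PASS",
                ".",
                "GT",
            ]
            if key in hap_index:
                row = h.alleles[hap_index[key]]
                for j in range(len(g.samples)):
                    fields.append(f"{row[2 * j]}|{row[2 * j + 1]}")
            else:
                coded = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                for call in g.calls[i]:
                    fields.append(coded[int(call)])
            fh.write("\t".join(fields) + "\n")


def read_sample_table(path: str) -> SampleTable:
    df = pd.read_csv(path, sep=None, engine="python")
    return SampleTable(df)


def write_sample_table(path: str, st: SampleTable) -> None:
    st.df.to_csv(path, sep="\t", index=False)


def read_coverage(path: str) -> CoverageMatrix:
    """Coverage TSV: columns contig, start, end, then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    for col in ("contig", "start", "end"):
        if col not in df.columns:
            raise DataError(f"coverage table missing column {col!r}")
    contigs = df["contig"].unique()
    if len(contigs) != 1:
        raise DataError("coverage matrix must cover a single contig")
    widths = (df["end"] - df["start"]).unique()
    if len(widths) != 1 or widths[0] != COVERAGE_WINDOW_BP:
        raise DataError(f"coverage windows must be exactly {COVERAGE_WINDOW_BP} bp")
    sample_cols = [c for c in df.columns if c not in ("contig", "start", "end")]
    return CoverageMatrix(
        contig=str(contigs[0]),
        starts=df["start"].to_numpy(),
        samples=sample_cols,
        values=df[sample_cols].to_numpy().T,
    )


def write_coverage(path: str, cov: CoverageMatrix) -> None:
    meta = pd.DataFrame(
        {"contig": cov.contig, "start": cov.starts, "end": cov.ends}
    )
    values = pd.DataFrame(cov.values.T, columns=cov.samples)
    pd.concat([meta, values], axis=1).to_csv(path, sep="\t", index=False)


def read_regions(path: str) -> list[GeneRegion]:
    """BED (0-based half-open); column 4, when present, names the region."""
    regions: list[GeneRegion] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"BED line {ln}: fewer than 3 columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"region_{ln}"
            if start >= end:
                raise DataError(f"BED line {ln}: start {start} >= end {end}")
            regions.append(GeneRegion(name=name, contig=contig, start=start, end=end))
    return regions


def write_regions(path: str, regions: Iterable[GeneRegion]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.name}\n")


# ---------------------------------------------------------------------------
# Site filters and window construction
# ---------------------------------------------------------------------------


def filter_sites(
    g: GenotypeSet, min_mac: int = 0, max_missing: float = 1.0
) -> GenotypeSet:
    """Keep sites with minor allele count >= ``min_mac`` and missing
    fraction <= ``max_missing``; site order is preserved."""
    if min_mac < 0:
        raise ValueError("min_mac must be >= 0")
    ac = g.allele_counts()
    mac = ac.min(axis=1)
    miss_frac = (g.calls == MISSING).mean(axis=1) if g.n_samples else np.zeros(g.n_sites)
    keep = np.flatnonzero((mac >= min_mac) & (miss_frac <= max_missing))
    return g.take_sites(keep)


def make_snp_windows(
    sites: Sequence[SiteInfo], window_size: int, step: Optional[int] = None
) -> list[SNPWindow]:
    """Consecutive-index windows of ``window_size`` SNPs; the trailing
    partial window is dropped. Default step = window_size (non-overlap)."""
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    step = window_size if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    n = len(sites)
    windows: list[SNPWindow] = []
    start = 0
    while start + window_size <= n:
        last = start + window_size - 1
        if sites[start].contig == sites[last].contig:
            windows.append(
                SNPWindow(
                    contig=sites[start].contig,
                    first_index=start,
                    last_index=last,
                    first_pos=sites[start].pos,
                    last_pos=sites[last].pos,
                )
            )
        start += step
    return windows
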