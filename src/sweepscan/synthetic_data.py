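"""Synthetic cohorts with the statistical structure of a field resistance study.

The generator emulates two partially differentiated mosquito populations
sampled after an insecticide bioassay: phased haplotypes from a
two-population split coalescent, a soft selective sweep in one genomic
block, a multi-copy CNV linked to the swept haplotypes, genotype-dependent
mortality that converts carrier status into a resistant/susceptible
phenotype, full-sib pairs, and a per-sample contamination covariate.

Haplotypes are built block-wise: each block is an independent Kingman
coalescent genealogy (independence between blocks stands in for
recombination). Within a block, the two populations coalesce separately
back to a divergence time ``tau`` (in units of 2N generations) and the
surviving lineages then coalesce in a shared ancestral pool, so ``tau``
is the differentiation knob. Mutations are placed on branches either as
a Poisson process with rate theta/2 per unit branch length (so the
expected pairwise diversity per block equals theta) or conditioned on a
fixed number of segregating sites, placed proportionally to branch
length. Sites map to integer positions uniformly within the block's
span of the contig; position collisions are re-drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core_io import (
    CoverageMatrix,
    GeneRegion,
    GenotypeSet,
    HaplotypeSet,
    SampleTable,
    SiteInfo,
    to_genotype_set,
)
import pandas as pd

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_haplotypes",
    "implant_sweep",
    "assign_cnv_and_coverage",
    "simulate_phenotypes",
    "make_sib_pairs",
    "simulate_contamination",
    "select_case_control",
    "simulate_dataset",
    "sweep_study_config",
    "simulate_study_cohort",
]


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the structure of the field study the workflow is
    built for: two populations of 100 mosquitoes, a sweep at carrier
    fraction 0.6 in the focal block of population 0, a linked multi-copy
    CNV, and mortalities of 44.2% (non-carriers) vs 16.7% (CNV carriers).
    """

    n_samples: tuple[int, int] = (100, 100)
    n_blocks: int = 8
    sites_per_block: Optional[int] = 200  # None -> Poisson(theta) sites
    theta: float = 20.0
    divergence: float = 0.08  # split time tau, units of 2N generations
    contig: str = "2L"
    block_bp: int = 100_000
    # sweep
    sweep_block: int = 3
    sweep_fraction: float = 0.6
    sweep_mut_rate: float = 0.25  # mean private mutations per swept copy
    sweep_population: Optional[int] = 0
    sweep_core_population: Optional[int] = None  # migrant-core sweep when set
    # CNV
    cnv_region: Optional[GeneRegion] = None  # default: mid-sweep-block 13 kb
    cnv_link_p: float = 1.0
    cnv_extra_copies: tuple[int, int] = (2, 8)  # inclusive uniform range
    coverage_noise_sd: float = 0.5
    # phenotype
    base_mortality: float = 0.442
    carrier_mortality: float = 0.167
    # relatedness / contamination
    n_sib_pairs: int = 4
    contamination_max: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sweep_fraction", "cnv_link_p", "base_mortality",
                     "carrier_mortality", "contamination_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.cnv_region is None:
            mid = (self.sweep_block * self.block_bp
                   + self.block_bp // 2) // 300 * 300
            self.cnv_region = GeneRegion(
                "cnv_locus", self.contig, mid, mid + 13_200
            )


@dataclass
class TruthSet:
    """Ground truth emitted alongside a synthetic dataset."""

    sweep_member: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    population: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    cnv_carrier: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    true_copy_number: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    sib_group: list[Optional[str]] = field(default_factory=list)
    causal_sites: list[int] = field(default_factory=list)
    block_bounds: list[tuple[int, int]] = field(default_factory=list)

    def to_frame(self, samples: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(samples),
                "population": self.population[: len(samples)],
                "cnv_carrier": self.cnv_carrier.astype(int)
                if len(self.cnv_carrier)
                else 0,
                "true_copy_number": self.true_copy_number
                if len(self.true_copy_number)
                else 2,
                "sib_group": [g if g is not None else "" for g in self.sib_group]
                if self.sib_group
                else "",
            }
        )


# ---------------------------------------------------------------------------
# Coalescent machinery
# ---------------------------------------------------------------------------


def _split_genealogy(
    n_per_pop: Sequence[int], tau: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a two-population split genealogy.

    Returns (parent, time): parent[i] is the parent node of node i (-1
    for the root); leaves are nodes 0..sum(n)-1, population 0 first.
    """
    n_total = int(sum(n_per_pop))
    max_nodes = 2 * n_total - 1
    parent = np.full(max_nodes, -1, dtype=np.int64)
    time = np.zeros(max_nodes, dtype=float)
    next_node = n_total

    def merge(active: list[int], a_i: int, b_i: int, t: float) -> None:
        nonlocal next_node
        node = next_node
        next_node += 1
        a, b = active[a_i], active[b_i]
        parent[a] = parent[b] = node
        time[node] = t
        # O(1) removal: overwrite with the two tail elements, then append
        hi, lo = max(a_i, b_i), min(a_i, b_i)
        active[hi] = active[-1]
        active.pop()
        active[lo] = active[-1]
        active.pop()
        active.append(node)

    offset = 0
    survivors: list[int] = []
    for n in n_per_pop:
        active = list(range(offset, offset + n))
        offset += n
        t = 0.0
        while len(active) > 1:
            k = len(active)
            t_next = t + rng.exponential(1.0 / (k * (k - 1) / 2.0))
            if t_next > tau:
                break
            t = t_next
            i, j = rng.choice(k, size=2, replace=False)
            merge(active, int(i), int(j), t)
        survivors.extend(active)

    active = survivors
    t = tau
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        merge(active, int(i), int(j), t)
    return parent[:next_node], time[:next_node]


def _leaf_sets(parent: np.ndarray, n_leaves: int) -> list[np.ndarray]:
    """Boolean leaf membership below each node (index = node id)."""
    n_nodes = len(parent)
    below = np.zeros((n_nodes, n_leaves), dtype=bool)
    below[np.arange(n_leaves), np.arange(n_leaves)] = True
    # children have lower ids than parents by construction
    for node in range(n_nodes):
        p = parent[node]
        if p >= 0:
            below[p] |= below[node]
    return [below[i] for i in range(n_nodes)]


def _mutate_block(
    parent: np.ndarray,
    time: np.ndarray,
    n_leaves: int,
    theta: float,
    n_sites: Optional[int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Place mutations on branches; return (n_sites, n_leaves) 0/1 matrix."""
    has_parent = parent >= 0
    blen = np.where(has_parent, time[parent.clip(min=0)] - time, 0.0)
    total = blen.sum()
    if n_sites is None:
        n_mut = rng.poisson(theta / 2.0 * total)
    else:
        n_mut = int(n_sites)
    if n_mut == 0:
        return np.zeros((0, n_leaves), dtype=np.int8)
    probs = blen / total
    branch = rng.choice(len(parent), size=n_mut, p=probs)
    below = _leaf_sets(parent, n_leaves)
    out = np.zeros((n_mut, n_leaves), dtype=np.int8)
    for i, b in enumerate(branch):
        out[i] = below[b]
    return out


def _block_positions(
    n_sites: int, block_idx: int, block_bp: int, rng: np.random.Generator
) -> np.ndarray:
    """Sorted unique integer positions (1-based) within a block's span."""
    lo = block_idx * block_bp + 1
    hi = (block_idx + 1) * block_bp
    chosen: set[int] = set()
    while len(chosen) < n_sites:
        draw = rng.integers(lo, hi + 1, size=n_sites - len(chosen))
        chosen.update(int(x) for x in draw)
    return np.array(sorted(chosen), dtype=np.int64)


def simulate_haplotypes(cfg: SimConfig) -> tuple[HaplotypeSet, TruthSet]:
    """Draw phased haplotypes for two populations over independent blocks."""
    rng = np.random.default_rng(cfg.seed)
    n0, n1 = cfg.n_samples
    hap_per_pop = (2 * n0, 2 * n1)
    n_hap = sum(hap_per_pop)
    site_rows: list[np.ndarray] = []
    sites: list[SiteInfo] = []
    block_bounds: list[tuple[int, int]] = []
    for b in range(cfg.n_blocks):
        parent, time = _split_genealogy(hap_per_pop, cfg.divergence, rng)
        block = _mutate_block(
            parent, time, n_hap, cfg.theta, cfg.sites_per_block, rng
        )
        pos = _block_positions(block.shape[0], b, cfg.block_bp, rng)
        order = np.argsort(pos)
        start = len(sites)
        for p in pos[order]:
            sites.append(SiteInfo(cfg.contig, int(p)))
        site_rows.append(block[order])
        block_bounds.append((start, len(sites)))
    alleles = (
        np.concatenate(site_rows, axis=0)
        if site_rows
        else np.zeros((0, n_hap), dtype=np.int8)
    )
    samples = [f"P0_{i:03d}" for i in range(n0)] + [f"P1_{i:03d}" for i in range(n1)]
    labels = [(s, p) for s in samples for p in (0, 1)]
    h = HaplotypeSet(sites, labels, alleles)
    truth = TruthSet(
        sweep_member=np.zeros(n_hap, dtype=bool),
        population=np.repeat([0, 1], [n0, n1]),
        sib_group=[None] * (n0 + n1),
        block_bounds=block_bounds,
    )
    return h, truth


def implant_sweep(
    h: HaplotypeSet,
    truth: TruthSet,
    block: int,
    f: float,
    mut_rate: float,
    seed: int,
    population: Optional[int] = None,
    core_population: Optional[int] = None,
) -> tuple[HaplotypeSet, TruthSet]:
    """Overwrite the focal block of a fraction ``f`` of haplotypes with a
    single core haplotype, then add private mutations to each copy.

    The core is a randomly chosen haplotype; with ``core_population`` it
    is drawn from that population instead of the swept one, modelling a
    resistance haplotype that migrated in from a diverged population (a
    common origin of insecticide-resistance sweeps, and the situation
    the cross-population sharing statistic H1X is designed to flag).
    Private mutations flip alleles at randomly chosen focal-block sites
    of the copy (mean ``mut_rate`` flips per copy), creating the kind of
    sub-structure seen when a CNV arises on an already-sweeping haplotype.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError("sweep fraction must be in (0, 1]")
    if not 0 <= block < len(truth.block_bounds):
        raise ValueError(f"focal block {block} out of range")
    rng = np.random.default_rng(seed)
    lo, hi = truth.block_bounds[block]
    alleles = h.alleles.copy()
    hap_pop = np.repeat(truth.population, 2)
    if population is None:
        target = np.arange(h.n_haplotypes)
    else:
        target = np.flatnonzero(hap_pop == population)
    n_swept = max(1, int(round(f * len(target))))
    swept = rng.choice(target, size=n_swept, replace=False)
    if core_population is None:
        core = int(rng.choice(swept))
    else:
        donors = np.flatnonzero(hap_pop == core_population)
        if donors.size == 0:
            raise ValueError(f"no haplotypes in core population {core_population}")
        core = int(rng.choice(donors))
    core_block = alleles[lo:hi, core].copy()
    for col in swept:
        alleles[lo:hi, col] = core_block
        n_priv = rng.poisson(mut_rate)
        if n_priv and hi > lo:
            flip = rng.choice(hi - lo, size=min(n_priv, hi - lo), replace=False)
            alleles[lo + flip, col] = 1 - alleles[lo + flip, col]
    new_truth = TruthSet(**{**truth.__dict__})
    new_truth.sweep_member = truth.sweep_member.copy()
    new_truth.sweep_member[swept] = True
    new_truth.causal_sites = list(range(lo, hi))
    return HaplotypeSet(list(h.sites), list(h.haplotypes), alleles), new_truth


def assign_cnv_and_coverage(
    truth: TruthSet,
    region: GeneRegion,
    copy_dist: Callable[[np.random.Generator], int] | tuple[int, int],
    link_p: float,
    noise_sd: float,
    seed: int,
    contig_bp: int,
    samples: Sequence[str],
) -> tuple[CoverageMatrix, TruthSet]:
    """Assign CNV carrier status linked to the sweep and emit coverage.

    Samples carrying at least one swept haplotype become CNV carriers
    with probability ``link_p``; carriers draw extra copies from
    ``copy_dist`` (a callable on the RNG, or an inclusive integer range).
    Coverage per 300-bp window is Normal(true total copy number,
    noise_sd) truncated at zero, with diploid mean 2.0 outside the region.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    n_samples = len(samples)
    starts = np.arange(0, contig_bp - contig_bp % 300, 300, dtype=np.int64)
    in_region = (starts >= region.start) & (starts + 300 <= region.end)
    if not in_region.any():
        raise ValueError("CNV region not covered by the 300-bp window grid")
    sweep_by_sample = truth.sweep_member.reshape(-1, 2).any(axis=1)
    if len(sweep_by_sample) != n_samples:
        raise ValueError("truth set inconsistent with sample list")
    carrier = sweep_by_sample & (rng.random(n_samples) < link_p)
    if callable(copy_dist):
        extra = np.array([copy_dist(rng) if c else 0 for c in carrier])
    else:
        lo, hi = copy_dist
        extra = np.where(carrier, rng.integers(lo, hi + 1, size=n_samples), 0)
    total_copy = 2 + extra
    means = np.full((n_samples, len(starts)), 2.0)
    means[:, in_region] = total_copy[:, None]
    values = np.clip(means + rng.normal(0.0, noise_sd, means.shape), 0.0, None)
    cov = CoverageMatrix(region.contig, starts, list(samples), values)
    new_truth = TruthSet(**{**truth.__dict__})
    new_truth.cnv_carrier = carrier
    new_truth.true_copy_number = total_copy
    return cov, new_truth


def simulate_phenotypes(
    truth: TruthSet,
    samples: Sequence[str],
    base_mort: float,
    carrier_mort: float,
    seed: int,
    locations: tuple[str, str] = ("Moshi", "Muleba"),
    insecticide: str = "PM",
) -> SampleTable:
    """Bioassay outcome: dead -> susceptible, alive -> resistant.

    Death probability is ``base_mort`` for non-carriers and
    ``carrier_mort`` for CNV carriers.
    """
    for v in (base_mort, carrier_mort):
        if not 0.0 <= v <= 1.0:
            raise ValueError("mortalities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    carrier = (
        truth.cnv_carrier
        if len(truth.cnv_carrier)
        else np.zeros(len(samples), dtype=bool)
    )
    p_dead = np.where(carrier, carrier_mort, base_mort)
    dead = rng.random(len(samples)) < p_dead
    df = pd.DataFrame(
        {
            "sample_id": list(samples),
            "location": [locations[p] for p in truth.population[: len(samples)]],
            "insecticide": insecticide,
            "phenotype": np.where(dead, "susceptible", "resistant"),
            "contamination": 0.0,
            "sib_group": [g if g is not None else pd.NA for g in truth.sib_group]
            if truth.sib_group
            else pd.NA,
        }
    )
    return SampleTable(df)


def make_sib_pairs(
    h: HaplotypeSet, truth: TruthSet, n_pairs: int, seed: int
) -> tuple[HaplotypeSet, TruthSet]:
    """Replace the last ``2*n_pairs`` samples with full-sib pairs.

    Each pair of children draws, independently per block, one of the two
    haplotypes of each of two shared parents (free recombination between
    blocks). Parents are drawn from within a single population and are
    consumed: the children take their column slots, keeping cohort size
    and population labels unchanged.
    """
    samples = h.samples
    n_samples = len(samples)
    if 2 * n_pairs > n_samples:
        raise ValueError("n_pairs exceeds available founders / 2")
    rng = np.random.default_rng(seed)
    alleles = h.alleles.copy()
    sib_group = list(truth.sib_group) if truth.sib_group else [None] * n_samples
    sweep_member = truth.sweep_member.copy()
    # consume founder slots from the end of population 0's range
    pop0 = np.flatnonzero(truth.population == 0)
    if len(pop0) < 2 * n_pairs:
        raise ValueError("population 0 too small for requested sib pairs")
    slots = pop0[-2 * n_pairs:]
    parent_pool = pop0[: len(pop0) - 2 * n_pairs]
    if len(parent_pool) < 2:
        raise ValueError("not enough founders left to serve as parents")
    for k in range(n_pairs):
        pa, pb = rng.choice(parent_pool, size=2, replace=False)
        child_a, child_b = slots[2 * k], slots[2 * k + 1]
        for child in (child_a, child_b):
            cols = [2 * child, 2 * child + 1]
            new_sweep = [False, False]
            for lo, hi in truth.block_bounds:
                pick_a = 2 * pa + rng.integers(2)
                pick_b = 2 * pb + rng.integers(2)
                alleles[lo:hi, cols[0]] = h.alleles[lo:hi, pick_a]
                alleles[lo:hi, cols[1]] = h.alleles[lo:hi, pick_b]
                # child inherits sweep membership if the focal-block copy came
                # from a swept parental haplotype
                if truth.causal_sites and lo == truth.causal_sites[0]:
                    new_sweep = [sweep_member[pick_a], sweep_member[pick_b]]
            sweep_member[cols[0]], sweep_member[cols[1]] = new_sweep
            sib_group[child] = f"sib{k}"
    new_truth = TruthSet(**{**truth.__dict__})
    new_truth.sib_group = sib_group
    new_truth.sweep_member = sweep_member
    return HaplotypeSet(list(h.sites), list(h.haplotypes), alleles), new_truth


def simulate_contamination(
    st: SampleTable,
    seed: int,
    g: Optional[GenotypeSet] = None,
    target_site: Optional[int] = None,
    effect: float = 0.0,
    max_fraction: float = 0.05,
) -> tuple[SampleTable, Optional[GenotypeSet]]:
    """Draw contamination fractions Uniform(0, ``max_fraction``).

    If ``target_site`` is given, the genotype at that site is re-drawn so
    its alt dosage correlates with contamination: the per-sample alt
    allele probability is logistic in the standardised contamination with
    slope ``effect`` (effect 0 leaves the site independent).
    """
    rng = np.random.default_rng(seed)
    n = len(st.sample_ids)
    contam = rng.uniform(0.0, max_fraction, size=n)
    df = st.df.copy()
    df["contamination"] = contam
    new_g = g
    if target_site is not None:
        if g is None:
            raise ValueError("target_site requires a GenotypeSet")
        z = (contam - contam.mean()) / (contam.std() or 1.0)
        p_alt = 1.0 / (1.0 + np.exp(-(np.log(0.3 / 0.7) + effect * z)))
        dose = rng.binomial(2, p_alt).astype(np.int8)
        calls = g.calls.copy()
        calls[target_site] = dose
        new_g = GenotypeSet(list(g.sites), list(g.samples), calls)
    return SampleTable(df), new_g


def select_case_control(
    g: GenotypeSet,
    h: HaplotypeSet,
    cov: CoverageMatrix,
    st: SampleTable,
    truth: TruthSet,
    n_per_class: int,
    seed: int,
) -> tuple[GenotypeSet, HaplotypeSet, CoverageMatrix, SampleTable, TruthSet]:
    """Emulate the sequencing design: from the assayed pool, draw equal
    numbers of dead (susceptible) and alive (resistant) mosquitoes.

    Field studies phenotype a large bioassay pool and then sequence a
    roughly balanced case-control subset; downstream scans operate on
    that subset, not the pool.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(st.sample_ids, dtype=object)
    pheno = st.df["phenotype"].to_numpy()
    chosen: list[str] = []
    for cls in ("resistant", "susceptible"):
        pool = np.flatnonzero(pheno == cls)
        if len(pool) < n_per_class:
            raise ValueError(
                f"pool has only {len(pool)} {cls} samples, need {n_per_class}"
            )
        pick = np.sort(rng.choice(pool, size=n_per_class, replace=False))
        chosen.extend(ids[pick])
    chosen = [s for s in st.sample_ids if s in set(chosen)]  # original order
    idx = [st.sample_ids.index(s) for s in chosen]
    hap_idx = np.array([[2 * i, 2 * i + 1] for i in idx]).ravel()
    new_truth = TruthSet(**{**truth.__dict__})
    new_truth.sweep_member = truth.sweep_member[hap_idx]
    new_truth.population = truth.population[idx]
    if len(truth.cnv_carrier):
        new_truth.cnv_carrier = truth.cnv_carrier[idx]
        new_truth.true_copy_number = truth.true_copy_number[idx]
    new_truth.sib_group = [truth.sib_group[i] for i in idx]
    cov_idx = [cov.samples.index(s) for s in chosen]
    new_cov = CoverageMatrix(
        cov.contig, cov.starts, chosen, cov.values[cov_idx]
    )
    return (
        g.take_samples(chosen),
        h.take_samples(chosen),
        new_cov,
        st.subset(chosen),
        new_truth,
    )


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[GenotypeSet, HaplotypeSet, CoverageMatrix, SampleTable, TruthSet]:
    """Full synthetic dataset: haplotypes, sweep, sibs, CNV coverage,
    phenotypes and contamination, all seeded from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=6)
    h, truth = simulate_haplotypes(cfg)
    if cfg.sweep_fraction > 0:
        h, truth = implant_sweep(
            h,
            truth,
            cfg.sweep_block,
            cfg.sweep_fraction,
            cfg.sweep_mut_rate,
            int(seeds[0]),
            population=cfg.sweep_population,
            core_population=cfg.sweep_core_population,
        )
    if cfg.n_sib_pairs > 0:
        h, truth = make_sib_pairs(h, truth, cfg.n_sib_pairs, int(seeds[1]))
    cov, truth = assign_cnv_and_coverage(
        truth,
        cfg.cnv_region,
        cfg.cnv_extra_copies,
        cfg.cnv_link_p,
        cfg.coverage_noise_sd,
        int(seeds[2]),
        contig_bp=cfg.n_blocks * cfg.block_bp,
        samples=h.samples,
    )
    st = simulate_phenotypes(
        truth, h.samples, cfg.base_mortality, cfg.carrier_mortality, int(seeds[3])
    )
    g = to_genotype_set(h)
    st, _ = simulate_contamination(
        st, int(seeds[4]), max_fraction=cfg.contamination_max
    )
    return g, h, cov, st, truth


def sweep_study_config(seed: int, shared_sweep: bool = False) -> SimConfig:
    """Study conditions for the single-location sweep/CNV experiment.

    One bioassayed focal population (pool of 1100) plus a handful of
    diverged donors, 16 independent 400-SNP blocks, a migrant-core sweep
    at carrier fraction 0.6 in block 3 fully linked to a multi-copy CNV,
    and the bioassay mortalities 44.2% (non-carriers) vs 16.7% (CNV
    carriers). The swept haplotype is drawn from the diverged population
    so it is distinguishable from the local background — the situation
    in which resistance sweeps are detectable by frequency-based scans.
    ``shared_sweep`` detaches the sweep from the phenotype (no CNV
    linkage, so mortality is the non-carrier rate for everyone): the
    sweep is then shared equally by both phenotype classes.
    """
    return SimConfig(
        n_samples=(1100, 4),
        n_blocks=16,
        sites_per_block=400,
        theta=40.0,
        divergence=0.5,
        sweep_block=3,
        sweep_fraction=0.6,
        sweep_mut_rate=0.25,
        sweep_population=0,
        sweep_core_population=1,
        cnv_link_p=0.0 if shared_sweep else 1.0,
        n_sib_pairs=0,
        seed=seed,
    )


def simulate_study_cohort(
    seed: int, n_per_class: int = 200, shared_sweep: bool = False
) -> tuple[GenotypeSet, HaplotypeSet, CoverageMatrix, SampleTable, TruthSet]:
    """Sweep-study dataset after case-control sequencing selection.

    Mirrors the field design: phenotype the assayed focal-population
    pool, then sequence ``n_per_class`` dead and ``n_per_class`` alive
    mosquitoes (the diverged donor samples are not sequenced).
    """
    cfg = sweep_study_config(seed, shared_sweep=shared_sweep)
    g, h, cov, st, truth = simulate_dataset(cfg)
    focal = [
        s for i, s in enumerate(st.sample_ids) if truth.population[i] == 0
    ]
    idx = [st.sample_ids.index(s) for s in focal]
    hap_idx = np.array([[2 * i, 2 * i + 1] for i in idx]).ravel()
    sub_truth = TruthSet(**{**truth.__dict__})
    sub_truth.sweep_member = truth.sweep_member[hap_idx]
    sub_truth.population = truth.population[idx]
    sub_truth.cnv_carrier = truth.cnv_carrier[idx]
    sub_truth.true_copy_number = truth.true_copy_number[idx]
    sub_truth.sib_group = [truth.sib_group[i] for i in idx]
    cov_idx = [cov.samples.index(s) for s in focal]
    sub_cov = CoverageMatrix(cov.contig, cov.starts, focal, cov.values[cov_idx])
    return select_case_control(
        g.take_samples(focal),
        h.take_samples(focal),
        sub_cov,
        st.subset(focal),
        sub_truth,
        n_per_class,
        seed + 1,
    )
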