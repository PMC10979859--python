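"""KING-robust kinship, sib-group detection and sib-aware sample retention.

The KING-robust estimator for a pair (i, j) over the loci called in both is

    phi = (N_HetHet - 2 * N_OppHom) / (N_Het(i) + N_Het(j))

where N_HetHet counts loci heterozygous in both samples, N_OppHom counts
opposite homozygotes, and N_Het(.) counts each sample's heterozygous loci
restricted to the shared calls. phi is ~0.25 for full sibs and ~0.5 for a
self-comparison, and is robust to population structure. Regions of known
inversions are excluded before counting, since inversion genotypes mimic
relatedness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core_io import MISSING, GeneRegion, GenotypeSet, SampleTable

__all__ = [
    "KinshipMatrix",
    "SibGroup",
    "king_kinship",
    "find_sib_groups",
    "flag_contaminated",
    "dedup_sibs",
    "sib_retention_permutations",
]


@dataclass
class KinshipMatrix:
    samples: list[str]
    phi: np.ndarray  # (n, n), NaN where undefined
    n_loci: np.ndarray  # (n, n) informative shared loci

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.samples)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    (self.samples[i], self.samples[j], self.phi[i, j], self.n_loci[i, j])
                )
        return pd.DataFrame(rows, columns=["sample_a", "sample_b", "king", "n_loci"])


@dataclass
class SibGroup:
    group_id: str
    members: list[str]


def king_kinship(
    g: GenotypeSet, exclude_regions: Sequence[GeneRegion] = ()
) -> KinshipMatrix:
    """Pairwise KING-robust kinship from called genotypes.

    Sites falling inside ``exclude_regions`` are removed first. Pairs
    with a zero denominator get NaN.
    """
    keep = np.ones(g.n_sites, dtype=bool)
    for r in exclude_regions:
        for i, site in enumerate(g.sites):
            if keep[i] and r.contains_pos(site.contig, site.pos):
                keep[i] = False
    calls = g.calls[keep]
    het = (calls == 1).astype(np.float64)
    hom_ref = (calls == 0).astype(np.float64)
    hom_alt = (calls == 2).astype(np.float64)
    valid = (calls != MISSING).astype(np.float64)
    n_hethet = het.T @ het
    n_opphom = hom_ref.T @ hom_alt + hom_alt.T @ hom_ref
    het_shared = het.T @ valid  # [i, j] = het in i among loci called in j
    denom = het_shared + het_shared.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(denom > 0, (n_hethet - 2.0 * n_opphom) / denom, np.nan)
    n_loci = (valid.T @ valid).astype(np.int64)
    return KinshipMatrix(list(g.samples), phi, n_loci)


def find_sib_groups(k: KinshipMatrix, threshold: float = 0.185) -> list[SibGroup]:
    """Sib groups = connected components of the phi >= threshold graph.

    Singleton components are dropped; groups are ordered and named by
    their lowest member index so output is deterministic.
    """
    n = len(k.samples)
    adj = np.nan_to_num(k.phi, nan=-np.inf) >= threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: list[SibGroup] = []
    for comp in range(n_comp):
        members = [k.samples[i] for i in range(n) if labels[i] == comp]
        if len(members) >= 2:
            groups.append(SibGroup(group_id=f"sib_{len(groups)}", members=members))
    return groups


def flag_contaminated(
    k: KinshipMatrix,
    g: GenotypeSet,
    kin_quantile: float = 0.99,
    het_z: float = 4.0,
) -> list[str]:
    """Flag cross-contaminated samples.

    Contamination inflates heterozygosity and drags every pairwise KING
    value upward, so a sample is flagged when its median kinship to all
    others exceeds the ``kin_quantile`` quantile of the off-diagonal
    kinship distribution AND its heterozygosity z-score (vs the cohort)
    exceeds ``het_z``.
    """
    n = len(k.samples)
    if n < 2:
        return []
    off = k.phi[~np.eye(n, dtype=bool)]
    off = off[~np.isnan(off)]
    if off.size == 0:
        return []
    cutoff = np.quantile(off, kin_quantile)
    med_kin = np.array(
        [
            np.nanmedian(np.concatenate([k.phi[i, :i], k.phi[i, i + 1:]]))
            for i in range(n)
        ]
    )
    called = g.calls != MISSING
    with np.errstate(invalid="ignore"):
        het_rate = (g.calls == 1).sum(axis=0) / called.sum(axis=0)
    mu, sd = het_rate.mean(), het_rate.std(ddof=1)
    z = (het_rate - mu) / sd if sd > 0 else np.zeros(n)
    flags = (med_kin > cutoff) & (z > het_z)
    return [k.samples[i] for i in np.flatnonzero(flags)]


def _retained(
    st: SampleTable, groups: Sequence[SibGroup], rng: np.random.Generator
) -> list[str]:
    drop: set[str] = set()
    for grp in groups:
        keep = grp.members[rng.integers(len(grp.members))]
        drop.update(m for m in grp.members if m != keep)
    return [s for s in st.sample_ids if s not in drop]


def dedup_sibs(
    st: SampleTable, groups: Sequence[SibGroup], seed: int
) -> list[str]:
    """Retain one random member per sib group plus all non-sib samples."""
    return _retained(st, groups, np.random.default_rng(seed))


def sib_retention_permutations(
    st: SampleTable, groups: Sequence[SibGroup], n_perm: int, seed: int
) -> Iterator[list[str]]:
    """Yield ``n_perm`` retained-sample lists differing only in which sib
    is kept per group; deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        yield _retained(st, groups, rng)
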