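"""Haplotype clustering by pairwise distance and cluster-phenotype tests.

Swept haplotypes are near-identical, so hierarchical clustering of the
pairwise distance Dxy (proportion of differing sites) with the tree cut
at a small height groups them into clusters. Clusters of at least
``min_size`` haplotypes are tested for association with the bioassay
phenotype by a binomial-logit GLM with the per-sample haplotype dose
(0, 1 or 2 copies of the cluster) as the predictor. A differentiation
peak is only believed when it contains a cluster positively associated
with resistance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import HaplotypeSet, SampleTable, SNPWindow
from .differentiation import PeakEntry, PeakSet
from .association import glm_binomial

__all__ = [
    "HapCluster",
    "HapClusterSet",
    "pairwise_dxy",
    "cluster_haplotypes",
    "cluster_association",
    "filter_peaks_by_cluster",
]


@dataclass
class HapCluster:
    cluster_id: int
    members: list[int]  # haplotype column indices
    testable: bool
    p_value: Optional[float] = None
    coefficient: Optional[float] = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HapClusterSet:
    region: Optional[SNPWindow]
    clusters: list[HapCluster]
    min_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": [c.cluster_id for c in self.clusters],
                "size": [c.size for c in self.clusters],
                "testable": [c.testable for c in self.clusters],
                "p_value": [c.p_value for c in self.clusters],
                "coefficient": [c.coefficient for c in self.clusters],
            }
        )


def pairwise_dxy(h: HaplotypeSet, window: Optional[SNPWindow] = None) -> np.ndarray:
    """Dxy matrix: proportion of differing alleles between haplotype pairs
    over the window's sites (all sites when no window given)."""
    alleles = h.alleles if window is None else h.alleles[window.indices]
    if alleles.shape[0] == 0:
        raise ValueError("no sites in region")
    x = alleles.T.astype(np.float64)
    diff = x @ (1 - x).T
    d = (diff + diff.T) / alleles.shape[0]
    np.fill_diagonal(d, 0.0)
    return d


def cluster_haplotypes(
    distmat: np.ndarray,
    cut_height: float = 0.001,
    min_size: int = 20,
    region: Optional[SNPWindow] = None,
) -> HapClusterSet:
    """Average-linkage (UPGMA) clustering, tree cut at ``cut_height``.

    All clusters are kept; those below ``min_size`` are flagged
    untestable. Cluster ids are assigned by decreasing size then lowest
    member index, so output is deterministic.
    """
    n = distmat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes to cluster")
    condensed = squareform(distmat, checks=False)
    z = linkage(condensed, method="average")
    flat = fcluster(z, t=cut_height, criterion="distance")
    raw: dict[int, list[int]] = {}
    for i, c in enumerate(flat):
        raw.setdefault(int(c), []).append(i)
    ordered = sorted(raw.values(), key=lambda m: (-len(m), m[0]))
    clusters = [
        HapCluster(cluster_id=k, members=m, testable=len(m) >= min_size)
        for k, m in enumerate(ordered)
    ]
    return HapClusterSet(region=region, clusters=clusters, min_size=min_size)


def cluster_association(
    clusters: HapClusterSet, h: HaplotypeSet, st: SampleTable
) -> HapClusterSet:
    """Binomial-logit GLM of phenotype on per-sample cluster dose.

    Dose is the number of the sample's two haplotypes belonging to the
    cluster. Only testable (size >= min_size) clusters get p-values.
    """
    samples = h.samples
    y = st.phenotype_binary(samples)
    col_of_sample = {s: h.sample_columns(s) for s in samples}
    for cl in clusters.clusters:
        if not cl.testable:
            continue
        member_set = set(cl.members)
        dose = np.array(
            [sum(c in member_set for c in col_of_sample[s]) for s in samples],
            dtype=float,
        )
        res = glm_binomial(y, pd.DataFrame({"dose": dose}))
        if "dose" not in res.terms:  # constant dose: no test possible
            cl.p_value, cl.coefficient = None, None
            continue
        i = res.terms.index("dose")
        cl.coefficient = float(res.coefficients[i])
        cl.p_value = float(res.term_p(i))
    return clusters


def filter_peaks_by_cluster(
    peaks: PeakSet,
    h: HaplotypeSet,
    st: SampleTable,
    cut_height: float = 0.001,
    min_size: int = 20,
    alpha: float = 0.05,
) -> PeakSet:
    """Discard peaks lacking a haplotype cluster positively associated
    with resistance (coefficient > 0 and p < ``alpha``)."""
    kept: list[PeakEntry] = []
    positions = h.positions()
    for entry in peaks.entries:
        if not entry.retained:
            kept.append(entry)
            continue
        # peak windows may index a filtered site grid; re-anchor on h by
        # position span so the clustered sites are the genomic interval
        w = entry.window
        idx = np.flatnonzero(
            (positions >= w.first_pos)
            & (positions <= w.last_pos)
            & np.array([s.contig == w.contig for s in h.sites])
        )
        if idx.size < 2:
            kept.append(PeakEntry(w, entry.observed, entry.p_empirical, False))
            continue
        local = SNPWindow(
            w.contig, int(idx[0]), int(idx[-1]),
            int(positions[idx[0]]), int(positions[idx[-1]]),
        )
        d = pairwise_dxy(h, local)
        clusters = cluster_haplotypes(
            d, cut_height=cut_height, min_size=min_size, region=entry.window
        )
        clusters = cluster_association(clusters, h, st)
        ok = any(
            c.p_value is not None
            and c.coefficient is not None
            and c.coefficient > 0
            and c.p_value < alpha
            for c in clusters.clusters
        )
        kept.append(
            PeakEntry(entry.window, entry.observed, entry.p_empirical, ok)
        )
    return PeakSet(peaks.statistic, kept)
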