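"""Windowed Hudson FST, the population branch statistic, peak-candidate
rules and the phenotype-permutation false-positive filter.

Windowed FST is the ratio of sums: per-site Hudson numerators and
denominators are summed within each SNP window before dividing, which is
robust to near-monomorphic sites. PBS for a focal group f against sister
s and outgroup o is (T_fs + T_fo - T_so) / 2 with T = -ln(1 - FST),
isolating allele-frequency change on the focal branch.

Peak candidates come from either the mode-based rule (positive values
more than three times further from the mode of the genome-wide
distribution than its smallest negative value) or a centile rule
(multiplier x a centile of the track). Candidates are then re-tested
against an empirical null built by permuting phenotype labels within
location strata: a sweep present in both phenotype classes produces a
real peak in the observed scan but survives permutation, so it is
filtered out; only phenotype-linked differentiation is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .core_io import (
    MISSING,
    GenotypeSet,
    SampleTable,
    SNPWindow,
    make_snp_windows,
)
from .kinship import SibGroup, sib_retention_permutations
from .selection import WindowStatTrack, garud_h, hap_frequencies
from .core_io import HaplotypeSet

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSet",
    "hudson_fst_components",
    "fst_scan",
    "fst_scan_sib_averaged",
    "pbs_scan",
    "fst_peak_threshold",
    "pbs_from_fst",
    "centile_peak_threshold",
    "candidate_windows_above",
    "permutation_filter",
    "make_fst_recompute",
    "make_delta_h12_recompute",
    "make_h12_recompute",
]

FST_CLIP = 1.0 - 1e-12


@dataclass
class PeakEntry:
    window: SNPWindow
    observed: float
    p_empirical: Optional[float]
    retained: bool


@dataclass
class PeakSet:
    statistic: str
    entries: list[PeakEntry]

    @property
    def retained(self) -> list[PeakEntry]:
        return [e for e in self.entries if e.retained]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [e.window.contig for e in self.entries],
                "first_pos": [e.window.first_pos for e in self.entries],
                "last_pos": [e.window.last_pos for e in self.entries],
                "observed": [e.observed for e in self.entries],
                "p_empirical": [e.p_empirical for e in self.entries],
                "retained": [e.retained for e in self.entries],
            }
        )


# ---------------------------------------------------------------------------
# Hudson FST and windowed scans
# ---------------------------------------------------------------------------


def hudson_fst_components(
    ac1: np.ndarray, ac2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson estimator components.

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    where p is the alt-allele frequency and n the allele count in each
    population. Both populations need at least 2 called alleles per site.
    """
    ac1 = np.asarray(ac1, dtype=float)
    ac2 = np.asarray(ac2, dtype=float)
    n1 = ac1.sum(axis=1)
    n2 = ac2.sum(axis=1)
    if (n1 < 2).any() or (n2 < 2).any():
        raise ValueError("need >= 2 called alleles per population per site")
    p1 = ac1[:, 1] / n1
    p2 = ac2[:, 1] / n2
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _fst_site_mask(
    g: GenotypeSet, sample_groups: Sequence[Sequence[str]]
) -> np.ndarray:
    """Sites usable for FST: no missing call in any group, combined minor
    allele count > 1 (singleton and monomorphic sites removed)."""
    lookup = {s: i for i, s in enumerate(g.samples)}
    cols = [lookup[s] for grp in sample_groups for s in grp]
    sub = g.calls[:, cols]
    no_missing = (sub != MISSING).all(axis=1)
    alt = np.where(sub != MISSING, sub, 0).sum(axis=1)
    total = 2 * sub.shape[1]
    mac = np.minimum(alt, total - alt)
    return no_missing & (mac > 1)


def _windowed_ratio_of_sums(
    num: np.ndarray, den: np.ndarray, windows: Sequence[SNPWindow]
) -> np.ndarray:
    vals = np.empty(len(windows))
    for i, w in enumerate(windows):
        d = den[w.indices].sum()
        vals[i] = num[w.indices].sum() / d if d > 0 else np.nan
    return vals


def _group_allele_counts(
    g: GenotypeSet, ids: Sequence[str], site_idx: np.ndarray
) -> np.ndarray:
    lookup = {s: i for i, s in enumerate(g.samples)}
    cols = [lookup[s] for s in ids]
    calls = g.calls[np.ix_(site_idx, cols)]
    called = calls != MISSING
    alt = np.where(called, calls, 0).sum(axis=1)
    total = 2 * called.sum(axis=1)
    return np.stack([total - alt, alt], axis=1)


def fst_scan(
    g: GenotypeSet,
    group1: Sequence[str],
    group2: Sequence[str],
    window_size: int = 1000,
    windows: Optional[list[SNPWindow]] = None,
    site_idx: Optional[np.ndarray] = None,
) -> WindowStatTrack:
    """Windowed Hudson FST (ratio of sums) between two sample groups.

    Sites with missing calls in either group or combined minor allele
    count <= 1 are excluded before windows are laid down. Passing
    ``windows``/``site_idx`` pins the grid (used by permutations).
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs at least 2 samples")
    if site_idx is None:
        site_idx = np.flatnonzero(_fst_site_mask(g, [group1, group2]))
    sites = [g.sites[i] for i in site_idx]
    if windows is None:
        windows = make_snp_windows(sites, window_size)
    ac1 = _group_allele_counts(g, group1, site_idx)
    ac2 = _group_allele_counts(g, group2, site_idx)
    num, den = hudson_fst_components(ac1, ac2)
    vals = _windowed_ratio_of_sums(num, den, windows)
    return WindowStatTrack("fst", windows, vals, labels={"site_idx": site_idx})


def fst_scan_sib_averaged(
    g: GenotypeSet,
    st: SampleTable,
    sib_groups: Sequence[SibGroup],
    n_perm: int = 100,
    seed: int = 0,
    window_size: int = 1000,
) -> WindowStatTrack:
    """Mean of windowed FST over sib-retention permutations.

    Each permutation keeps one random member per sib group; the
    resistant-vs-susceptible track is recomputed on the retained samples
    (on a fixed site/window grid) and the tracks are averaged.
    """
    resistant = set(st.group_ids("phenotype", "resistant"))
    susceptible = set(st.group_ids("phenotype", "susceptible"))
    site_idx = np.flatnonzero(
        _fst_site_mask(g, [sorted(resistant), sorted(susceptible)])
    )
    sites = [g.sites[i] for i in site_idx]
    windows = make_snp_windows(sites, window_size)
    acc = np.zeros(len(windows))
    for retained in sib_retention_permutations(st, sib_groups, n_perm, seed):
        r = [s for s in retained if s in resistant]
        s_ = [s for s in retained if s in susceptible]
        track = fst_scan(g, r, s_, windows=windows, site_idx=site_idx)
        acc += track.values
    return WindowStatTrack("fst_sib_mean", windows, acc / n_perm)


def pbs_from_fst(
    fst_fs: np.ndarray, fst_fo: np.ndarray, fst_so: np.ndarray
) -> np.ndarray:
    """PBS of the focal branch from the three pairwise FST values:
    (T_fs + T_fo - T_so) / 2 with T = -ln(1 - FST), FST clipped below 1."""

    def t(x: np.ndarray) -> np.ndarray:
        return -np.log(1.0 - np.clip(np.asarray(x, dtype=float), None, FST_CLIP))

    return (t(fst_fs) + t(fst_fo) - t(fst_so)) / 2.0


def pbs_scan(
    g: GenotypeSet,
    focal: Sequence[str],
    sister: Sequence[str],
    outgroup: Sequence[str],
    window_size: int = 1000,
) -> WindowStatTrack:
    """Population branch statistic of the focal group per SNP window.

    Sites are restricted to those segregating across the union of the
    three groups with no missing calls; windowed pairwise FST values are
    clipped just below 1 before the log transform.
    """
    if set(focal) & set(sister) or set(focal) & set(outgroup) or set(sister) & set(outgroup):
        raise ValueError("the three sample groups must be disjoint")
    site_idx = np.flatnonzero(_fst_site_mask(g, [focal, sister, outgroup]))
    sites = [g.sites[i] for i in site_idx]
    windows = make_snp_windows(sites, window_size)
    acs = {
        name: _group_allele_counts(g, ids, site_idx)
        for name, ids in (("f", focal), ("s", sister), ("o", outgroup))
    }

    def wfst(a: str, b: str) -> np.ndarray:
        num, den = hudson_fst_components(acs[a], acs[b])
        fst = _windowed_ratio_of_sums(num, den, windows)
        if np.isnan(fst).any():
            raise ValueError("pairwise FST undefined in a window")
        return fst

    pbs = pbs_from_fst(wfst("f", "s"), wfst("f", "o"), wfst("s", "o"))
    return WindowStatTrack("pbs", windows, pbs)


# ---------------------------------------------------------------------------
# Peak-candidate rules
# ---------------------------------------------------------------------------


def fst_peak_threshold(values: np.ndarray) -> tuple[float, Optional[float]]:
    """Mode-based peak threshold for a windowed FST track.

    The mode is a Gaussian KDE argmax (Silverman bandwidth, 512-point
    grid over the data range); the threshold is
    mode + 3 * (mode - min(values)). Requires at least one negative
    value; otherwise the threshold is undefined (None) and a warning is
    logged.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), 512)
    mode = float(grid[np.argmax(kde(grid))])
    vmin = float(values.min())
    if vmin >= 0:
        logger.warning("no negative FST values: peak threshold undefined")
        return mode, None
    return mode, mode + 3.0 * (mode - vmin)


def centile_peak_threshold(
    values: np.ndarray, centile: float, multiplier: float = 3.0
) -> float:
    """multiplier x the linear-interpolation centile of the track."""
    values = np.asarray(values, dtype=float)
    return float(multiplier * np.percentile(values[~np.isnan(values)], centile))


def candidate_windows_above(
    track: WindowStatTrack, threshold: Optional[float], positive_only: bool = True
) -> list[int]:
    """Indices of windows strictly above threshold (and > 0 if required)."""
    if threshold is None:
        return []
    vals = track.values
    mask = vals > threshold
    if positive_only:
        mask &= vals > 0
    return [int(i) for i in np.flatnonzero(mask)]


# ---------------------------------------------------------------------------
# Phenotype-permutation filter
# ---------------------------------------------------------------------------


def _permute_within_strata(
    labels: np.ndarray, strata: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = labels.copy()
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        out[idx] = labels[rng.permutation(idx)]
    return out


def permutation_filter(
    observed: np.ndarray,
    candidate_windows: list[SNPWindow],
    st: SampleTable,
    recompute: Callable[[np.ndarray], np.ndarray],
    n_perm: int = 500,
    retain_quantile: float = 0.99,
    seed: int = 0,
    statistic: str = "fst",
) -> PeakSet:
    """Empirical-null filter for candidate peaks.

    Phenotype labels are permuted within location strata; ``recompute``
    maps a permuted label vector (aligned to ``st.sample_ids``) to the
    statistic's values on the candidate windows. A peak is retained iff
    its observed value is strictly greater than the ``retain_quantile``
    empirical quantile of its permuted values; the counting p-value
    (1 + #{perm >= obs}) / (n_perm + 1) is reported alongside.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: retention quantile unstable", n_perm)
    observed = np.asarray(observed, dtype=float)
    if len(observed) != len(candidate_windows):
        raise ValueError("one observed value per candidate window required")
    if not candidate_windows:
        return PeakSet(statistic, [])
    rng = np.random.default_rng(seed)
    labels = np.asarray(
        st.df["phenotype"].to_numpy(), dtype=object
    )
    strata = st.df["location"].to_numpy()
    perm_vals = np.empty((n_perm, len(candidate_windows)))
    for p in range(n_perm):
        perm_vals[p] = recompute(_permute_within_strata(labels, strata, rng))
    entries: list[PeakEntry] = []
    for j, w in enumerate(candidate_windows):
        obs = observed[j]
        q = np.quantile(perm_vals[:, j], retain_quantile)
        p_emp = (1 + int((perm_vals[:, j] >= obs).sum())) / (n_perm + 1)
        entries.append(PeakEntry(w, float(obs), p_emp, bool(obs > q)))
    return PeakSet(statistic, entries)


def make_fst_recompute(
    g: GenotypeSet,
    st: SampleTable,
    candidate_windows: list[SNPWindow],
    site_idx: np.ndarray,
) -> Callable[[np.ndarray], np.ndarray]:
    """Recompute windowed FST on candidate windows for permuted labels."""
    ids = np.asarray(st.sample_ids, dtype=object)

    def recompute(labels: np.ndarray) -> np.ndarray:
        r = list(ids[labels == "resistant"])
        s = list(ids[labels == "susceptible"])
        track = fst_scan(g, r, s, windows=candidate_windows, site_idx=site_idx)
        return track.values

    return recompute


def make_delta_h12_recompute(
    h: HaplotypeSet, st: SampleTable, candidate_windows: list[SNPWindow]
) -> Callable[[np.ndarray], np.ndarray]:
    ids = np.asarray(st.sample_ids, dtype=object)

    def _h12_for(samples: list[str]) -> np.ndarray:
        sub = h.take_samples(samples)
        return np.array(
            [garud_h(hap_frequencies(sub, w))[1] for w in candidate_windows]
        )

    def recompute(labels: np.ndarray) -> np.ndarray:
        res = list(ids[labels == "resistant"])
        sus = list(ids[labels == "susceptible"])
        return _h12_for(res) - _h12_for(sus)

    return recompute


def make_h12_recompute(
    h: HaplotypeSet, st: SampleTable, candidate_windows: list[SNPWindow]
) -> Callable[[np.ndarray], np.ndarray]:
    """H12 of the (permuted) resistant class on the candidate windows."""
    ids = np.asarray(st.sample_ids, dtype=object)

    def recompute(labels: np.ndarray) -> np.ndarray:
        res = list(ids[labels == "resistant"])
        sub = h.take_samples(res)
        return np.array(
            [garud_h(hap_frequencies(sub, w))[1] for w in candidate_windows]
        )

    return recompute
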