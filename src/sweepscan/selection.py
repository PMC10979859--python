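"""Haplotype-frequency selection statistics: H1, H12, H1X and their scans.

H1 = sum p_i^2 over the haplotype frequency spectrum of a window; H12
pools the two most frequent haplotypes before squaring,
H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2, which makes it sensitive to soft
sweeps where two haplotypes share the rise in frequency. H1X measures
haplotype sharing between two cohorts: the sum over distinct haplotypes
of the product of their frequencies in each cohort. dH12 (H12 in
resistant minus H12 in susceptible samples) localises sweeps that are
enriched in the resistant phenotype class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import HaplotypeSet, SNPWindow, make_snp_windows

__all__ = [
    "WindowStatTrack",
    "hap_frequencies",
    "hap_frequency_table",
    "garud_h",
    "h1x",
    "h12_scan",
    "h1x_scan",
    "delta_h12",
]


@dataclass
class WindowStatTrack:
    """Windowed values of one statistic over a shared SNP-window grid."""

    statistic: str
    windows: list[SNPWindow]
    values: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.windows):
            raise ValueError("one value per window required")

    def argmax(self) -> int:
        return int(np.argmax(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [w.contig for w in self.windows],
                "first_pos": [w.first_pos for w in self.windows],
                "last_pos": [w.last_pos for w in self.windows],
                "n_snps": [w.n_snps for w in self.windows],
                self.statistic: self.values,
            }
        )


def hap_frequency_table(h: HaplotypeSet, w: SNPWindow) -> dict[bytes, float]:
    """Distinct haplotype strings in the window -> frequency."""
    block = np.ascontiguousarray(h.alleles[w.indices].T)
    counts: dict[bytes, int] = {}
    for row in block:
        key = row.tobytes()
        counts[key] = counts.get(key, 0) + 1
    n = block.shape[0]
    return {k: c / n for k, c in counts.items()}


def hap_frequencies(h: HaplotypeSet, w: SNPWindow) -> np.ndarray:
    """Haplotype frequency spectrum of a window, sorted descending."""
    freqs = np.array(sorted(hap_frequency_table(h, w).values(), reverse=True))
    return freqs


def garud_h(freqs: np.ndarray) -> tuple[float, float]:
    """(H1, H12) from a descending frequency spectrum."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty haplotype frequency spectrum")
    if np.any(np.diff(freqs) > 1e-12):
        raise ValueError("spectrum must be sorted descending")
    h1 = float(np.sum(freqs**2))
    if freqs.size == 1:
        return 1.0, 1.0
    h12 = float((freqs[0] + freqs[1]) ** 2 + np.sum(freqs[2:] ** 2))
    return h1, h12


def h1x(freqs_a: dict[bytes, float], freqs_b: dict[bytes, float]) -> float:
    """Cross-population haplotype sharing: sum_i p_ia * p_ib."""
    if len(freqs_b) < len(freqs_a):
        freqs_a, freqs_b = freqs_b, freqs_a
    return float(sum(p * freqs_b.get(k, 0.0) for k, p in freqs_a.items()))


def h12_scan(
    h: HaplotypeSet,
    window_size: int,
    step: Optional[int] = None,
    windows: Optional[list[SNPWindow]] = None,
    label: str = "",
) -> WindowStatTrack:
    """H12 per SNP window (the paired H1 track is in ``labels['h1']``)."""
    if windows is None:
        windows = make_snp_windows(h.sites, window_size, step)
    h1s, h12s = [], []
    for w in windows:
        a, b = garud_h(hap_frequencies(h, w))
        h1s.append(a)
        h12s.append(b)
    return WindowStatTrack(
        "h12", windows, np.array(h12s), labels={"h1": np.array(h1s), "group": label}
    )


def _check_shared_grid(h_a: HaplotypeSet, h_b: HaplotypeSet) -> None:
    if [(s.contig, s.pos) for s in h_a.sites] != [
        (s.contig, s.pos) for s in h_b.sites
    ]:
        raise ValueError("both haplotype sets must share one SNP index set")


def h1x_scan(
    h_a: HaplotypeSet,
    h_b: HaplotypeSet,
    window_size: int,
    step: Optional[int] = None,
    windows: Optional[list[SNPWindow]] = None,
) -> WindowStatTrack:
    _check_shared_grid(h_a, h_b)
    if windows is None:
        windows = make_snp_windows(h_a.sites, window_size, step)
    vals = [
        h1x(hap_frequency_table(h_a, w), hap_frequency_table(h_b, w))
        for w in windows
    ]
    return WindowStatTrack("h1x", windows, np.array(vals))


def delta_h12(
    h_resistant: HaplotypeSet,
    h_susceptible: HaplotypeSet,
    window_size: int,
    step: Optional[int] = None,
    windows: Optional[list[SNPWindow]] = None,
) -> WindowStatTrack:
    """H12(resistant) - H12(susceptible) per window; positive values mean
    swept haplotypes are enriched in the resistant class."""
    _check_shared_grid(h_resistant, h_susceptible)
    if windows is None:
        windows = make_snp_windows(h_resistant.sites, window_size, step)
    res = h12_scan(h_resistant, window_size, windows=windows)
    sus = h12_scan(h_susceptible, window_size, windows=windows)
    return WindowStatTrack("delta_h12", windows, res.values - sus.values)
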