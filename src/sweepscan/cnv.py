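"""Copy-number inference from normalised sequencing coverage.

A hidden Markov model over integer total copy-number states 0..12
(diploid 2 plus up to 10 extra copies) emits normalised coverage in
300-bp windows: emissions are Normal(state value, sigma) on the scale
where diploid coverage is 2.0, with the zero state's mean floored above
zero (deleted sequence still attracts stray reads). Transitions share a
single change probability split equally among non-self states, so state
changes are penalised uniformly and single-window flips are unlikely.
Per-gene copy number is the modal Viterbi state over the windows
overlapping the gene. Amplifications beyond the HMM ceiling are
quantified instead by the median normalised coverage over the CNV region
minus 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import CoverageMatrix, GeneRegion

__all__ = [
    "CoverageHMMParams",
    "CopyNumberCalls",
    "hmm_decode",
    "decode_all",
    "gene_copy_number",
    "gene_copy_number_table",
    "region_median_copy_number",
    "carrier_table",
]


@dataclass
class CoverageHMMParams:
    """HMM parameters; defaults favour contiguous copy-number segments."""

    max_state: int = 12  # diploid 2 + up to 10 extra copies
    sigma: float = 0.5  # emission sd per unit coverage
    transition_p: float = 1e-4  # total probability of leaving a state
    zero_state_mean: float = 0.1
    state_means: Optional[np.ndarray] = None  # override, mostly for testing

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.transition_p < 1.0:
            raise ValueError("transition_p must be in (0, 1)")

    @property
    def n_states(self) -> int:
        return self.max_state + 1

    def means(self) -> np.ndarray:
        if self.state_means is not None:
            return np.asarray(self.state_means, dtype=float)
        m = np.arange(self.n_states, dtype=float)
        m[0] = self.zero_state_mean
        return m


@dataclass
class CopyNumberCalls:
    """Per sample x gene modal copy-number state."""

    samples: list[str]
    genes: list[str]
    modal_state: np.ndarray  # (n_samples, n_genes)

    @property
    def extra_copies(self) -> np.ndarray:
        return self.modal_state - 2

    @property
    def carrier(self) -> np.ndarray:
        return self.extra_copies > 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.modal_state, columns=self.genes)
        df.insert(0, "sample_id", self.samples)
        return df


def hmm_decode(track: np.ndarray, params: CoverageHMMParams) -> np.ndarray:
    """Viterbi path of copy-number states for one sample's coverage track.

    Uniform initial distribution; log-space recursion.
    """
    track = np.asarray(track, dtype=float)
    if track.size == 0:
        raise ValueError("empty coverage track")
    if not np.isfinite(track).all() or (track < 0).any():
        raise ValueError("coverage track must be finite and non-negative")
    k = params.n_states
    means = params.means()
    # emission log-likelihoods, (n_windows, k)
    resid = track[:, None] - means[None, :]
    log_emit = -0.5 * (resid / params.sigma) ** 2  # shared const dropped
    log_stay = np.log1p(-params.transition_p)
    log_move = np.log(params.transition_p / (k - 1))
    n = track.size
    delta = log_emit[0].copy()  # uniform prior: constant dropped
    back = np.zeros((n, k), dtype=np.int64)
    for t in range(1, n):
        # score[i, j] = delta[i] + logA[i, j]
        scores = delta[:, None] + np.where(
            np.eye(k, dtype=bool), log_stay, log_move
        )
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(k)] + log_emit[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def decode_all(
    cov: CoverageMatrix, params: Optional[CoverageHMMParams] = None
) -> np.ndarray:
    """Viterbi states for every sample; shape (n_samples, n_windows)."""
    params = params or CoverageHMMParams()
    return np.stack([hmm_decode(row, params) for row in cov.values])


def gene_copy_number(
    states: np.ndarray,
    region: GeneRegion,
    cov: CoverageMatrix,
) -> int:
    """Modal HMM state over the windows overlapping a gene (ties take the
    lower state)."""
    idx = cov.windows_overlapping(region)
    if idx.size == 0:
        raise ValueError(f"no coverage window overlaps {region.name}")
    counts = np.bincount(np.asarray(states)[idx])
    return int(np.argmax(counts))  # argmax returns the lowest tied state


def gene_copy_number_table(
    cov: CoverageMatrix,
    regions: Sequence[GeneRegion],
    params: Optional[CoverageHMMParams] = None,
    states: Optional[np.ndarray] = None,
) -> CopyNumberCalls:
    if states is None:
        states = decode_all(cov, params)
    modal = np.empty((len(cov.samples), len(regions)), dtype=np.int64)
    for i in range(len(cov.samples)):
        for j, r in enumerate(regions):
            modal[i, j] = gene_copy_number(states[i], r, cov)
    return CopyNumberCalls(list(cov.samples), [r.name for r in regions], modal)


def region_median_copy_number(cov: CoverageMatrix, region: GeneRegion) -> np.ndarray:
    """Per-sample extra copies = median normalised coverage over windows
    fully inside the region, minus 2 (the diploid baseline). Robust to
    amplifications beyond the HMM state ceiling."""
    idx = cov.windows_within(region)
    if idx.size == 0:
        raise ValueError(f"no coverage window fully inside {region.name}")
    return np.median(cov.values[:, idx], axis=1) - 2.0


def carrier_table(calls: CopyNumberCalls) -> pd.DataFrame:
    """Presence/absence coding: carrier iff extra copies > 0."""
    df = pd.DataFrame(calls.carrier.astype(int), columns=calls.genes)
    df.insert(0, "sample_id", calls.samples)
    return df
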