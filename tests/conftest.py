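"""Shared builders for small, fully specified test datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sweepscan.core_io import GenotypeSet, HaplotypeSet, SampleTable, SiteInfo


def make_sites(n: int, contig: str = "2L", start: int = 1, spacing: int = 10):
    return [SiteInfo(contig, start + i * spacing) for i in range(n)]


def make_genotypes(calls: np.ndarray, contig: str = "2L") -> GenotypeSet:
    calls = np.asarray(calls, dtype=np.int8)
    sites = make_sites(calls.shape[0], contig)
    samples = [f"S{i}" for i in range(calls.shape[1])]
    return GenotypeSet(sites, samples, calls)


def make_haplotypes(alleles: np.ndarray, contig: str = "2L") -> HaplotypeSet:
    alleles = np.asarray(alleles, dtype=np.int8)
    n_hap = alleles.shape[1]
    assert n_hap % 2 == 0
    sites = make_sites(alleles.shape[0], contig)
    labels = [(f"S{i // 2}", i % 2) for i in range(n_hap)]
    return HaplotypeSet(sites, labels, alleles)


def make_sample_table(
    samples,
    phenotypes=None,
    locations=None,
    contamination=None,
) -> SampleTable:
    n = len(samples)
    if phenotypes is None:
        phenotypes = ["resistant" if i % 2 == 0 else "susceptible" for i in range(n)]
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": list(samples),
                "location": locations if locations is not None else "Moshi",
                "insecticide": "PM",
                "phenotype": list(phenotypes),
                "contamination": contamination if contamination is not None else 0.0,
            }
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
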