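"""Generator contracts: coalescent diversity, sweep, CNV coverage,
phenotypes, sib pairs, contamination and determinism."""

import numpy as np
import pytest

from sweepscan.cnv import CoverageHMMParams, hmm_decode
from sweepscan.core_io import GeneRegion, to_genotype_set
from sweepscan.selection import garud_h, hap_frequencies
from sweepscan.core_io import SNPWindow
from sweepscan.synthetic_data import (
    SimConfig,
    assign_cnv_and_coverage,
    implant_sweep,
    make_sib_pairs,
    select_case_control,
    simulate_contamination,
    simulate_dataset,
    simulate_haplotypes,
    simulate_phenotypes,
)


def pairwise_diversity(alleles: np.ndarray) -> float:
    n = alleles.shape[1]
    p = alleles.mean(axis=1)
    return float((2 * p * (1 - p) * n / (n - 1)).sum())


def small_cfg(**kw) -> SimConfig:
    base = dict(n_samples=(20, 0), n_blocks=2, sites_per_block=50,
                divergence=0.0, sweep_block=0, n_sib_pairs=0, seed=0)
    base.update(kw)
    return SimConfig(**base)


class TestCoalescent:
    def test_mean_pairwise_diversity_matches_theta(self):
        # E(pi) = theta per block under the neutral coalescent
        theta = 8.0
        pis = []
        for s in range(200):
            cfg = small_cfg(n_samples=(10, 0), n_blocks=1, sites_per_block=None,
                            theta=theta, sweep_fraction=0.0, seed=s)
            h, _ = simulate_haplotypes(cfg)
            pis.append(pairwise_diversity(h.alleles.astype(float)))
        assert np.mean(pis) == pytest.approx(theta, rel=0.10)

    def test_two_haplotypes_single_block(self):
        cfg = small_cfg(n_samples=(1, 0), n_blocks=1, sites_per_block=None,
                        theta=5.0, sweep_fraction=0.0, seed=1)
        h, _ = simulate_haplotypes(cfg)
        assert h.n_haplotypes == 2
        # with 2 haplotypes every mutation is a singleton of one lineage
        assert set(h.alleles.sum(axis=1)) <= {0, 1, 2}

    def test_same_seed_is_deterministic(self):
        cfg = small_cfg(seed=42)
        a = simulate_dataset(cfg)
        b = simulate_dataset(small_cfg(seed=42))
        assert np.array_equal(a[1].alleles, b[1].alleles)
        assert np.allclose(a[2].values, b[2].values)
        assert a[3].df.equals(b[3].df)

    def test_positions_strictly_increasing(self):
        h, _ = simulate_haplotypes(small_cfg(seed=9))
        pos = h.positions()
        assert (np.diff(pos) > 0).all()


class TestSweep:
    def test_full_sweep_gives_h12_one(self):
        h, truth = simulate_haplotypes(small_cfg(seed=2))
        h2, truth2 = implant_sweep(h, truth, block=1, f=1.0, mut_rate=0.0, seed=5)
        lo, hi = truth2.block_bounds[1]
        w = SNPWindow("2L", lo, hi - 1, h2.sites[lo].pos, h2.sites[hi - 1].pos)
        h1, h12 = garud_h(hap_frequencies(h2, w))
        assert h12 == pytest.approx(1.0)

    def test_half_sweep_top_frequency(self):
        cfg = small_cfg(n_samples=(50, 0), seed=3)
        h, truth = simulate_haplotypes(cfg)
        h2, truth2 = implant_sweep(h, truth, block=0, f=0.5, mut_rate=0.0, seed=5)
        lo, hi = truth2.block_bounds[0]
        w = SNPWindow("2L", lo, hi - 1, h2.sites[lo].pos, h2.sites[hi - 1].pos)
        freqs = hap_frequencies(h2, w)
        assert freqs[0] >= 0.5

    def test_focal_block_out_of_range(self):
        h, truth = simulate_haplotypes(small_cfg(seed=4))
        with pytest.raises(ValueError):
            implant_sweep(h, truth, block=5, f=0.5, mut_rate=0.0, seed=0)

    def test_sweep_membership_recorded(self):
        h, truth = simulate_haplotypes(small_cfg(n_samples=(50, 0), seed=6))
        _, truth2 = implant_sweep(h, truth, block=0, f=0.4, mut_rate=0.0, seed=7)
        assert truth2.sweep_member.sum() == round(0.4 * 100)


class TestCnvCoverage:
    def region(self):
        return GeneRegion("cnv", "2L", 30_000, 43_200)

    def test_carrier_coverage_level(self):
        h, truth = simulate_haplotypes(small_cfg(seed=8))
        h, truth = implant_sweep(h, truth, 0, 0.5, 0.0, seed=8)
        cov, truth2 = assign_cnv_and_coverage(
            truth, self.region(), lambda rng: 8, link_p=1.0, noise_sd=0.05,
            seed=9, contig_bp=200_000, samples=h.samples,
        )
        idx = cov.windows_within(self.region())
        carriers = np.flatnonzero(truth2.cnv_carrier)
        assert carriers.size > 0
        assert cov.values[np.ix_(carriers, idx)].mean() == pytest.approx(10.0, abs=0.1)
        non = np.flatnonzero(~truth2.cnv_carrier)
        assert cov.values[np.ix_(non, idx)].mean() == pytest.approx(2.0, abs=0.1)

    def test_full_linkage_equates_carriers_and_swept(self):
        h, truth = simulate_haplotypes(small_cfg(seed=10))
        h, truth = implant_sweep(h, truth, 0, 0.5, 0.0, seed=10)
        cov, truth2 = assign_cnv_and_coverage(
            truth, self.region(), (2, 8), link_p=1.0, noise_sd=0.3,
            seed=11, contig_bp=200_000, samples=h.samples,
        )
        swept_samples = truth.sweep_member.reshape(-1, 2).any(axis=1)
        assert np.array_equal(truth2.cnv_carrier, swept_samples)

    def test_low_noise_hmm_recovers_truth_exactly(self):
        h, truth = simulate_haplotypes(small_cfg(seed=12))
        h, truth = implant_sweep(h, truth, 0, 0.5, 0.0, seed=12)
        cov, truth2 = assign_cnv_and_coverage(
            truth, self.region(), (2, 8), link_p=1.0, noise_sd=0.01,
            seed=13, contig_bp=200_000, samples=h.samples,
        )
        params = CoverageHMMParams(sigma=0.05)
        idx = cov.windows_within(self.region())
        for i in range(len(cov.samples)):
            path = hmm_decode(cov.values[i], params)
            assert (path[idx] == truth2.true_copy_number[i]).all()


class TestPhenotypes:
    def test_zero_mortality_all_resistant(self):
        h, truth = simulate_haplotypes(small_cfg(seed=14))
        truth.cnv_carrier = np.zeros(len(h.samples), dtype=bool)
        st = simulate_phenotypes(truth, h.samples, 0.0, 0.0, seed=1)
        assert (st.df["phenotype"] == "resistant").all()

    def test_perfect_separation_by_carrier(self):
        h, truth = simulate_haplotypes(small_cfg(seed=15))
        carrier = np.zeros(len(h.samples), dtype=bool)
        carrier[:10] = True
        truth.cnv_carrier = carrier
        st = simulate_phenotypes(truth, h.samples, 1.0, 0.0, seed=2)
        pheno = st.df["phenotype"].to_numpy()
        assert (pheno[:10] == "resistant").all()
        assert (pheno[10:] == "susceptible").all()

    def test_mortalities_within_binomial_interval(self):
        n = 4000
        cfg = small_cfg(n_samples=(n, 0), n_blocks=1, sites_per_block=10, seed=16)
        h, truth = simulate_haplotypes(cfg)
        carrier = np.zeros(n, dtype=bool)
        carrier[: n // 2] = True
        truth.cnv_carrier = carrier
        st = simulate_phenotypes(truth, h.samples, 0.442, 0.167, seed=3)
        dead = (st.df["phenotype"] == "susceptible").to_numpy()
        for mask, mort in ((carrier, 0.167), (~carrier, 0.442)):
            rate = dead[mask].mean()
            se = np.sqrt(mort * (1 - mort) / mask.sum())
            assert abs(rate - mort) < 4 * se


class TestSibPairs:
    def test_child_blocks_come_from_parents(self):
        cfg = small_cfg(n_samples=(12, 0), seed=17)
        h, truth = simulate_haplotypes(cfg)
        h2, truth2 = make_sib_pairs(h, truth, n_pairs=2, seed=18)
        child_cols = [
            c
            for i, grp in enumerate(truth2.sib_group)
            if grp is not None
            for c in (2 * i, 2 * i + 1)
        ]
        parental = {h.alleles[lo:hi, c].tobytes()
                    for lo, hi in truth.block_bounds
                    for c in range(h.n_haplotypes)}
        for c in child_cols:
            for lo, hi in truth2.block_bounds:
                assert h2.alleles[lo:hi, c].tobytes() in parental

    def test_too_many_pairs_rejected(self):
        h, truth = simulate_haplotypes(small_cfg(n_samples=(4, 0), seed=19))
        with pytest.raises(ValueError):
            make_sib_pairs(h, truth, n_pairs=3, seed=0)


class TestContamination:
    def test_fractions_bounded(self):
        cfg = small_cfg(seed=20)
        g, h, cov, st, truth = simulate_dataset(cfg)
        st2, _ = simulate_contamination(st, seed=1)
        frac = st2.df["contamination"].to_numpy()
        assert (frac >= 0).all() and (frac <= 0.05).all()

    def test_effect_zero_leaves_site_unbiased(self):
        # with no effect the rewritten site stays near its base frequency
        cfg = small_cfg(n_samples=(200, 0), seed=21)
        g, h, cov, st, truth = simulate_dataset(cfg)
        st2, g2 = simulate_contamination(st, seed=2, g=g, target_site=0, effect=0.0)
        freq = g2.calls[0].mean() / 2
        assert 0.15 < freq < 0.45  # logistic base rate 0.3


class TestCaseControl:
    def test_balanced_classes_and_truth_alignment(self):
        cfg = small_cfg(n_samples=(300, 0), sweep_fraction=0.6, seed=22)
        data = simulate_dataset(cfg)
        g, h, cov, st, truth = select_case_control(*data, n_per_class=40, seed=5)
        assert (st.df["phenotype"] == "resistant").sum() == 40
        assert (st.df["phenotype"] == "susceptible").sum() == 40
        assert len(truth.cnv_carrier) == 80
        # haplotype truth stays aligned with the genotype columns
        g2 = to_genotype_set(h)
        assert g2.samples == g.samples
        assert np.array_equal(g2.calls, g.calls)
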