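"""Wright-Fisher simulator: drift law, determinism, corruption operators."""

import numpy as np
import pytest

from driftscan import genodata, syndata
from driftscan.genodata import MISSING
from driftscan.syndata import (
    HaploSimConfig,
    SweepSpec,
    TemporalSimConfig,
    simulate_haplotypes,
    simulate_temporal_dataset,
    simulate_wf_trajectory,
)

from conftest import make_table


class TestTrajectory:
    def test_absorbing_at_zero(self):
        for s in (0.0, 0.3, -0.3):
            traj = simulate_wf_trajectory(0.0, 50, s, 10, seed=1)
            assert (traj == 0.0).all()

    def test_absorbing_at_one_neutral(self):
        traj = simulate_wf_trajectory(1.0, 50, 0.0, 10, seed=1)
        assert (traj == 1.0).all()

    def test_selection_shifts_mean_one_generation(self):
        # deterministic update p(1+s)/(1+ps): 0.5*1.2/1.1 = 0.5455
        rng = np.random.default_rng(11)
        n_rep, ne = 10_000, 10_000
        finals = np.array(
            [simulate_wf_trajectory(0.5, ne, 0.2, 1, seed=rng)[-1] for _ in range(n_rep)]
        )
        expect = 0.6 / 1.1
        se = np.sqrt(expect * (1 - expect) / (2 * ne) / n_rep)
        assert abs(finals.mean() - expect) < 3 * se

    def test_neutral_drift_variance(self):
        # one-generation drift variance p(1-p)/(2 ne), within 15%
        ne, p, reps = 50, 0.5, 6000
        rng = np.random.default_rng(3)
        deltas = np.array(
            [simulate_wf_trajectory(p, ne, 0.0, 1, seed=rng)[-1] - p for _ in range(reps)]
        )
        expect = p * (1 - p) / (2 * ne)
        assert abs(deltas.var() - expect) / expect < 0.15

    def test_neutral_fixation_probability_equals_p0(self):
        # neutral fixation probability equals the initial frequency
        ne, p0, reps = 20, 0.1, 2000
        rng = np.random.default_rng(5)
        fixed = 0
        for _ in range(reps):
            traj = simulate_wf_trajectory(p0, ne, 0.0, 400, seed=rng)
            assert traj[-1] in (0.0, 1.0)
            fixed += traj[-1] == 1.0
        se = np.sqrt(p0 * (1 - p0) / reps)
        assert abs(fixed / reps - p0) < 3 * se

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_wf_trajectory(1.5, 50, 0.0, 5)
        with pytest.raises(ValueError):
            simulate_wf_trajectory(0.5, 0, 0.0, 5)

    def test_deterministic_under_seed(self):
        a = simulate_wf_trajectory(0.3, 100, 0.1, 20, seed=42)
        b = simulate_wf_trajectory(0.3, 100, 0.1, 20, seed=42)
        assert (a == b).all()


class TestTemporalDataset:
    def _cfg(self, **kw):
        base = dict(
            ne=100, s=0.0, n_generations=8,
            sampling_plan={g: 10 for g in range(1, 9)},
            n_snps=30, seed=7,
        )
        base.update(kw)
        return TemporalSimConfig(**base)

    def test_sampling_plan_respected(self):
        cfg = self._cfg(sampling_plan={1: 0, 3: 5, 7: 8, 8: 0})
        with pytest.raises(ValueError):
            TemporalSimConfig(ne=100, s=0.0, n_generations=8,
                              sampling_plan={3: 5}, n_snps=10)
        gt, md, _ = simulate_temporal_dataset(cfg)
        assert sorted(md["generation"].unique()) == [3, 7]
        assert len(md) == 13

    def test_metadata_years_recover_generations(self):
        from driftscan import temporal

        gt, md, _ = simulate_temporal_dataset(self._cfg())
        plan = temporal.GenerationPlan(1980, 4)
        labels = temporal.assign_generations(md["birth_year"].to_numpy(), plan)
        assert (labels == md["generation"].to_numpy()).all()

    def test_huge_ne_keeps_frequency(self):
        # ne = 1e6, s = 0: pooled frequency stays at p0 up to sampling noise
        cfg = self._cfg(ne=1_000_000, n_snps=1000, init_freq_law=("fixed", 0.5))
        gt, md, _ = simulate_temporal_dataset(cfg)
        n_copies = 2 * gt.n_samples * gt.n_snps
        pooled = gt.genotypes.sum() / n_copies
        se = np.sqrt(0.25 / n_copies)
        assert abs(pooled - 0.5) < 3 * se

    def test_ground_truth_matches_config(self):
        cfg = self._cfg(s=0.25)
        _, _, truth = simulate_temporal_dataset(cfg)
        assert (truth["s"] == 0.25).all()
        assert len(truth) == cfg.n_snps
        traj0 = [float(x) for x in truth["trajectory"][0].split(",")]
        assert len(traj0) == cfg.n_generations

    def test_determinism(self):
        a = simulate_temporal_dataset(self._cfg())
        b = simulate_temporal_dataset(self._cfg())
        assert (a[0].genotypes == b[0].genotypes).all()
        assert a[1].equals(b[1])
        assert a[2].equals(b[2])


class TestHaplotypes:
    def test_no_recomb_copies_founders(self):
        cfg = HaploSimConfig(n_haplotypes=10, n_snps=40, recomb_prob=0.0,
                             ne=20, n_generations=2, seed=9)
        # rebuild founders with the same stream to compare
        tab = simulate_haplotypes(cfg)
        # with r=0 and no mutation every output haplotype must be one of the
        # 2*ne founders; founders aren't returned, so check copy structure:
        # any two identical columns in founders stay identical; weaker but
        # sufficient check: every haplotype present in the output occurs an
        # integer number of times among gametes -> rows must tile blocks.
        # Direct check: simulate 1 generation from explicit founders.
        rng = np.random.default_rng(0)
        founders = (rng.random((40, 30)) < 0.5).astype(np.int8)
        from driftscan.syndata import _next_generation

        child = _next_generation(founders, 20, 0.0, rng)
        founder_set = {tuple(row) for row in founders}
        assert all(tuple(row) in founder_set for row in child)

    def test_sweep_reaches_target_band(self):
        cfg = HaploSimConfig(
            n_haplotypes=40, n_snps=200, recomb_prob=0.01, ne=100, seed=2,
            sweep=SweepSpec(focal=100, s=0.3, p0=0.2, target=0.8),
        )
        tab = simulate_haplotypes(cfg)
        f = tab.haplotypes[:, 100].mean()
        # population hits >= 0.8; the 40-haplotype sample adds binomial noise
        assert 0.65 <= f <= 1.0

    def test_sweep_unattainable_raises_with_restart_count(self):
        cfg = HaploSimConfig(
            n_haplotypes=10, n_snps=20, ne=20, seed=3, max_restarts=3,
            sweep=SweepSpec(focal=5, s=-0.9, p0=0.02, target=0.99),
        )
        with pytest.raises(syndata.SweepFailedError) as exc:
            simulate_haplotypes(cfg)
        assert exc.value.restarts == 3

    def test_sweep_increases_identity_lengths(self):
        from driftscan.nsl import pair_identity_length

        focal = 100
        sweep_cfg = HaploSimConfig(
            n_haplotypes=30, n_snps=201, recomb_prob=0.02, ne=80, seed=4,
            sweep=SweepSpec(focal=focal, s=0.2, p0=0.1, target=0.8),
        )
        neutral_cfg = HaploSimConfig(
            n_haplotypes=30, n_snps=201, recomb_prob=0.02, ne=80,
            n_generations=25, seed=4,
        )
        def mean_len(tab):
            h = tab.haplotypes
            tot = cnt = 0
            for i in range(h.shape[0]):
                for j in range(i + 1, h.shape[0]):
                    tot += pair_identity_length(h, i, j, focal)
                    cnt += 1
            return tot / cnt

        assert mean_len(simulate_haplotypes(sweep_cfg)) > mean_len(
            simulate_haplotypes(neutral_cfg)
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            HaploSimConfig(n_haplotypes=9, n_snps=10)
        with pytest.raises(ValueError):
            HaploSimConfig(n_haplotypes=10, n_snps=10, recomb_prob=0.7)
        with pytest.raises(ValueError):
            HaploSimConfig(n_haplotypes=10, n_snps=10,
                           sweep=SweepSpec(focal=10, s=0.1))

    def test_determinism(self):
        cfg = HaploSimConfig(n_haplotypes=20, n_snps=50, ne=40, seed=5)
        assert (simulate_haplotypes(cfg).haplotypes
                == simulate_haplotypes(cfg).haplotypes).all()


class TestMissingness:
    def test_rate_zero_unchanged(self, toy_table):
        out = syndata.inject_missingness(toy_table, 0.0, seed=1)
        assert (out.genotypes == toy_table.genotypes).all()

    def test_rate_one_all_missing(self, toy_table):
        out = syndata.inject_missingness(toy_table, 1.0, seed=1)
        assert (out.genotypes == MISSING).all()

    def test_realized_rate_concentrates(self):
        g = np.ones((100, 1000), dtype=np.int8)
        out = syndata.inject_missingness(make_table(g), 0.23, seed=2)
        frac = (out.genotypes == MISSING).mean()
        assert 0.21 <= frac <= 0.25

    def test_gq_law_low_fraction(self):
        g = np.ones((50, 200), dtype=np.int8)
        out = syndata.inject_missingness(
            make_table(g), 0.1, gq_law={"low_frac": 0.3}, seed=3
        )
        obs = out.genotypes != MISSING
        low = (out.gq[obs] < 10).mean()
        assert 0.2 < low < 0.4
        assert np.isnan(out.gq[~obs]).all()


class TestAlleleFlip:
    def test_involution(self, toy_table):
        once = syndata.inject_allele_flip(toy_table, [0, 2], "chip")
        twice = syndata.inject_allele_flip(once, [0, 2], "chip")
        assert (twice.genotypes == toy_table.genotypes).all()

    def test_fixed_alt_reads_all_ref_after_flip(self):
        g = np.full((4, 1), 2, dtype=np.int8)
        gt = make_table(g, sources=["a", "a", "b", "b"])
        out = syndata.inject_allele_flip(gt, [0], "b")
        assert (out.genotypes[2:] == 0).all()
        assert (out.genotypes[:2] == 2).all()

    def test_missing_untouched(self):
        g = np.array([[MISSING], [1]], dtype=np.int8)
        out = syndata.inject_allele_flip(make_table(g), [0], "chip")
        assert out.genotypes[0, 0] == MISSING
        assert out.genotypes[1, 0] == 1
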