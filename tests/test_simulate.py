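"""Generator contracts: bookkeeping, determinism, MNAR structure, truth."""

import numpy as np
import pytest

import bioidcall as bc
from bioidcall import SimParams


class TestBookkeeping:
    def test_row_and_sample_counts(self, sim):
        table, design, truth = sim
        p = truth.params
        expected_rows = p.n_background + p.n_cytosolic + 4 * p.interactors_per_bait + 4
        assert len(table.protein_ids) == expected_rows
        assert len(table.sample_ids) == 5 * p.n_reps == 15

    def test_truth_sets_are_disjoint(self, sim):
        _, _, truth = sim
        ints = [set(v) for v in truth.interactors.values()]
        for i, a in enumerate(ints):
            for b in ints[i + 1:]:
                assert not (a & b)
        baits = set(truth.bait_protein_ids.values())
        assert not (set().union(*ints) & baits)
        assert not (truth.residents & truth.cytosolic)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(leakage=0.5)
        with pytest.raises(ValueError):
            SimParams(n_reps=1)
        with pytest.raises(ValueError):
            SimParams(n_background=-1)


class TestStructure:
    def test_bait_protein_tops_its_own_line(self, sim):
        table, design, truth = sim
        for bait, pid in truth.bait_protein_ids.items():
            samples = design.samples_of(bait)
            means = table.data[samples].mean(axis=1, skipna=True)
            assert means.idxmax() == pid

    def test_bait_protein_absent_outside_its_line(self, sim):
        table, design, truth = sim
        for bait, pid in truth.bait_protein_ids.items():
            others = [s for ln in design.lines if ln.name != bait for s in ln.samples]
            assert table.data.loc[pid, others].isna().all()

    def test_cytosolic_proteins_only_in_leader(self, sim):
        table, design, truth = sim
        bait_samples = [s for b in design.bait_names for s in design.samples_of(b)]
        sub = table.data.loc[sorted(truth.cytosolic), bait_samples]
        assert sub.isna().all().all()

    def test_missingness_monotone_decreasing_in_latent_intensity(self):
        # pool detected fraction by latent-mean bin over resident rows
        params = SimParams(seed=3, n_background=3000, n_cytosolic=0,
                           interactors_per_bait=0)
        table, design, truth = bc.simulate_experiment(params)
        leader = design.samples_of("IscU_leader")
        sub = table.data.loc[sorted(truth.residents), leader]
        # leader latent mean spans the LOD midpoint; bin by observed bait mean
        bait_mean = table.data.loc[sub.index,
                                   [s for b in design.bait_names
                                    for s in design.samples_of(b)]].mean(axis=1)
        latent_leader = bait_mean - np.log2(params.leakage)
        bins = np.quantile(latent_leader.dropna(), [0, .2, .4, .6, .8, 1])
        rates = []
        for lo, hi in zip(bins[:-1], bins[1:]):
            mask = (latent_leader >= lo) & (latent_leader < hi)
            rates.append(sub[mask].isna().to_numpy().mean())
        assert all(a >= b - 0.03 for a, b in zip(rates[:-1], rates[1:]))

    def test_noise_free_limit_reproduces_depletion_exactly(self):
        params = SimParams(seed=0, sigma_r=0.0, lod=-np.inf, leakage=60.0)
        table, design, truth = bc.simulate_experiment(params)
        f = bc.control_depletion_factor(table, design, truth.residents)
        assert f == pytest.approx(60.0, rel=1e-9)


class TestDeterminism:
    def test_same_seed_bit_identical_reports(self, tmp_path):
        paths = []
        for run in ("x", "y"):
            table, design, truth = bc.simulate_experiment(SimParams(seed=5))
            p = tmp_path / f"{run}.tsv"
            bc.write_protein_groups(table, p)
            d = tmp_path / f"{run}_design.yaml"
            bc.write_design(design, d)
            t = tmp_path / f"{run}_truth.tsv"
            truth.truth_frame().to_csv(t, sep="\t", index=False)
            paths.append((p, d, t))
        for a, b in zip(*paths):
            assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self):
        t1, _, _ = bc.simulate_experiment(SimParams(seed=1))
        t2, _, _ = bc.simulate_experiment(SimParams(seed=2))
        assert not t1.data.equals(t2.data)


class TestEffectSizeLimits:
    def test_vanishing_effect_kills_recall(self):
        params = SimParams(seed=4, effect_log2=0.0)
        table, design, truth = bc.simulate_experiment(params)
        policy = bc.CallPolicy(test=bc.TestPolicy(seed=4))
        calls = {b: bc.call_interactors(table, design, b, policy)
                 for b in design.bait_names}
        pooled = bc.evaluate_recovery(calls, truth)
        pooled = pooled[pooled.bait == "pooled"].iloc[0]
        assert pooled.recall <= 0.2

    def test_huge_effect_saturates_recall(self):
        recalls = []
        for seed in range(3):
            params = SimParams(seed=seed, effect_log2=np.log2(150.0))
            table, design, truth = bc.simulate_experiment(params)
            policy = bc.CallPolicy(test=bc.TestPolicy(seed=seed))
            calls = {b: bc.call_interactors(table, design, b, policy)
                     for b in design.bait_names}
            pooled = bc.evaluate_recovery(calls, truth)
            recalls.append(pooled[pooled.bait == "pooled"].iloc[0].recall)
        assert np.mean(recalls) >= 0.95


class TestEvaluateRecovery:
    def test_perfect_calls_give_unit_metrics(self, sim):
        _, _, truth = sim
        calls = {
            b: [
                bc.InteractorCall(pid, b, "enriched", 10.0, {}, False, 12.0)
                for pid in truth.interactors[b]
            ]
            for b in truth.interactors
        }
        r = bc.evaluate_recovery(calls, truth)
        pooled = r[r.bait == "pooled"].iloc[0]
        assert pooled.precision == 1.0 and pooled.recall == 1.0

    def test_no_calls_gives_zero_recall_nan_precision(self, sim):
        _, _, truth = sim
        r = bc.evaluate_recovery({b: [] for b in truth.interactors}, truth)
        pooled = r[r.bait == "pooled"].iloc[0]
        assert pooled.recall == 0.0 and np.isnan(pooled.precision)

    def test_bait_protein_excluded_from_both_sides(self, sim):
        _, _, truth = sim
        bait = "IscU"
        calls = {bait: [
            bc.InteractorCall(truth.bait_protein_ids[bait], bait, "exclusive",
                              np.inf, {}, True, 20.0)
        ]}
        r = bc.evaluate_recovery(calls, truth)
        row = r[r.bait == bait].iloc[0]
        assert row.n_called == 0 and np.isnan(row.precision)
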