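"""Compartment-proteome calling: 3-of-4 rule, depletion summary, annotation."""

import numpy as np
import pandas as pd
import pytest

import bioidcall as bc
from bioidcall import CallPolicy, TestPolicy


def leader_table(rows, design):
    """Build a table over the full 4-bait + leader design from per-line log2
    means given as {protein_id: {line: value-or-nan}} with tiny replicate
    jitter so variances are defined."""
    rng = np.random.default_rng(99)
    cols = design.sample_ids
    data = {}
    for pid, per_line in rows.items():
        vals = []
        for line in [ln.name for ln in design.lines]:
            mu = per_line.get(line, np.nan)
            for _ in range(3):
                vals.append(np.nan if np.isnan(mu) else mu + rng.normal(0, 0.1))
        data[pid] = vals
    df = pd.DataFrame(data, index=cols).T
    df.index.name = "protein_id"
    return bc.IntensityTable(data=df)


@pytest.fixture()
def policy():
    return CallPolicy(test=TestPolicy(seed=21))


class TestQualifyBait:
    def test_exclusive_vs_leader(self, design, policy):
        table = leader_table(
            {
                "p_exc": {"ZapE1": 12.0},
                "bg": {b: 10.0 for b in design.bait_names} | {"IscU_leader": 10.0},
            },
            design,
        )
        q = bc.qualify_bait(table, design, "p_exc", "ZapE1", policy)
        assert q.exclusive and q.qualifies

    def test_large_shift_is_significant_enrichment(self, design, policy):
        rng = np.random.default_rng(5)
        rows = {
            f"bg{i}": {ln.name: v for ln, v in zip(design.lines, rng.normal(12, 1, 5))}
            for i in range(40)
        }
        rows["p_hi"] = {b: 16.0 for b in design.bait_names} | {"IscU_leader": 10.0}
        table = leader_table(rows, design)
        q = bc.qualify_bait(table, design, "p_hi", "ZapE1", policy)
        assert q.significant_enriched and not q.exclusive

    def test_equal_abundance_qualifies_nowhere(self, design, policy):
        rows = {
            f"bg{i}": {ln.name: 12.0 for ln in design.lines} for i in range(10)
        }
        table = leader_table(rows, design)
        q = bc.qualify_bait(table, design, "bg0", "IscU", policy)
        assert not q.exclusive and not q.significant_enriched


class TestCallCompartmentProteome:
    def _three_of_four_table(self, design):
        # p3 qualifies under exactly 3 baits (exclusive there, equal under ZapE2);
        # p2 under exactly 2; background everywhere equal
        rows = {
            f"bg{i}": {ln.name: 11.0 for ln in design.lines} for i in range(20)
        }
        rows["p3"] = {"ZapE1": 12.0, "IscU": 12.0, "LigK_beta": 12.0, "ZapE2": np.nan}
        rows["p2"] = {"ZapE1": 12.0, "ZapE2": 12.0, "IscU": np.nan, "LigK_beta": np.nan}
        return leader_table(rows, design)

    def test_membership_boundary_at_three_of_four(self, design, policy):
        table = self._three_of_four_table(design)
        calls = {c.protein_id: c for c in bc.call_compartment_proteome(table, design, policy)}
        assert calls["p3"].n_qualifying == 3 and calls["p3"].is_member
        assert calls["p2"].n_qualifying == 2 and not calls["p2"].is_member

    def test_lowering_min_qualifying_never_removes_members(self, design, policy):
        table = self._three_of_four_table(design)
        members = {}
        for k in (4, 3, 2, 1):
            pol = CallPolicy(min_qualifying_baits=k, test=policy.test)
            members[k] = {
                c.protein_id
                for c in bc.call_compartment_proteome(table, design, pol)
                if c.is_member
            }
        assert members[4] <= members[3] <= members[2] <= members[1]

    def test_exclusive_under_all_baits_is_always_a_member(self, design, policy):
        rows = {f"bg{i}": {ln.name: 11.0 for ln in design.lines} for i in range(10)}
        rows["p_all"] = {b: 12.0 for b in design.bait_names}  # absent in leader
        table = leader_table(rows, design)
        calls = {c.protein_id: c for c in bc.call_compartment_proteome(table, design, policy)}
        assert calls["p_all"].n_qualifying == 4 and calls["p_all"].is_member

    def test_deterministic_ordering(self, design, policy):
        table = self._three_of_four_table(design)
        calls = bc.call_compartment_proteome(table, design, policy)
        keys = [(-c.n_qualifying, c.protein_id) for c in calls]
        assert keys == sorted(keys)


class TestControlDepletionFactor:
    def test_single_protein_definition(self, design):
        rows = {"m": {b: 10.0 for b in design.bait_names} | {"IscU_leader": 10.0 - np.log2(60)}}
        table = leader_table(rows, design)
        # jitter-free check: rebuild without noise
        df = table.data.copy()
        for line in design.bait_names:
            df.loc["m", design.samples_of(line)] = 10.0
        df.loc["m", design.samples_of("IscU_leader")] = 10.0 - np.log2(60)
        table = bc.IntensityTable(data=df)
        f = bc.control_depletion_factor(table, design, {"m"})
        assert f == pytest.approx(60.0)

    def test_equal_abundance_gives_factor_one(self, design):
        rows = {f"m{i}": {ln.name: 12.0 for ln in design.lines} for i in range(5)}
        table = leader_table(rows, design)
        f = bc.control_depletion_factor(table, design, {f"m{i}" for i in range(5)})
        assert f == pytest.approx(1.0, abs=0.1)

    def test_estimators_agree_in_the_noise_free_limit(self, design):
        df_rows = {}
        cols = design.sample_ids
        for i in range(4):
            vals = []
            for ln in design.lines:
                v = 12.0 - np.log2(60) if ln.name == "IscU_leader" else 12.0
                vals += [v] * 3
            df_rows[f"m{i}"] = vals
        table = bc.IntensityTable(data=pd.DataFrame(df_rows, index=cols).T)
        members = set(df_rows)
        for est in ("mean_ratio", "geometric_mean", "ratio_of_means"):
            assert bc.control_depletion_factor(table, design, members, est) == pytest.approx(60.0)

    def test_members_unseen_in_leader_contribute_no_ratio(self, design):
        rows = {
            "seen": {b: 12.0 for b in design.bait_names} | {"IscU_leader": 12.0 - np.log2(60)},
            "unseen": {b: 12.0 for b in design.bait_names},
        }
        table = leader_table(rows, design)
        f = bc.control_depletion_factor(table, design, {"seen", "unseen"})
        assert f == pytest.approx(60.0, rel=0.2)

    def test_empty_members_and_no_leader_detection_are_errors(self, design):
        rows = {"x": {b: 12.0 for b in design.bait_names}}
        table = leader_table(rows, design)
        with pytest.raises(ValueError, match="empty"):
            bc.control_depletion_factor(table, design, set())
        with pytest.raises(ValueError, match="leader"):
            bc.control_depletion_factor(table, design, {"x"})


class TestAnnotatePriorEvidence:
    def _member_calls(self, n):
        return [
            bc.ProteomeCall(
                protein_id=f"m{i}", qualifies={}, n_qualifying=3, is_member=True
            )
            for i in range(n)
        ]

    def test_counts(self):
        calls = self._member_calls(5)
        ann = pd.DataFrame(
            {
                "prior_localized": [True, True, False, False],
                "in_importome": [False, True, True, False],
                "targeting_prob": [0.9, np.nan, 0.5, 0.1],
            },
            index=pd.Index(["m0", "m1", "m2", "m3"], name="protein_id"),
        )
        s = bc.annotate_prior_evidence(calls, ann)
        # m3 annotated but neither flag set; m4 unannotated
        assert s == {"n_members": 5, "n_prior_localized": 3, "n_novel": 2}

    def test_empty_annotation(self):
        calls = self._member_calls(3)
        ann = pd.DataFrame(
            columns=["prior_localized", "in_importome", "targeting_prob"],
            index=pd.Index([], name="protein_id"),
        )
        s = bc.annotate_prior_evidence(calls, ann)
        assert s == {"n_members": 3, "n_prior_localized": 0, "n_novel": 3}
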