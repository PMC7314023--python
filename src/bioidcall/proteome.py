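"""Compartment (mitochondrial) proteome calling against the leader control.

The leader negative-control line carries only the mitochondrial import signal
fused to the ligase; it is mostly cytosolic, so compartment residents appear
in it strongly depleted (about 60-fold in the motivating experiment) rather
than absent.  A protein *qualifies* under a bait when, compared with the
leader control, it is either exclusively present (all bait replicates
detected, all leader replicates missing) or significantly enriched (the
S0-moderated test significant with a positive difference — no fold-change
gate here; the 3x gate belongs to interactor calling).  A protein is called a
compartment member when it qualifies under at least ``min_qualifying_baits``
of the baits (3 of 4 in the motivating design).

The module also summarises how depleted the members are in the leader
control and cross-references membership against prior-evidence annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interactors import CallPolicy
from .io import ExperimentDesign, IntensityTable
from .stats import permutation_qvalues, row_nanmean

__all__ = [
    "ProteomeCall",
    "BaitQualification",
    "qualify_bait",
    "call_compartment_proteome",
    "control_depletion_factor",
    "annotate_prior_evidence",
]


@dataclass(frozen=True)
class BaitQualification:
    exclusive: bool
    significant_enriched: bool

    @property
    def qualifies(self) -> bool:
        return self.exclusive or self.significant_enriched


@dataclass
class ProteomeCall:
    protein_id: str
    qualifies: dict[str, BaitQualification]   # bait -> evidence
    n_qualifying: int
    is_member: bool
    prior_localized: bool | None = None

    def report_row(self) -> dict:
        row = {"protein_id": self.protein_id}
        for bait in sorted(self.qualifies):
            q = self.qualifies[bait]
            row[f"exclusive_{bait}"] = q.exclusive
            row[f"enriched_{bait}"] = q.significant_enriched
        row["n_qualifying"] = self.n_qualifying
        row["is_member"] = self.is_member
        row["strong"] = self.is_member  # membership is the report highlight
        return row


def _bait_evidence(
    table: IntensityTable, design: ExperimentDesign, bait: str, policy: CallPolicy
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (exclusive, significant_enriched) vs the leader for one bait."""
    leader = design.negative_control_line
    B = table.matrix(design.samples_of(bait))
    L = table.matrix(design.samples_of(leader))
    exclusive = (~np.isnan(B)).all(axis=1) & np.isnan(L).all(axis=1)
    # NaN means (all-missing group) compare False, as intended
    with np.errstate(invalid="ignore"):
        diff_pos = row_nanmean(B) > row_nanmean(L)
    if policy.test.use_permutation:
        q = permutation_qvalues(
            table, design.samples_of(bait), design.samples_of(leader), policy.test
        ).to_numpy()
        significant = np.where(np.isnan(q), False, q <= policy.test.alpha)
    else:
        from .stats import _d_for_assignment
        from scipy import stats as sps

        sub = np.concatenate([B, L], axis=1)
        idx = np.arange(sub.shape[1])
        d = _d_for_assignment(
            sub, idx[: B.shape[1]], idx[B.shape[1]:], policy.test.s0,
            policy.test.min_valid_per_group,
        )
        n1 = np.sum(~np.isnan(B), axis=1)
        n2 = np.sum(~np.isnan(L), axis=1)
        p = 2.0 * sps.t.sf(np.abs(d), np.maximum(n1 + n2 - 2, 1))
        significant = np.where(np.isnan(d), False, p <= policy.test.alpha)
    return exclusive, significant & diff_pos


def qualify_bait(
    table: IntensityTable,
    design: ExperimentDesign,
    protein_id: str,
    bait: str,
    policy: CallPolicy | None = None,
) -> BaitQualification:
    """Does one protein qualify under one bait versus the leader control?

    Exclusivity follows :func:`bioidcall.interactors.classify_exclusive`;
    enrichment is test significance with a positive difference, with the
    permutation null built from the whole table.
    """
    policy = policy or CallPolicy()
    exclusive, enriched = _bait_evidence(table, design, bait, policy)
    i = table.protein_ids.index(protein_id)
    return BaitQualification(
        exclusive=bool(exclusive[i]), significant_enriched=bool(enriched[i])
    )


def call_compartment_proteome(
    table: IntensityTable,
    design: ExperimentDesign,
    policy: CallPolicy | None = None,
) -> list[ProteomeCall]:
    """One membership call per protein, ordered by descending qualifying-bait
    count then protein id."""
    policy = policy or CallPolicy()
    baits = design.bait_names
    if len(baits) < policy.min_qualifying_baits:
        raise ValueError(
            f"design has {len(baits)} bait lines but min_qualifying_baits="
            f"{policy.min_qualifying_baits}"
        )
    per_bait = {b: _bait_evidence(table, design, b, policy) for b in baits}
    calls = []
    for i, pid in enumerate(table.protein_ids):
        quals = {
            b: BaitQualification(bool(exc[i]), bool(enr[i]))
            for b, (exc, enr) in per_bait.items()
        }
        n_q = sum(q.qualifies for q in quals.values())
        calls.append(
            ProteomeCall(
                protein_id=pid,
                qualifies=quals,
                n_qualifying=n_q,
                is_member=n_q >= policy.min_qualifying_baits,
            )
        )
    calls.sort(key=lambda c: (-c.n_qualifying, c.protein_id))
    return calls


def control_depletion_factor(
    table: IntensityTable,
    design: ExperimentDesign,
    members: set[str],
    estimator: str = "mean_ratio",
) -> float:
    """How much less abundant the member proteins are in the leader control.

    Restricted to members detected in the leader control and in at least one
    bait-line sample (proteins never seen in the leader are the exclusivity
    cases and contribute no ratio).  Per protein the ratio is
    ``2**(mean bait log2 - mean leader log2)`` over detected values;
    estimators: ``mean_ratio`` — arithmetic mean of the linear ratios
    (default); ``geometric_mean`` — 2**(mean log2 ratio); ``ratio_of_means``
    — summed linear bait means over summed linear leader means.
    """
    if not members:
        raise ValueError("members set is empty")
    if estimator not in ("mean_ratio", "ratio_of_means", "geometric_mean"):
        raise ValueError(f"unknown estimator {estimator!r}")
    leader_samples = design.samples_of(design.negative_control_line)
    bait_samples = [s for b in design.bait_names for s in design.samples_of(b)]
    member_ids = [p for p in table.protein_ids if p in members]
    B = table.data.loc[member_ids, bait_samples].to_numpy(dtype=float)
    L = table.data.loc[member_ids, leader_samples].to_numpy(dtype=float)
    mb = row_nanmean(B)
    ml = row_nanmean(L)
    ok = ~np.isnan(mb) & ~np.isnan(ml)
    if not ok.any():
        raise ValueError("no member protein is detected in the leader control")
    log_ratio = mb[ok] - ml[ok]
    if estimator == "mean_ratio":
        return float(np.mean(2.0 ** log_ratio))
    if estimator == "geometric_mean":
        return float(2.0 ** np.mean(log_ratio))
    return float(np.sum(2.0 ** mb[ok]) / np.sum(2.0 ** ml[ok]))


def annotate_prior_evidence(
    calls: list[ProteomeCall], annotation: pd.DataFrame
) -> dict[str, int]:
    """Summarise members against prior evidence of compartment localization.

    A member counts as prior-localized when the annotation marks it
    ``prior_localized`` or ``in_importome``; proteins absent from the
    annotation count as novel.  Returns ``{n_members, n_prior_localized,
    n_novel}`` and stamps ``prior_localized`` on each member call.
    """
    n_members = 0
    n_prior = 0
    for call in calls:
        if not call.is_member:
            continue
        n_members += 1
        prior = False
        if call.protein_id in annotation.index:
            row = annotation.loc[call.protein_id]
            prior = bool(row.get("prior_localized", False)) or bool(
                row.get("in_importome", False)
            )
        call.prior_localized = prior
        n_prior += prior
    return {
        "n_members": n_members,
        "n_prior_localized": n_prior,
        "n_novel": n_members - n_prior,
    }
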