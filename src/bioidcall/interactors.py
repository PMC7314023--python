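"""Per-bait putative-interactor calling with cross-bait negative controls.

The design runs several BioID2 bait lines side by side; the pulldown of every
*other* bait doubles as a negative control that removes abundant,
promiscuously biotinylated compartment proteins.  Baits expected to share
partners (here ZapE1 and ZapE2) are declared *related* and excluded from each
other's control sets; the leader negative-control line is reserved for
compartment-proteome calling and never enters an interactor control set.

A protein is called, per bait:

* ``exclusive``  — detected in every bait replicate and absent from every
  replicate of every control line;
* ``enriched``   — detected in every bait replicate; against each control
  line either exclusivity holds or the S0-moderated test is significant with
  a positive difference; and the mean linear fold change across control
  lines exceeds the enrichment threshold (default 3x);
* ``rejected``   — otherwise (a reason code records why).

Per-control fold changes with an all-missing control are +inf; the mean fold
change excludes +inf entries when any finite entry exists and is +inf only
when all are.  Calls that are exclusive or enriched on average more than the
strong threshold (default 100x) carry a ``strong`` highlight flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ExperimentDesign, IntensityTable
from .stats import TestPolicy, permutation_qvalues, row_nanmean, _d_for_assignment

__all__ = [
    "CallPolicy",
    "ControlEvidence",
    "InteractorCall",
    "classify_exclusive",
    "fold_change",
    "control_set",
    "call_interactors",
]


@dataclass(frozen=True)
class CallPolicy:
    """Thresholds and modes for interactor and proteome calling.

    enrichment_threshold
        minimum mean linear fold change vs the control lines (default 3.0).
    strong_threshold
        mean fold change above which a call is highlighted (default 100.0).
    min_qualifying_baits
        baits a protein must qualify under for compartment membership
        (default 3 of the paper-style 4-bait design).
    control_mode
        how a bait's control set is formed; only ``cross_bait`` (all other
        bait lines minus the bait's related set) is defined.
    depletion_estimator
        ``mean_ratio`` (default), ``ratio_of_means`` or ``geometric_mean``
        for the control-depletion summary.
    """

    enrichment_threshold: float = 3.0
    strong_threshold: float = 100.0
    test: TestPolicy = field(default_factory=TestPolicy)
    min_qualifying_baits: int = 3
    control_mode: str = "cross_bait"
    depletion_estimator: str = "mean_ratio"

    def __post_init__(self) -> None:
        if self.enrichment_threshold <= 1:
            raise ValueError("enrichment_threshold must exceed 1")
        if self.strong_threshold < self.enrichment_threshold:
            raise ValueError("strong_threshold must be >= enrichment_threshold")
        if self.control_mode != "cross_bait":
            raise ValueError(f"unknown control_mode {self.control_mode!r}")
        if self.depletion_estimator not in ("mean_ratio", "ratio_of_means", "geometric_mean"):
            raise ValueError(f"unknown depletion_estimator {self.depletion_estimator!r}")

    def with_seed(self, seed: int) -> "CallPolicy":
        return replace(self, test=self.test.with_seed(seed))


@dataclass(frozen=True)
class ControlEvidence:
    """Evidence for one protein against one control line."""

    exclusive: bool
    fc: float           # linear ratio; +inf when the control is all-missing
    significant: bool   # moderated test significant with positive diff
    q: float | None = None


@dataclass
class InteractorCall:
    protein_id: str
    bait: str
    status: str                       # exclusive | enriched | rejected
    mean_fc: float                    # mean linear fold change (may be +inf)
    per_control: dict[str, ControlEvidence]
    strong: bool
    mean_bait_log2: float
    reason: str = ""

    def report_row(self) -> dict:
        row = {
            "protein_id": self.protein_id,
            "bait": self.bait,
            "status": self.status,
            "mean_bait_log2": self.mean_bait_log2,
            "mean_fc": self.mean_fc,
            "strong": self.strong,
        }
        for name in sorted(self.per_control):
            ev = self.per_control[name]
            row[f"fc_vs_{name}"] = ev.fc
            row[f"sig_vs_{name}"] = ev.significant
        row["reason"] = self.reason
        return row


def classify_exclusive(bait_values, control_values) -> bool:
    """Exclusive identification: detected in *every* bait replicate and
    absent from *every* control replicate (any replicate count >= 2)."""
    b = np.asarray(bait_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    return bool((~np.isnan(b)).all() and np.isnan(c).all())


def fold_change(bait_values, control_values) -> float:
    """Linear bait/control ratio from mean log2 intensities of detected values.

    +inf when the control group is entirely missing (the exclusivity limit);
    NaN (undefined) when the bait group is entirely missing.
    """
    b = np.asarray(bait_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if np.isnan(b).all():
        return float("nan")
    if np.isnan(c).all():
        return float("inf")
    return float(2.0 ** (np.nanmean(b) - np.nanmean(c)))


def control_set(design: ExperimentDesign, bait: str, policy: CallPolicy) -> set[str]:
    """Control lines for a bait: all other baits minus its related set.

    The leader negative-control line is never included — it is reserved for
    compartment-proteome calling.  An empty result is a hard error.
    """
    if bait not in design.bait_names:
        raise ValueError(f"{bait!r} is not a declared bait line")
    controls = set(design.bait_names) - {bait} - set(design.related_to(bait))
    if not controls:
        raise ValueError(
            f"empty control set for bait {bait!r}: all other baits are related"
        )
    return controls


def _mean_fold_change(fcs: list[float]) -> float:
    """Mean of per-control linear fold changes, +inf entries excluded when any
    finite entry exists; +inf when all entries are +inf."""
    finite = [f for f in fcs if np.isfinite(f)]
    if finite:
        return float(np.mean(finite))
    return float("inf")


def call_interactors(
    table: IntensityTable,
    design: ExperimentDesign,
    bait: str,
    policy: CallPolicy | None = None,
) -> list[InteractorCall]:
    """Call putative interactors of one bait against its cross-bait controls.

    Candidates must be detected in every bait replicate (proteins with a
    partial bait detection pattern are never candidates).  See the module
    docstring for the exclusive / enriched / rejected rules.  The returned
    list places non-rejected calls first, ordered by descending mean bait
    intensity (the autobiotinylated bait protein therefore tops its own
    list), then rejected proteins by id.
    """
    policy = policy or CallPolicy()
    controls = sorted(control_set(design, bait, policy))
    bait_samples = design.samples_of(bait)
    B = table.matrix(bait_samples)
    bait_complete = (~np.isnan(B)).all(axis=1)
    mean_bait = row_nanmean(B)

    evidence: dict[str, dict] = {}
    for ctrl in controls:
        ctrl_samples = design.samples_of(ctrl)
        C = table.matrix(ctrl_samples)
        ctrl_all_missing = np.isnan(C).all(axis=1)
        mean_ctrl = row_nanmean(C)
        with np.errstate(invalid="ignore"):
            fc = np.where(ctrl_all_missing, np.inf, 2.0 ** (mean_bait - mean_ctrl))
        fc = np.where(np.isnan(mean_bait), np.nan, fc)  # bait all missing: undefined
        exclusive = bait_complete & ctrl_all_missing
        if policy.test.use_permutation:
            q = permutation_qvalues(
                table, bait_samples, ctrl_samples, policy.test
            ).to_numpy()
            significant = np.where(np.isnan(q), False, q <= policy.test.alpha)
        else:
            sub = np.concatenate([B, C], axis=1)
            idx = np.arange(sub.shape[1])
            d = _d_for_assignment(
                sub, idx[: B.shape[1]], idx[B.shape[1]:], policy.test.s0,
                policy.test.min_valid_per_group,
            )
            from scipy import stats as sps

            n1 = np.sum(~np.isnan(B), axis=1)
            n2 = np.sum(~np.isnan(C), axis=1)
            p = 2.0 * sps.t.sf(np.abs(d), np.maximum(n1 + n2 - 2, 1))
            significant = np.where(np.isnan(d), False, p <= policy.test.alpha)
            q = np.full(len(d), np.nan)
        diff_pos = np.where(np.isnan(mean_ctrl), True, mean_bait > mean_ctrl)
        evidence[ctrl] = {
            "exclusive": exclusive,
            "fc": fc,
            "significant": significant & diff_pos,
            "q": q,
        }

    calls: list[InteractorCall] = []
    ids = table.protein_ids
    for i, pid in enumerate(ids):
        per_control = {
            c: ControlEvidence(
                exclusive=bool(ev["exclusive"][i]),
                fc=float(ev["fc"][i]),
                significant=bool(ev["significant"][i]),
                q=(None if np.isnan(ev["q"][i]) else float(ev["q"][i])),
            )
            for c, ev in evidence.items()
        }
        if not bait_complete[i]:
            n_det = int((~np.isnan(B[i])).sum())
            reason = (
                "not_detected_in_bait" if n_det == 0 else "incomplete_bait_detection"
            )
            status, mean_fc, strong = "rejected", float("nan"), False
        else:
            fcs = [per_control[c].fc for c in controls]
            mean_fc = _mean_fold_change(fcs)
            if all(per_control[c].exclusive for c in controls):
                status, reason = "exclusive", ""
            elif all(
                per_control[c].exclusive or per_control[c].significant
                for c in controls
            ) and mean_fc > policy.enrichment_threshold:
                status, reason = "enriched", ""
            else:
                status = "rejected"
                failing = [
                    c for c in controls
                    if not (per_control[c].exclusive or per_control[c].significant)
                ]
                if failing:
                    reason = "not_significant_vs_" + ",".join(failing)
                else:
                    reason = "below_fold_threshold"
            strong = status != "rejected" and (
                status == "exclusive" or mean_fc > policy.strong_threshold
            )
        calls.append(
            InteractorCall(
                protein_id=pid,
                bait=bait,
                status=status,
                mean_fc=mean_fc,
                per_control=per_control,
                strong=strong,
                mean_bait_log2=float(mean_bait[i]) if not np.isnan(mean_bait[i]) else float("nan"),
                reason=reason,
            )
        )

    def sort_key(call: InteractorCall):
        rejected = call.status == "rejected"
        mb = call.mean_bait_log2
        return (rejected, -(mb if not np.isnan(mb) else -np.inf), call.protein_id)

    calls.sort(key=sort_key)
    return calls
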