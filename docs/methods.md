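# Methods

## Data model

Intensities are log2 LFQ values with NaN as the explicit missing marker. A
raw intensity of 0 or an empty cell is "not detected" (the MaxQuant
convention) and is never mapped to log2(0) or imputed; arithmetic therefore
cannot silently absorb a non-detection. Rows flagged as reverse decoys or
potential contaminants are dropped by default when the flag columns exist.
No further row-level filtering (minimum peptides, unique peptides) is
applied: the tables are taken as delivered by upstream processing, which is
also assumed to have normalized intensities across runs.

The experimental design is a validated object, not a convention: every
sample belongs to exactly one line, every line has ≥2 replicates, exactly
one line is the negative control, and related-bait pairs must be declared
symmetrically. Violations are hard errors at parse time.

## The moderated statistic

The test statistic is the SAM-style moderation of the pooled two-sample t:
`d = diff / (se_pooled + s0)` with `s0 = 0.1` by default. The pooled
(equal-variance) form is used rather than Welch because that is how the
statistic is defined in the software lineage this analysis follows; the
choice is isolated in one function. At `s0 = 0` the statistic reduces
exactly to the classical pooled t (verified against an independent
closed-form implementation to 1e-10 over 1000 random cases).

Two significance routes:

* **Analytic p** — two-sided t with n1+n2−2 df applied to `d`. Exact at
  `s0 = 0`; conservative for `s0 > 0` since the inflated denominator only
  shrinks `|d|`. Measured null rate at α = 0.05: ≈ 0.049 (s0 = 0).
* **Permutation q (default)** — the observed `|d|` of each protein is
  compared with the pooled null of `|d|` over group-label reassignments of
  the whole table: `q(t) = E_perm[#null ≥ t] / #observed ≥ t`, made monotone
  non-increasing in `|d|` and clipped to [0, 1]; no π0 estimate (π0 = 1,
  conservative). The identity assignment — and, for balanced groups, its
  complement, which yields the same `|d|` — is excluded from the null:
  with 3 + 3 replicates there are only 20 assignments, and keeping the
  identity pair imposes a hard floor of q ≥ 0.1 on every protein, below
  which no call could ever clear α = 0.05. With the exclusion a protein
  more extreme than every null value gets q = 0. All assignments are
  enumerated when ≤ `n_perm` exist (the 3v3 case), otherwise `n_perm`
  are sampled from the stated seed; identical seeds give identical q.
  Measured null rate of q ≤ 0.05: ≈ 0.0003.

Proteins with fewer than `min_valid_per_group = 2` detected replicates in
either group are excluded from testing, never imputed; presence/absence
patterns are the exclusivity classifier's job.

## Interactor calling

Per bait, the control set is every other bait line minus the bait's related
set; the leader control line never enters it. The per-control requirement is
conjunctive (pass against *each* control line), matching per-dataset
evidence columns; the 3× gate applies to the across-controls **mean** linear
fold change (mean rather than median — exposed as a parameter since the
estimator is ambiguous in principle). Per-control fold changes with an
all-missing control are recorded as +inf; the mean excludes +inf entries
whenever a finite entry exists and is +inf only when all are (capping +inf
at a large constant was rejected as threshold-sensitive). Candidates must be
detected in **all** bait replicates; partial bait detection is never a
candidate and is reported with a reason code. Calls that are exclusive or
>100× mean-enriched carry the `strong` highlight. The report layer owns the
100× highlight convention, so written reports are consistent even if a
caller constructed calls by hand.

## Compartment-proteome calling

"Enriched" in the ≥3-of-4-baits rule means test-significant with a positive
difference versus the leader — the 3× fold-change gate deliberately does
**not** apply here (it belongs to interactor calling); both gates are
parameters so the interpretation can be swapped. The leader depletion factor
is the mean over member proteins of `2^(mean bait log2 − mean leader log2)`,
restricted to members actually detected in the leader (never-detected
members are the exclusivity cases and contribute no ratio). Because "on
average N times less abundant" is estimator-ambiguous, the arithmetic mean
of linear ratios is the default and the geometric mean and ratio-of-means
are implemented behind a flag and reported side by side by the CLI.

## The synthetic generator

Defaults emulate the motivating study conditions: 4 baits (ZapE1, ZapE2,
IscU, LigK-β, with ZapE1↔ZapE2 related) + leader control × 3 replicates;
1000 compartment-resident background proteins with base log2 abundance
N(14, 2) and replicate noise sd 0.3; residents depleted 60× in the leader
line (the leader construct leaks a small fraction into the organelle, so
residents are depleted, not absent); 200 cytosol-only proteins present only
in the leader line; 5 spiked true interactors per bait at 10× enrichment in
their bait's line only; each bait's own protein placed one log2 unit above
the highest resident in its line (autobiotinylation) and absent elsewhere.
Detection is MNAR: a replicate value at latent log2 intensity x is observed
with probability `logistic((x − 9) · 1.5)`; `lod = −inf` disables dropout
for noise-free checks. One global seed fans out through per-category
substreams so changing one category's count does not perturb the others'
draws.

What the generator does *not* emulate: peptide-level quantification and
shared-peptide protein inference, batch effects across runs, correlated
(co-complex) interactors, abundance-dependent replicate noise, and
contaminant/decoy rows. Passing benchmarks therefore demonstrate that the
calling rules recover the intended signal under idealized LFQ-like noise
and dropout, not that they are robust to every artifact of real pulldowns.

Measured at the defaults over 20 seeds (also recomputed by
`scripts/acceptance.py`): interactor pooled recall and precision ≈ 0.99,
bait protein called exclusive in its own dataset in every seed, leader
depletion factor ≈ 60 (exactly 60 in the noise-free limit), false-member
rate 0.

**Known limitation — compartment-member recall ≈ 0.78.** A resident with
exactly one detected leader replicate (probability ≈ 0.18 under the default
abundance and dropout parameters, since the depleted leader intensities
straddle the detection midpoint) is neither exclusive (the leader is not
all-missing) nor testable (one valid value < `min_valid_per_group`), and
because the same three leader replicates serve all four baits, such a
protein qualifies under zero baits no matter how strong its bait-line
signal. This is a structural consequence of the strict all-or-nothing
exclusivity definition combined with MNAR dropout near the detection limit,
not a tuning issue; the corresponding acceptance test documents the gap.
Practical mitigations (not enabled by default, to keep the published rules):
lower `min_qualifying_baits`, or relax exclusivity to "at most k control
detections".

## Numerical choices

* Fold-change thresholds are applied on the linear scale after
  back-transform; all internal arithmetic is log2.
* Zero-variance, zero-difference pairs give d = 0 (0/0 defined as 0);
  zero-variance nonzero differences at s0 = 0 give ±inf with p clamped to
  the smallest positive float.
* Report ordering is deterministic: interactor calls non-rejected first by
  descending mean bait intensity, then rejected by id; proteome calls by
  descending qualifying-bait count then id. NaN fold changes print as "-"
  (enrichment not computable), infinities as "inf".
* Problem sizes: benchmarks and calibration checks use 20 seeds, 1224
  proteins per experiment and 300-protein null tables, the scale at which
  the Monte-Carlo error on the reported rates is well below the decision
  margins.
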