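# Methods

This note records the model, procedures, parameter choices, and known
limitations of `rnaconsensus`.

## 1. Data model

A **structure model** is an ordered list of nucleotide residues
(chain, number, insertion code, base) with their atoms. Files are read
with gemmi; PDB vs mmCIF is decided by content sniffing, archives
(zip/tar) are unpacked one level, and multi-model files are split into
`stem#k` entries. Non-nucleotide residues (ions, water, ligands,
amino acids) are skipped at load time.

An **interaction** is one of:

* `canonical_pair` — Watson–Crick/wobble pair (AU, GC, GU as cWW);
* `noncanonical_pair` — any other pair, carrying one of 12
  Leontis–Westhof classes ({cis, trans} × unordered edge pair from
  {W, H, S});
* `stacking` — face-to-face contact of two base planes.

Interaction identity is the unordered residue pair plus kind, plus the
LW class for noncanonical pairs only. Canonical pairs and stackings
deliberately ignore any edge annotation, so two models agree on a
Watson–Crick pair even if their exact geometries differ.

## 2. Geometric annotation

When no external annotation table is supplied, interactions are
detected from coordinates. Per residue we compute the base-ring
least-squares plane (SVD), centroid, glycosidic nitrogen, C1′, and
polar edge atoms. Residue pairs within 15 Å centroid distance are
examined; **stacking is tested before pairing**, because stacked
neighbours are close enough to satisfy polar-contact cutoffs but are
never coplanar.

Thresholds (Å, degrees), chosen from standard RNA geometry surveys and
validated against idealized A-form duplexes:

| parameter | value | rationale |
|---|---|---|
| stacking centroid distance | ≤ 5.5 | typical ring separation 3.3–5 Å |
| stacking plane angle | ≤ 30° | near-parallel planes |
| stacking rise (normal offset) | 2.0–5.5 | excludes coplanar side-by-side pairs |
| pair C1′–C1′ distance | 8–12 | WC pairs cluster near 10.4 Å |
| pair H-bond donor–acceptor | ≤ 3.5 | standard H-bond cutoff |
| pair plane angle | ≤ 65° | pairs may propeller/buckle but not stack |
| pair rise | ≤ 2.0 | a paired base sits in its partner's plane |

The pair-rise cutoff is the complement of the stacking-rise window: it
removes diagonal cross-strand neighbours that satisfy distance and
H-bond-pattern tests while sitting a full helical rise apart.

Canonical pairs require the complete hydrogen-bond pattern of their
pair type (e.g. G·C: N1–N3, O6–N4, N2–O2). Noncanonical pairs take
their edges from the closest polar contact (priority W > H > S when a
contact atom lies on an edge boundary) and cis/trans from the relative
sidedness of the two glycosidic bonds about the pair axis.

## 3. Consensus construction

Given `N ≥ 2` interaction sets, the frequency multiset maps each
observed interaction to its count and membership `count/N`.

* **Threshold mode** keeps interactions with count ≥ `n`; the user must
  supply `n` (no default — the choice is scientific, not technical).
* **Weighted mode** (default) keeps everything with graded membership.

Dot-bracket constraints: bracket families `()[]{}<>` mark *required*
pairs (inserted with membership forced to 1 even if absent from every
model); `x` marks *forced unpaired* positions (pairs touching them are
flagged forbidden and excluded from the consensus); `.` is
unconstrained. Constraints apply to pairs only, never stackings.

The consensus secondary structure is exported as dot-bracket by a
greedy pass over canonical pairs in descending effective membership
(ties broken lexicographically by interaction key, making the output
deterministic); pairs clashing with an already-accepted partner are
dropped, and crossing pairs are coloured into up to four bracket
families by first-fit graph colouring.

## 4. Scoring and ranking

Crisp (threshold) confusion is plain set algebra against the kept set.
Fuzzy (weighted) confusion accumulates, per consensus entry with
membership `p`: present → `TP += p`, `FP += 1 − p`; absent → `FN += p`.
Required entries use effective membership 1; a forbidden pair present
in a model adds a full FP. Interactions a model has that the consensus
lacks entirely (possible only under constraints or scope filtering)
count as full FP.

Scores: `INF = sqrt(precision · recall)` and F1. Conventions:
all-zero confusion → 1.0 (vacuous perfection, e.g. empty consensus and
empty model); `TP = 0` otherwise → 0.0. Ranking sorts by descending
score, ties broken by model id, so reruns are byte-identical (scores
are serialized with 6 decimals).

Scopes restrict which interaction kinds participate:
`pairs_and_stacking` (default), `all_pairs`, `canonical_only`,
`stacking_only`.

## 5. Ranking similarity and the null model

Four metrics compare two rankings of the same `k` items:

* Spearman's ρ = `1 − 6Σd²/(k(k²−1))` over rank differences;
* Kendall's τ via concordant/discordant sign products;
* enrichment score ES = `|top-f overlap| / (f²·k)` with
  `topsize = max(1, floor(f·k))`, default fraction `f = 0.25`;
* extrapolated rank-biased overlap,
  `RBO = (1−p)·Σ_{d=1..k} p^{d−1}·A_d + p^k·A_k` with prefix-overlap
  agreement `A_d`, default persistence `p = 0.9` (standard choice:
  ~86 % of weight in the top 10).

The null model draws batches of independent uniformly random
permutation pairs (argsort of uniform variates), computes per-batch
metric means, and reports the empirical 2.5th/97.5th percentiles across
batches. For 13 items, 100 pairs/batch, 10,000 batches the bounds are
±0.056 (ρ) and ±0.041 (τ), matching the analytic half-width
`1.96/(√(k−1)·√pairs) ≈ 0.0566` for ρ. ES and RBO null intervals are
normalization-dependent and are reported but not treated as reference
values.

Significance of an observed similarity profile against the null uses
Welch's t test per noise level (scipy) with Benjamini–Hochberg FDR
adjustment across levels (statsmodels), plus Cohen's d against the null
mean and SD.

## 6. Robustness simulation

`run_noise_simulation` perturbs an ensemble's interaction sets one
edit at a time: uniformly choose a model, an interaction kind, and
add/remove; additions draw uniformly from the unused universe
(all residue pairs; ×12 LW classes for noncanonical pairs) by rejection
sampling, removals delete a uniformly chosen present interaction of
that kind; infeasible (kind, action) combinations fall through to the
next. Perturbations accumulate within a run; each run `r` uses an
independent `default_rng(seed + r)`, so results are reproducible and
runs are order-independent. After each edit the perturbed ensemble is
re-ranked and compared to the unperturbed reference ranking with all
four metrics.

`synth_ensemble` builds abstract test ensembles: a shared interaction
core present in every model plus Poisson-distributed random additions
and deletions per model. It emulates method ensembles whose agreement
is concentrated in a conserved core; it does not emulate correlated
errors between methods, realistic interaction-geometry distributions,
or sequence-dependent pairing propensities.

The idealized duplex builder (`helix.build_duplex`) places CCD residue
templates on an A-form trajectory (rise 2.81 Å, twist 32.7°, C1′–C1′
10.4 Å, λ = 54.5°). It produces clean WC geometry for detector tests;
it is not a physically minimized structure (no backbone continuity
optimization, no sugar-pucker variation).

## 7. Design choices and limitations

* **12-class LW identity.** Ordered LW spellings (e.g. tHS vs tSH) are
  normalized to an unordered class so interaction identity is symmetric
  in the two residues.
* **Default metric INF, default mode weighted.** Weighted mode needs no
  user parameter and uses all evidence; INF is the field's standard
  interaction-set similarity.
* **Non-nucleotide residues are skipped**, not rejected: mixed files
  (protein–RNA complexes, ions) are common and the RNA portion is what
  is being ranked.
* **PDB legacy limits** (99,999 atoms, 9,999 residues per chain, 62
  chains) are checked before writing PDB output; larger systems must be
  written as mmCIF by other tools.
* Consensus quality degrades when the ensemble is small, when methods
  share systematic errors (the consensus then codifies the shared
  error), or when models disagree so thoroughly that the consensus is
  nearly empty — in weighted mode every model then scores near the
  degenerate conventions and the ranking carries little signal.
* The geometric annotator targets well-formed models; severely
  distorted geometries may yield sparse annotations, which the
  consistency check cannot detect (it compares sequences, not
  geometry).
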