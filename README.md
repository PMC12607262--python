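# rnaconsensus

Reference-free consensus ranking of RNA 3D structure model ensembles.

## The problem

RNA 3D structure prediction methods routinely emit ensembles of candidate
models for one target sequence. When an experimental reference structure
exists, models are ranked by similarity to it (RMSD, INF, and relatives).
When no reference exists — the common case for novel targets — those
metrics are unusable. `rnaconsensus` ranks the models of an ensemble
against each other instead: the interactions (base pairs and stackings)
that recur across many models form a *consensus*, and each model is
scored by how faithfully it reproduces that consensus. The working
hypothesis is that prediction methods err in different directions, so the
interactions they agree on are the trustworthy core of the ensemble.

## The core model

For an ensemble of `N` models, each model `m` is reduced to its set of
annotated interactions `S_m` (canonical pairs, noncanonical pairs with
Leontis–Westhof class, and stackings). The **frequency multiset** assigns
every observed interaction `t` a membership

```
p(t) = |{m : t ∈ S_m}| / N  ∈ (0, 1].
```

Two consensus modes are supported:

* **Threshold** mode keeps exactly the interactions with count ≥ `n`
  (a user-chosen confidence level, `1 ≤ n ≤ N`) and scores each model
  with crisp set algebra: `TP = |S_m ∩ C|`, `FP = |S_m \ C|`,
  `FN = |C \ S_m|`.
* **Conditionally weighted** (fuzzy) mode keeps everything and treats
  `p(t)` as a graded truth value. For each consensus interaction `t`:
  if `t ∈ S_m` then `TP += p(t)` and `FP += 1 − p(t)`; otherwise
  `FN += p(t)`.

Either way the model's score is the Interaction Network Fidelity

```
INF = sqrt( TP/(TP+FP) · TP/(TP+FN) )
```

or the F1 score `2·TP / (2·TP + FP + FN)`; models are ranked by
descending score. Degenerate cases follow the conventions
`TP = FP = FN = 0 → 1.0` and `TP = 0` otherwise `→ 0.0`.

Optional dot-bracket constraints inject prior knowledge: a bracketed
pair is *required* (membership forced to 1, absence costs a full FN) and
an `x` position is *forced unpaired* (pairs touching it leave the
consensus and cost a full FP when a model contains one).

## Worked example

A three-model ensemble of the duplex `GGCAGC`/`GCUGCC`: two identical
idealized A-form duplexes (`m1.pdb`, `m2.pdb`) and one copy whose
terminal base pair was displaced (`m3.pdb`).

```
$ rnaconsensus rank m1.pdb m2.pdb m3.pdb --outdir out
results written to out
$ cat out/ranking.csv
rank,model_id,INF,F1,TP,FP,FN,mode,scope
1,m1,0.981307,0.981132,17.333333,0.666667,0.000000,weighted,pairs_and_stacking
2,m2,0.981307,0.981132,17.333333,0.666667,0.000000,weighted,pairs_and_stacking
3,m3,0.960769,0.960000,16.000000,0.000000,1.333333,weighted,pairs_and_stacking
$ cat out/consensus.dbn
GGCAGCGCUGCC
(((((())))))
```

The displaced terminal pair of `m3` keeps its internal geometry (both
residues moved rigidly) but loses its stacking contacts, so `m3` misses
two consensus stackings (`FN = 2·(2/3) = 4/3`) and ranks last; the
complete duplexes pay only the small fuzzy FP for carrying stackings
that `m3` lacks. The consensus secondary structure is the full
six-pair duplex.

The same arithmetic on a minimal abstract ensemble — `A = {x, y}`,
`B = {x}`, `C = {x, z}` — gives `B` the fuzzy sums
`TP = 1, FP = 0, FN = 2/3`, hence `F1 = 3/4` and `INF = sqrt(3/5)`,
and `A`/`C` the sums `TP = 4/3, FP = 2/3, FN = 1/3`, hence
`F1 = 8/11 ≈ 0.7273` and `INF = sqrt(8/15) ≈ 0.7303`; ranking
`B > A = C`.

## Interpreting ranking agreement

To judge whether two rankings of the same ensemble agree more than
chance, `rnaconsensus nullmodel` simulates batches of uniformly random
ranking pairs and reports empirical 95% confidence intervals of the
batch-mean similarity:

```
$ rnaconsensus nullmodel --items 13 --pairs 100 --batches 1000 --seed 1 \
    --metrics spearman,kendall --out null.csv
spearman: 95% CI [-0.056, 0.054]
kendall: 95% CI [-0.041, 0.038]
```

Four similarity metrics are implemented: Spearman's ρ, Kendall's τ, a
top-fraction enrichment score, and extrapolated rank-biased overlap
(persistence 0.9). `rnaconsensus robustness` perturbs an ensemble's
interaction sets one interaction at a time and tracks how quickly the
ranking decays from the unperturbed reference, with Welch's t tests
against the null and Benjamini–Hochberg FDR control across noise levels.

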