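"""Noise-injection robustness protocol and synthetic ensemble generation.

The simulator iteratively perturbs an ensemble's interaction tables: each
iteration picks a random model, an interaction kind (canonical,
non-canonical, or stacking) and an action (add or remove), then either
inserts a previously absent random interaction or deletes an existing one.
Perturbations accumulate within a run, so noise level n means n total
alterations since the reference state.  After every alteration the ensemble
is re-ranked and the noisy ranking is compared to the reference ranking
with four similarity metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import (
    KINDS,
    LW_CLASSES,
    Interaction,
    ModelInteractionSet,
)
from .consensus import AnalysisConfig, build_frequency_multiset
from .model_io import ResidueRef
from .ranksim import (
    DEFAULT_ES_FRACTION,
    DEFAULT_RBO_P,
    METRICS,
    effect_size,
    null_metric_samples,
    ranking_similarity,
    significance_profile,
)
from .scoring import rank_models

__all__ = [
    "NoiseOperation",
    "NoiseProfile",
    "perturb_once",
    "run_noise_simulation",
    "compute_noise_statistics",
    "synth_ensemble",
]


@dataclass(frozen=True)
class NoiseOperation:
    model_id: str
    kind: str
    action: str  # "add" | "remove"
    payload: Interaction


@dataclass
class NoiseProfile:
    """Per-noise-level samples of ranking similarity across runs."""

    n_runs: int
    n_iterations: int
    seed: int
    reference: list[str]
    # level (1-based) -> metric -> array of per-run values
    samples: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    # filled in by compute_noise_statistics:
    statistics: dict[str, list[dict]] | None = None


def _pair_space_size(n_residues: int, kind: str) -> int:
    pairs = n_residues * (n_residues - 1) // 2
    return pairs * len(LW_CLASSES) if kind == "noncanonical_pair" else pairs


def _random_interaction(
    rng: np.random.Generator, residues: Sequence[ResidueRef], kind: str
) -> Interaction:
    i, j = rng.choice(len(residues), size=2, replace=False)
    lw = None
    if kind == "noncanonical_pair":
        lw = LW_CLASSES[rng.integers(len(LW_CLASSES))]
    return Interaction(kind, residues[i], residues[j], lw)


def perturb_once(
    sets: Sequence[ModelInteractionSet],
    residues: Sequence[ResidueRef],
    rng: np.random.Generator,
) -> tuple[list[ModelInteractionSet], NoiseOperation]:
    """Apply one random add/remove alteration; returns perturbed copies.

    Kind and action are drawn uniformly and re-drawn when infeasible
    (nothing of that kind to remove, or the add space for that kind is
    exhausted).  Exactly one interaction differs between input and output.
    """
    if not sets:
        raise ValueError("need at least one model")
    if len(residues) < 2:
        raise ValueError("residue universe must contain at least two residues")
    new_sets = [s.copy() for s in sets]
    m_idx = int(rng.integers(len(new_sets)))
    target = new_sets[m_idx]

    tried: set[tuple[str, str]] = set()
    while len(tried) < len(KINDS) * 2:
        kind = KINDS[rng.integers(len(KINDS))]
        action = ("add", "remove")[rng.integers(2)]
        if (kind, action) in tried:
            continue
        if action == "remove":
            candidates = [x for x in target if x.kind == kind]
            if not candidates:
                tried.add((kind, action))
                continue
            victim = candidates[rng.integers(len(candidates))]
            target.discard(victim.key())
            op = NoiseOperation(target.model_id, kind, "remove", victim)
            return new_sets, op
        else:
            present = sum(1 for x in target if x.kind == kind)
            if present >= _pair_space_size(len(residues), kind):
                tried.add((kind, action))
                continue
            while True:  # rejection-sample until a previously absent entry
                cand = _random_interaction(rng, residues, kind)
                if cand.key() not in target:
                    break
            target.add(cand)
            op = NoiseOperation(target.model_id, kind, "add", cand)
            return new_sets, op
    raise RuntimeError("no feasible perturbation exists for the chosen model")


def run_noise_simulation(
    sets: Sequence[ModelInteractionSet],
    residues: Sequence[ResidueRef],
    cfg: AnalysisConfig,
    n_runs: int,
    n_iterations: int,
    seed: int,
    *,
    rbo_p: float = DEFAULT_RBO_P,
    es_fraction: float = DEFAULT_ES_FRACTION,
) -> NoiseProfile:
    """Reference ranking on the clean ensemble, then ``n_runs`` independent
    runs of ``n_iterations`` cumulative perturbations, re-ranking after each
    alteration.  Deterministic under a fixed seed (run r uses seed + r)."""
    cm = build_frequency_multiset(sets)
    ref_ranking, _ = rank_models(sets, cm, cfg)
    reference = [mid for mid, _ in ref_ranking.order]

    profile = NoiseProfile(n_runs, n_iterations, seed, reference)
    per_level: dict[int, dict[str, list[float]]] = {
        lvl: {m: [] for m in METRICS} for lvl in range(1, n_iterations + 1)
    }
    for run in range(n_runs):
        rng = np.random.default_rng(seed + run)
        working = [s.copy() for s in sets]
        for level in range(1, n_iterations + 1):
            working, _ = perturb_once(working, residues, rng)
            noisy_cm = build_frequency_multiset(working)
            noisy_ranking, _ = rank_models(working, noisy_cm, cfg)
            noisy = [mid for mid, _ in noisy_ranking.order]
            sim = ranking_similarity(
                reference, noisy, rbo_p=rbo_p, es_fraction=es_fraction
            )
            for metric, value in sim.as_dict().items():
                per_level[level][metric].append(value)
    profile.samples = {
        lvl: {m: np.array(v) for m, v in d.items()}
        for lvl, d in per_level.items()
    }
    return profile


def compute_noise_statistics(
    profile: NoiseProfile,
    *,
    null_pairs: int = 1000,
    null_seed: int | None = None,
    rbo_p: float = DEFAULT_RBO_P,
    es_fraction: float = DEFAULT_ES_FRACTION,
) -> dict[str, list[dict]]:
    """Per metric and noise level: Welch t vs the random-ranker null,
    BH-adjusted p across levels, and Cohen's d against the null sd."""
    n_items = len(profile.reference)
    seed = profile.seed if null_seed is None else null_seed
    null = null_metric_samples(
        n_items, null_pairs, seed, METRICS, rbo_p=rbo_p, es_fraction=es_fraction
    )
    levels = sorted(profile.samples)
    out: dict[str, list[dict]] = {}
    for metric in METRICS:
        level_samples = [profile.samples[lvl][metric] for lvl in levels]
        trio = significance_profile(level_samples, null[metric])
        null_mean = float(np.mean(null[metric]))
        null_sd = float(np.std(null[metric], ddof=1))
        rows = []
        for lvl, sample, (t, p, adj) in zip(levels, level_samples, trio):
            d = effect_size(sample, null_mean, null_sd).d
            rows.append(
                {
                    "level": lvl,
                    "mean": float(np.mean(sample)),
                    "t": t,
                    "p_raw": p,
                    "p_adj": adj,
                    "cohens_d": d,
                }
            )
        out[metric] = rows
    profile.statistics = out
    return out


# ---------------------------------------------------------------------------
# synthetic ensembles


def synth_ensemble(
    n_models: int,
    n_residues: int,
    core_size: int,
    noise_rate: float,
    seed: int,
    *,
    chain: str = "A",
) -> tuple[list[ModelInteractionSet], list[ResidueRef]]:
    """Generate an ensemble sharing a random interaction core.

    Every model contains the same ``core_size`` random interactions; on top
    of the core each model receives Poisson(noise_rate) random additions
    and Poisson(noise_rate) random deletions, emulating the disagreement
    between independently predicted 3D models of one sequence.
    """
    if n_models < 2:
        raise ValueError("an ensemble needs at least two models")
    rng = np.random.default_rng(seed)
    bases = "ACGU"
    residues = [
        ResidueRef(chain, k + 1, "", bases[rng.integers(4)])
        for k in range(n_residues)
    ]
    total_space = sum(_pair_space_size(n_residues, k) for k in KINDS)
    if core_size > total_space:
        raise ValueError(
            f"core_size {core_size} exceeds the interaction space "
            f"({total_space})"
        )

    core: dict[tuple, Interaction] = {}
    while len(core) < core_size:
        kind = KINDS[rng.integers(len(KINDS))]
        x = _random_interaction(rng, residues, kind)
        core.setdefault(x.key(), x)

    sets = []
    for m in range(n_models):
        s = ModelInteractionSet(f"model_{m + 1:02d}", core.values())
        n_del = int(rng.poisson(noise_rate))
        for _ in range(min(n_del, len(s))):
            keys = sorted(s.keys())
            s.discard(keys[rng.integers(len(keys))])
        n_add = int(rng.poisson(noise_rate))
        for _ in range(n_add):
            for _attempt in range(100):
                kind = KINDS[rng.integers(len(KINDS))]
                x = _random_interaction(rng, residues, kind)
                if x.key() not in s:
                    s.add(x)
                    break
        sets.append(s)
    return sets, residues
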