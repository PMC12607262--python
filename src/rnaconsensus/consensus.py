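"""Virtual consensus structure: interaction frequency multiset, 2D
constraints, threshold subsets and dot-bracket export.

The consensus of an ensemble is the multiset of every interaction observed
in any model, each carrying its occurrence count c and fuzzy membership
p = c / N (N = number of contributing models).  A user-supplied extended
dot-bracket constraint can mark pairs as required (favoured) or positions
as forced-unpaired (penalised).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from .annotation import Interaction, ModelInteractionSet, interaction_key
from .model_io import ResidueRef

__all__ = [
    "ConsensusEntry",
    "ConsensusMultiset",
    "Constraint2D",
    "AnalysisConfig",
    "ConsensusError",
    "ConstraintError",
    "build_frequency_multiset",
    "threshold_consensus",
    "parse_constraints",
    "apply_constraints",
    "consensus_to_dotbracket",
    "write_consensus_csv",
]

SCOPES = ("canonical_only", "all_pairs", "pairs_and_stacking")
BRACKET_FAMILIES = ("()", "[]", "{}", "<>")


class ConsensusError(Exception):
    pass


class ConstraintError(Exception):
    pass


@dataclass
class ConsensusEntry:
    interaction: Interaction
    count: int
    membership: float
    constraint_flag: Literal["none", "required", "x_forbidden"] = "none"

    @property
    def effective_membership(self) -> float:
        """Membership after constraint override: required pairs count as
        unanimous regardless of how many models contain them."""
        return 1.0 if self.constraint_flag == "required" else self.membership


@dataclass
class ConsensusMultiset:
    """The virtual consensus structure of an ensemble of N models."""

    n_models: int
    entries: dict[tuple, ConsensusEntry] = field(default_factory=dict)

    def __len__(self):
        return len(self.entries)

    def scoped_entries(self, scope: str = "pairs_and_stacking"):
        return {
            k: e for k, e in self.entries.items() if in_scope(e.interaction.kind, scope)
        }


def in_scope(kind: str, scope: str) -> bool:
    if scope not in SCOPES:
        raise ConsensusError(f"unknown interaction scope {scope!r}")
    if scope == "canonical_only":
        return kind == "canonical_pair"
    if scope == "all_pairs":
        return kind in ("canonical_pair", "noncanonical_pair")
    return True


@dataclass
class AnalysisConfig:
    """Configuration of one consensus/scoring run."""

    mode: Literal["weighted", "threshold"] = "weighted"
    confidence_level: int | None = None
    scope: str = "pairs_and_stacking"
    metric: Literal["INF", "F1"] = "INF"

    def validate(self, n_models: int | None = None) -> None:
        if self.mode not in ("weighted", "threshold"):
            raise ConsensusError(f"unknown mode {self.mode!r}")
        if self.scope not in SCOPES:
            raise ConsensusError(f"unknown scope {self.scope!r}")
        if self.metric not in ("INF", "F1"):
            raise ConsensusError(f"unknown ranking metric {self.metric!r}")
        if self.mode == "threshold":
            if self.confidence_level is None:
                raise ConsensusError("threshold mode requires a confidence level")
            if n_models is not None and not (
                1 <= self.confidence_level <= n_models
            ):
                raise ConsensusError(
                    f"confidence level must be in [1, {n_models}], got "
                    f"{self.confidence_level}"
                )


def build_frequency_multiset(
    sets: Sequence[ModelInteractionSet],
) -> ConsensusMultiset:
    """Count every interaction across the ensemble; membership = count / N."""
    if len(sets) < 2:
        raise ConsensusError(
            "consensus requires at least two models, got " f"{len(sets)}"
        )
    n = len(sets)
    cm = ConsensusMultiset(n_models=n)
    for s in sets:
        for x in s:
            k = x.key()
            entry = cm.entries.get(k)
            if entry is None:
                cm.entries[k] = ConsensusEntry(x, 1, 1.0 / n)
            else:
                entry.count += 1
                entry.membership = entry.count / n
    return cm


def threshold_consensus(cm: ConsensusMultiset, n: int) -> set[tuple]:
    """Keys observed in >= n models (required keys always retained,
    x-forbidden keys always excluded)."""
    if not 1 <= n <= cm.n_models:
        raise ConsensusError(
            f"confidence level must be in [1, {cm.n_models}], got {n}"
        )
    out = set()
    for k, e in cm.entries.items():
        if e.constraint_flag == "x_forbidden":
            continue
        if e.count >= n or e.constraint_flag == "required":
            out.add(k)
    return out


# ---------------------------------------------------------------------------
# 2D constraints


@dataclass
class Constraint2D:
    """Parsed extended dot-bracket constraint over L positions (1-based)."""

    length: int
    pairs: set[tuple[int, int]]  # (i, j) with i < j
    forced_unpaired: set[int]

    def __post_init__(self):
        for i, j in self.pairs:
            if i >= j:
                raise ConstraintError(f"pair ({i},{j}) is not ordered")
            if i in self.forced_unpaired or j in self.forced_unpaired:
                raise ConstraintError(
                    f"pair ({i},{j}) involves a forced-unpaired position"
                )


_OPENERS = {b[0]: b for b in BRACKET_FAMILIES}
_CLOSERS = {b[1]: b for b in BRACKET_FAMILIES}


def parse_constraints(db: str, sequence_length: int | None = None) -> Constraint2D:
    """Parse extended dot-bracket: ``()[]{}<>`` pairs (each family matched by
    its own stack, so pseudoknots across families are allowed), ``.`` free,
    ``x`` forced-unpaired."""
    db = db.strip()
    if sequence_length is not None and len(db) != sequence_length:
        raise ConstraintError(
            f"constraint length {len(db)} != sequence length {sequence_length}"
        )
    stacks: dict[str, list[int]] = {b: [] for b in BRACKET_FAMILIES}
    pairs: set[tuple[int, int]] = set()
    forced: set[int] = set()
    for pos, ch in enumerate(db, start=1):
        if ch == ".":
            continue
        if ch == "x":
            forced.add(pos)
        elif ch in _OPENERS:
            stacks[_OPENERS[ch]].append(pos)
        elif ch in _CLOSERS:
            fam = _CLOSERS[ch]
            if not stacks[fam]:
                raise ConstraintError(
                    f"unbalanced {ch!r} at position {pos}"
                )
            pairs.add((stacks[fam].pop(), pos))
        else:
            raise ConstraintError(
                f"invalid constraint character {ch!r} at position {pos}"
            )
    for fam, stack in stacks.items():
        if stack:
            raise ConstraintError(
                f"unbalanced {fam[0]!r} opened at position {stack[-1]}"
            )
    return Constraint2D(len(db), pairs, forced)


def _position_map(residues: Sequence[ResidueRef]) -> dict[tuple, int]:
    """Residue identity -> 1-based global position in unified order."""
    return {
        (r.chain, r.number, r.insertion_code): pos
        for pos, r in enumerate(residues, start=1)
    }


def apply_constraints(
    cm: ConsensusMultiset,
    constraint: Constraint2D,
    residues: Sequence[ResidueRef],
) -> ConsensusMultiset:
    """Flag consensus entries against a 2D constraint (in place, returned).

    Every constrained pair becomes a required canonical-pair entry (created
    with count 0 and effective membership 1.0 if no model contains it);
    every pair entry touching a forced-unpaired position is flagged
    x_forbidden.  Stacking entries are never constraint-flagged.
    """
    if constraint.length != len(residues):
        raise ConstraintError(
            f"constraint length {constraint.length} != residue count "
            f"{len(residues)}"
        )
    posmap = _position_map(residues)

    for i, j in constraint.pairs:
        ri, rj = residues[i - 1], residues[j - 1]
        x = Interaction("canonical_pair", ri, rj)
        k = x.key()
        entry = cm.entries.get(k)
        if entry is None:
            cm.entries[k] = ConsensusEntry(x, 0, 0.0, "required")
        else:
            entry.constraint_flag = "required"

    if constraint.forced_unpaired:
        for e in cm.entries.values():
            if e.interaction.kind == "stacking":
                continue
            pi = posmap.get(
                (e.interaction.i.chain, e.interaction.i.number,
                 e.interaction.i.insertion_code)
            )
            pj = posmap.get(
                (e.interaction.j.chain, e.interaction.j.number,
                 e.interaction.j.insertion_code)
            )
            if pi is None or pj is None:
                raise ConstraintError(
                    f"interaction residue outside the constrained sequence: "
                    f"{e.interaction.i.label()}-{e.interaction.j.label()}"
                )
            if pi in constraint.forced_unpaired or pj in constraint.forced_unpaired:
                e.constraint_flag = "x_forbidden"
    return cm


# ---------------------------------------------------------------------------
# dot-bracket export


def consensus_to_dotbracket(
    cm: ConsensusMultiset,
    residues: Sequence[ResidueRef],
    *,
    confidence_level: int | None = None,
    membership_cutoff: float = 0.5,
) -> str:
    """Render the canonical-pair consensus as extended dot-bracket.

    Candidate pairs are the canonical entries selected either by a
    threshold confidence level or by a membership cutoff (weighted mode
    default 0.5); they are accepted greedily by descending membership
    (ties broken lexicographically by key) so that each position pairs at
    most once, then bracket families are assigned first-fit over the
    pseudoknot conflict graph.
    """
    posmap = _position_map(residues)
    candidates = []
    for k, e in cm.entries.items():
        if e.interaction.kind != "canonical_pair":
            continue
        if e.constraint_flag == "x_forbidden":
            continue
        if confidence_level is not None:
            keep = e.count >= confidence_level or e.constraint_flag == "required"
        else:
            keep = e.effective_membership > membership_cutoff
        if not keep:
            continue
        pi = posmap[
            (e.interaction.i.chain, e.interaction.i.number,
             e.interaction.i.insertion_code)
        ]
        pj = posmap[
            (e.interaction.j.chain, e.interaction.j.number,
             e.interaction.j.insertion_code)
        ]
        lo, hi = min(pi, pj), max(pi, pj)
        candidates.append((-e.effective_membership, k, lo, hi))

    candidates.sort()
    used: set[int] = set()
    accepted: list[tuple[int, int]] = []
    for _, _, lo, hi in candidates:
        if lo in used or hi in used:
            continue
        used.update((lo, hi))
        accepted.append((lo, hi))

    accepted.sort()
    families = _assign_families(accepted)
    chars = ["."] * len(residues)
    for (lo, hi), fam in zip(accepted, families):
        chars[lo - 1] = BRACKET_FAMILIES[fam][0]
        chars[hi - 1] = BRACKET_FAMILIES[fam][1]
    return "".join(chars)


def _crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


def _assign_families(pairs: list[tuple[int, int]]) -> list[int]:
    """First-fit colouring of the pair-crossing conflict graph."""
    families: list[int] = []
    for idx, p in enumerate(pairs):
        taken = {
            families[i]
            for i in range(idx)
            if _crosses(pairs[i], p)
        }
        fam = next((f for f in range(len(BRACKET_FAMILIES)) if f not in taken), None)
        if fam is None:
            raise ConsensusError(
                "more than four mutually crossing bracket families required"
            )
        families.append(fam)
    return families


# ---------------------------------------------------------------------------
# output


def write_consensus_csv(cm: ConsensusMultiset, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "kind", "chain_i", "num_i", "icode_i",
                "chain_j", "num_j", "icode_j", "lw",
                "count", "membership", "constraint_flag",
            ]
        )
        for k in sorted(cm.entries):
            e = cm.entries[k]
            x = e.interaction
            writer.writerow(
                [
                    x.kind,
                    x.i.chain, x.i.number, x.i.insertion_code,
                    x.j.chain, x.j.number, x.j.insertion_code,
                    x.lw_class or "",
                    e.count, f"{e.effective_membership:.6f}", e.constraint_flag,
                ]
            )


def write_dotbracket(
    sequence: str, structure: str, path: str | Path
) -> None:
    Path(path).write_text(f"{sequence}\n{structure}\n")
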