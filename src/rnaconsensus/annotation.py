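"""Base-pair and stacking interactions with canonical identity keys.

Interactions are either imported from a CSV table (the fidelity path,
emulating the output of external annotation tools) or detected by a
built-in geometric annotator with configurable thresholds.

Interaction identity: canonical pairs and stackings are identified by the
unordered residue pair alone; non-canonical pairs additionally carry their
Leontis-Westhof class (cis/trans x Watson-Crick/Hoogsteen/Sugar edges).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model_io import ResidueRef, StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "Interaction",
    "ModelInteractionSet",
    "InteractionTableError",
    "GeometricThresholds",
    "interaction_key",
    "annotate_geometric",
    "read_interaction_table",
    "write_interaction_table",
    "KINDS",
    "LW_CLASSES",
]

KINDS = ("canonical_pair", "noncanonical_pair", "stacking")

_EDGE_ORDER = {"W": 0, "H": 1, "S": 2}

#: The 12 Leontis-Westhof classes: cis/trans x unordered edge pair.
#: cWW on a canonical base combination (AU/GC/GU) is kind=canonical_pair
#: by convention, not a non-canonical class.
LW_CLASSES = tuple(
    f"{o}{e1}{e2}"
    for o in "ct"
    for e1 in "WHS"
    for e2 in "WHS"
    if _EDGE_ORDER[e1] <= _EDGE_ORDER[e2]
)


def normalize_lw(code: str) -> str:
    """Normalise a Leontis-Westhof code to orientation + sorted edge pair.

    Accepts any of the 18 ordered spellings (e.g. ``cHW`` -> ``cWH``);
    raises ValueError for anything else.
    """
    if (
        len(code) == 3
        and code[0] in "ct"
        and code[1] in "WHS"
        and code[2] in "WHS"
    ):
        e1, e2 = sorted(code[1:], key=_EDGE_ORDER.__getitem__)
        return f"{code[0]}{e1}{e2}"
    raise ValueError(f"invalid Leontis-Westhof class {code!r}")


class InteractionTableError(Exception):
    """Malformed interaction table input."""


def _res_sort_key(r: ResidueRef):
    return (r.chain, r.number, r.insertion_code)


@dataclass(frozen=True)
class Interaction:
    """A typed interaction between two residues, stored with i < j."""

    kind: str
    i: ResidueRef
    j: ResidueRef
    lw_class: str | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if (self.i.chain, self.i.number, self.i.insertion_code) == (
            self.j.chain, self.j.number, self.j.insertion_code,
        ):
            raise ValueError("interaction requires two distinct residues")
        if self.kind == "noncanonical_pair":
            if self.lw_class is None:
                raise ValueError("noncanonical_pair requires an lw_class")
            object.__setattr__(self, "lw_class", normalize_lw(self.lw_class))
        elif self.lw_class is not None:
            raise ValueError("lw_class is only valid for noncanonical_pair")
        # normalise orientation so that i < j (edge pair is unordered,
        # so the class is unaffected by the swap)
        if _res_sort_key(self.i) > _res_sort_key(self.j):
            i, j = self.j, self.i
            object.__setattr__(self, "i", i)
            object.__setattr__(self, "j", j)

    def key(self) -> tuple:
        return interaction_key(self)


def interaction_key(x: Interaction) -> tuple:
    """Canonical identity key; symmetric in the two residues."""
    return (
        x.kind,
        x.i.chain, x.i.number, x.i.insertion_code,
        x.j.chain, x.j.number, x.j.insertion_code,
        x.lw_class or "",
    )


class ModelInteractionSet:
    """The set of unique interactions of one model, keyed by identity."""

    def __init__(self, model_id: str, interactions: Iterable[Interaction] = ()):
        self.model_id = model_id
        self._by_key: dict[tuple, Interaction] = {}
        for x in interactions:
            self.add(x)

    def add(self, x: Interaction) -> None:
        self._by_key[x.key()] = x

    def discard(self, key: tuple) -> None:
        self._by_key.pop(key, None)

    def __contains__(self, key: tuple) -> bool:
        return key in self._by_key

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def keys(self) -> set[tuple]:
        return set(self._by_key)

    def get(self, key: tuple) -> Interaction | None:
        return self._by_key.get(key)

    def copy(self) -> "ModelInteractionSet":
        return ModelInteractionSet(self.model_id, self._by_key.values())

    def __repr__(self):
        return f"ModelInteractionSet({self.model_id!r}, n={len(self)})"


# ---------------------------------------------------------------------------
# geometric annotation

PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

#: Base nitrogen/oxygen atoms that can act as hydrogen-bond donors/acceptors.
POLAR_ATOMS = {
    "A": ("N1", "N3", "N6", "N7"),
    "G": ("N1", "N2", "N3", "O6", "N7"),
    "C": ("O2", "N3", "N4"),
    "U": ("O2", "N3", "O4"),
}

#: Edge membership of polar atoms, used for Leontis-Westhof edge assignment.
EDGE_ATOMS = {
    "A": {"W": ("N1", "N6"), "H": ("N6", "N7"), "S": ("N3",)},
    "G": {"W": ("N1", "O6", "N2"), "H": ("O6", "N7"), "S": ("N3", "N2")},
    "C": {"W": ("N3", "N4", "O2"), "H": ("N4",), "S": ("O2",)},
    "U": {"W": ("N3", "O4", "O2"), "H": ("O4",), "S": ("O2",)},
}

#: Hydrogen-bond patterns of the canonical pairs (Watson-Crick AU, GC and
#: the GU wobble, which counts as canonical by the standard 2D convention).
CANONICAL_HBONDS = {
    ("A", "U"): (("N1", "N3"), ("N6", "O4")),
    ("G", "C"): (("N1", "N3"), ("O6", "N4"), ("N2", "O2")),
    ("G", "U"): (("N1", "O2"), ("O6", "N3")),
}


@dataclass(frozen=True)
class GeometricThresholds:
    """Detection thresholds of the built-in annotator (Angstrom / degrees)."""

    c1_min: float = 8.0
    c1_max: float = 12.0
    hbond_max: float = 3.5
    pair_plane_angle_max: float = 65.0
    pair_rise_max: float = 2.0  # pairs are coplanar, stacks are not
    stack_centroid_max: float = 5.5
    stack_plane_angle_max: float = 30.0
    stack_rise_min: float = 2.0
    stack_rise_max: float = 5.5


def _ring_atoms(model: StructureModel, idx: int) -> np.ndarray | None:
    base = model.residues[idx].base
    names = PURINE_RING if base in ("A", "G") else PYRIMIDINE_RING
    coords = [model.get_atom(idx, n) for n in names]
    if any(c is None for c in coords):
        return None
    return np.asarray(coords)


def _plane(ring: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = ring.mean(axis=0)
    _, _, vt = np.linalg.svd(ring - centroid)
    return centroid, vt[2]


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _edge_of(base: str, atom: str) -> str:
    for edge in "WHS":  # priority W > H > S on overlap
        if atom in EDGE_ATOMS[base][edge]:
            return edge
    return "W"


def annotate_geometric(
    model: StructureModel, thresholds: GeometricThresholds | None = None
) -> ModelInteractionSet:
    """Detect canonical/non-canonical pairs and stackings from coordinates.

    A simple threshold detector: canonical pairs require the standard
    hydrogen-bond pattern within ``hbond_max``, a C1'-C1' distance in the
    Watson-Crick range and roughly coplanar bases; remaining base-base
    contacts with at least one polar contact become non-canonical pairs
    with edges assigned by nearest contact atom and cis/trans by glycosidic
    bond sidedness; stacking requires nearby, near-parallel base planes with
    a vertical rise in the stacking range.  At most one pair interaction is
    emitted per residue pair.
    """
    th = thresholds or GeometricThresholds()
    out = ModelInteractionSet(model.model_id)
    n = len(model.residues)

    geoms: list[dict | None] = []
    for idx in range(n):
        res = model.residues[idx]
        if not res.known_base:
            geoms.append(None)
            continue
        ring = _ring_atoms(model, idx)
        c1 = model.get_atom(idx, "C1'")
        ng = model.get_atom(idx, GLYCOSIDIC_N[res.base])
        if ring is None or c1 is None or ng is None:
            logger.warning(
                "%s: residue %s missing base atoms, skipped",
                model.model_id, res.label(),
            )
            geoms.append(None)
            continue
        centroid, normal = _plane(ring)
        polar = {
            name: model.get_atom(idx, name)
            for name in POLAR_ATOMS[res.base]
            if model.get_atom(idx, name) is not None
        }
        geoms.append(
            dict(centroid=centroid, normal=normal, c1=c1, ng=ng, polar=polar)
        )

    for a in range(n):
        ga = geoms[a]
        if ga is None:
            continue
        for b in range(a + 1, n):
            gb = geoms[b]
            if gb is None:
                continue
            if np.linalg.norm(ga["centroid"] - gb["centroid"]) > 15.0:
                continue
            # stacking geometry takes precedence: bases lying face-to-face
            # (parallel planes, vertical rise in the stacking range) are
            # never emitted as pairs, which requires roughly coplanar bases
            if _is_stacked(ga, gb, th):
                out.add(
                    Interaction("stacking", model.residues[a], model.residues[b])
                )
                continue
            pair = _detect_pair(model, a, b, ga, gb, th)
            if pair is not None:
                out.add(pair)
    return out


def _rise(ga, gb) -> float:
    nb = gb["normal"] * np.sign(np.dot(ga["normal"], gb["normal"]))
    normal = ga["normal"] + nb
    normal /= np.linalg.norm(normal)
    return abs(float(np.dot(gb["centroid"] - ga["centroid"], normal)))


def _detect_pair(model, a, b, ga, gb, th: GeometricThresholds):
    res_a, res_b = model.residues[a], model.residues[b]
    if _rise(ga, gb) > th.pair_rise_max:
        return None
    angle = _plane_angle(ga["normal"], gb["normal"])
    c1c1 = float(np.linalg.norm(ga["c1"] - gb["c1"]))

    # canonical Watson-Crick / wobble geometry
    combo = (res_a.base, res_b.base)
    for (x, y), bonds in CANONICAL_HBONDS.items():
        if combo == (x, y):
            order = (ga, gb)
        elif combo == (y, x):
            order = (gb, ga)
        else:
            continue
        g1, g2 = order
        dists = []
        for a1, a2 in bonds:
            p1, p2 = g1["polar"].get(a1), g2["polar"].get(a2)
            if p1 is None or p2 is None:
                break
            dists.append(float(np.linalg.norm(p1 - p2)))
        else:
            if (
                all(d <= th.hbond_max for d in dists)
                and th.c1_min <= c1c1 <= th.c1_max
                and angle <= th.pair_plane_angle_max
            ):
                return Interaction("canonical_pair", res_a, res_b)

    # non-canonical: any polar-polar contact
    if c1c1 > th.c1_max or angle > th.pair_plane_angle_max:
        return None
    best = None
    for na, pa in ga["polar"].items():
        for nb, pb in gb["polar"].items():
            d = float(np.linalg.norm(pa - pb))
            if d <= th.hbond_max and (best is None or d < best[0]):
                best = (d, na, nb)
    if best is None:
        return None
    _, na, nb = best
    edge_a = _edge_of(res_a.base, na)
    edge_b = _edge_of(res_b.base, nb)
    orientation = _cis_or_trans(ga, gb)
    lw = f"{orientation}{edge_a}{edge_b}"
    if lw == "cWW" and combo in (
        ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")
    ):
        # a weak/distorted canonical pairing that failed the strict canonical
        # test; by convention cWW on a canonical base combination is canonical
        return Interaction("canonical_pair", res_a, res_b)
    return Interaction("noncanonical_pair", res_a, res_b, lw)


def _cis_or_trans(ga, gb) -> str:
    """cis if both glycosidic bonds lie on the same side of the N-N axis."""
    axis = gb["ng"] - ga["ng"]
    norm = ga["normal"] + gb["normal"] * np.sign(np.dot(ga["normal"], gb["normal"]))
    sa = np.dot(np.cross(axis, ga["c1"] - ga["ng"]), norm)
    sb = np.dot(np.cross(axis, gb["c1"] - gb["ng"]), norm)
    return "c" if sa * sb > 0 else "t"


def _is_stacked(ga, gb, th: GeometricThresholds) -> bool:
    d = gb["centroid"] - ga["centroid"]
    if np.linalg.norm(d) > th.stack_centroid_max:
        return False
    if _plane_angle(ga["normal"], gb["normal"]) > th.stack_plane_angle_max:
        return False
    rise = _rise(ga, gb)
    return th.stack_rise_min <= rise <= th.stack_rise_max


# ---------------------------------------------------------------------------
# interaction tables

TABLE_COLUMNS = (
    "model_id", "kind", "chain_i", "num_i", "icode_i",
    "chain_j", "num_j", "icode_j", "lw",
)


def read_interaction_table(path: str | Path) -> list[ModelInteractionSet]:
    """Read per-model interactions from CSV (one row per interaction)."""
    path = Path(path)
    sets: dict[str, ModelInteractionSet] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise InteractionTableError(f"{path}: empty interaction table")
        missing = set(TABLE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise InteractionTableError(
                f"{path}: missing columns {sorted(missing)}"
            )
        n_rows = 0
        for lineno, row in enumerate(reader, start=2):
            n_rows += 1
            try:
                kind = row["kind"].strip()
                if kind not in KINDS:
                    raise ValueError(f"unknown kind {kind!r}")
                lw = (row["lw"] or "").strip() or None
                if kind != "noncanonical_pair":
                    lw = None
                ri = ResidueRef(
                    row["chain_i"].strip(), int(row["num_i"]),
                    (row["icode_i"] or "").strip(), "N",
                )
                rj = ResidueRef(
                    row["chain_j"].strip(), int(row["num_j"]),
                    (row["icode_j"] or "").strip(), "N",
                )
                x = Interaction(kind, ri, rj, lw)
            except (ValueError, KeyError) as exc:
                raise InteractionTableError(f"{path}:{lineno}: {exc}") from exc
            mid = row["model_id"].strip()
            sets.setdefault(mid, ModelInteractionSet(mid)).add(x)
        if n_rows == 0:
            raise InteractionTableError(f"{path}: empty interaction table")
    return list(sets.values())


def write_interaction_table(
    sets: Sequence[ModelInteractionSet], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TABLE_COLUMNS)
        for s in sets:
            for x in sorted(s, key=interaction_key):
                writer.writerow(
                    [
                        s.model_id, x.kind,
                        x.i.chain, x.i.number, x.i.insertion_code,
                        x.j.chain, x.j.number, x.j.insertion_code,
                        x.lw_class or "",
                    ]
                )
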