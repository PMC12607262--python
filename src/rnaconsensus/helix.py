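"""Idealized A-form RNA duplex construction from residue templates.

Builds synthetic double-helical RNA coordinates good enough for geometric
interaction detection: Watson-Crick pairs are assembled by the standard
dyad construction (both glycosidic bonds at the lambda angle to the
C1'-C1' line, partner strand related by a two-fold rotation in the pair
plane) and successive pairs are stacked with A-form rise and twist.
Residue geometry comes from the Chemical Component Dictionary templates
bundled with biotite.

The output is intentionally idealized — flat, perfectly regular pairs —
and is meant for tests and demos, not for modelling real RNA.
"""

from __future__ import annotations

import numpy as np
from biotite.structure.info import residue as ccd_residue

from .model_io import Atom, ResidueRef, StructureModel

__all__ = ["build_duplex", "COMPLEMENT"]

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# A-form helix parameters
RISE = 2.81  # Angstrom per base pair
TWIST = 32.7  # degrees per base pair
C1_C1 = 10.4  # Angstrom across a Watson-Crick pair
LAMBDA = 54.5  # degrees: glycosidic bond vs the C1'-C1' line

_PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
_GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}


def _template(base: str) -> tuple[list[str], np.ndarray]:
    arr = ccd_residue(base)
    mask = arr.element != "H"
    names = list(arr.atom_name[mask])
    coords = np.asarray(arr.coord[mask], dtype=float)
    return names, coords


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(axis, axis)


def _place_base(base: str, mirror: bool) -> tuple[list[str], np.ndarray]:
    """Place a nucleotide template into the standard pair frame.

    The base plane becomes z = 0, C1' sits at (-C1_C1/2, 0, 0) and the
    glycosidic bond points at the lambda angle above the +x axis; with
    ``mirror`` the placed residue is then rotated 180 degrees about the
    y axis, producing the antiparallel partner position.
    """
    names, coords = _template(base)
    idx = {n: i for i, n in enumerate(names)}
    ring_names = _PURINE_RING if base in "AG" else _PYRIMIDINE_RING
    ring = coords[[idx[n] for n in ring_names]]
    c1 = coords[idx["C1'"]]
    ng = coords[idx[_GLYCOSIDIC_N[base]]]

    # template frame: e1 along C1'->N, e3 the ring normal (orthogonalised),
    # e2 chosen so the base body lies on the +e2 side
    centroid = ring.mean(axis=0)
    _, _, vt = np.linalg.svd(ring - centroid)
    normal = vt[2]
    e1 = ng - c1
    e1 /= np.linalg.norm(e1)
    e3 = normal - np.dot(normal, e1) * e1
    e3 /= np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    if np.dot(centroid - ng, e2) < 0:
        e2 = -e2
        e3 = np.cross(e1, e2)
    frame = np.stack([e1, e2, e3])  # rows

    # target frame: C1'->N direction at +LAMBDA from +x in the xy-plane,
    # base body toward the helix axis (+x half-plane)
    lam = np.radians(LAMBDA)
    t1 = np.array([np.cos(lam), np.sin(lam), 0.0])
    t3 = np.array([0.0, 0.0, 1.0])
    t2 = np.cross(t3, t1)
    if t2[0] < 0:
        t2 = -t2
        t3 = np.cross(t1, t2)
    target = np.stack([t1, t2, t3])

    rot = target.T @ frame
    placed = (coords - c1) @ rot.T + np.array([-C1_C1 / 2, 0.0, 0.0])
    if mirror:
        placed = placed @ np.diag([-1.0, 1.0, -1.0]).T
    return names, placed


def build_duplex(
    sequence: str,
    model_id: str = "duplex",
    *,
    rise: float = RISE,
    twist: float = TWIST,
) -> StructureModel:
    """Build an idealized A-form duplex for ``sequence`` (chain A, 5'->3')
    paired with its reverse complement (chain B)."""
    sequence = sequence.upper()
    if not set(sequence) <= set("ACGU"):
        raise ValueError("sequence must be over the ACGU alphabet")
    length = len(sequence)
    z_axis = np.array([0.0, 0.0, 1.0])

    strand_a: list[tuple[str, list[str], np.ndarray]] = []
    strand_b: list[tuple[str, list[str], np.ndarray]] = []
    for k, base in enumerate(sequence):
        comp = COMPLEMENT[base]
        names_a, coords_a = _place_base(base, mirror=False)
        names_b, coords_b = _place_base(comp, mirror=True)
        step = _rotation(z_axis, k * twist)
        shift = np.array([0.0, 0.0, k * rise])
        strand_a.append((base, names_a, coords_a @ step.T + shift))
        strand_b.append((comp, names_b, coords_b @ step.T + shift))

    residues: list[ResidueRef] = []
    atoms: list[list[Atom]] = []
    for num, (base, names, coords) in enumerate(strand_a, start=1):
        residues.append(ResidueRef("A", num, "", base))
        atoms.append([Atom(n, c.copy()) for n, c in zip(names, coords)])
    # chain B runs antiparallel: 5'->3' is pair index descending
    for num, (base, names, coords) in enumerate(reversed(strand_b), start=1):
        residues.append(ResidueRef("B", num, "", base))
        atoms.append([Atom(n, c.copy()) for n, c in zip(names, coords)])
    return StructureModel(model_id, residues, atoms)
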