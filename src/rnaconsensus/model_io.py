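"""Reading, unification and validation of RNA 3D model ensembles.

Supports PDB and PDBx/mmCIF files (including multi-model files) and
ZIP / TAR.GZ archives thereof.  All models of an ensemble are expected to
share the same nucleotide composition; chain names and residue numbers are
normalised internally so that models from heterogeneous sources become
comparable.
"""

from __future__ import annotations

import io
import logging
import tarfile
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueRef",
    "Atom",
    "StructureModel",
    "ConsistencyReport",
    "EnsembleError",
    "ParseError",
    "EmptyEnsembleError",
    "load_ensemble",
    "unify_ensemble",
    "check_consistency",
    "check_pdb_limits",
    "write_pdb",
    "write_unification_map",
]

# Legacy PDB format ceilings: 5-digit atom serials, 4-digit residue numbers,
# single-character chain identifiers drawn from A-Z, a-z, 0-9.
MAX_PDB_ATOMS = 99_999
MAX_PDB_RESIDUES = 9_999
MAX_PDB_CHAINS = 62

CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ" "abcdefghijklmnopqrstuvwxyz" "0123456789"
)

#: Modified nucleotides mapped to their parent base.  Residues absent from
#: this table and from the standard four are excluded from interaction
#: analysis.
MODIFIED_BASES = {
    "PSU": "U", "H2U": "U", "5MU": "U", "4SU": "U", "OMU": "U", "UR3": "U",
    "DHU": "U", "3MU": "U",
    "1MA": "A", "2MA": "A", "A2M": "A", "MIA": "A", "MA6": "A", "6MA": "A",
    "1MG": "G", "2MG": "G", "M2G": "G", "7MG": "G", "OMG": "G", "G7M": "G",
    "YG": "G", "I": "G", "QUO": "G",
    "5MC": "C", "OMC": "C", "4OC": "C", "M5C": "C",
}

STANDARD_BASES = {"A", "C", "G", "U"}


class EnsembleError(Exception):
    """Base class for ensemble input errors."""


class ParseError(EnsembleError):
    """A file could not be parsed as PDB or PDBx/mmCIF."""


class EmptyEnsembleError(EnsembleError):
    """No structure models were found in the given inputs."""


@dataclass(frozen=True, order=True)
class ResidueRef:
    """A residue identifier plus its (possibly remapped) base identity."""

    chain: str
    number: int
    insertion_code: str = ""
    base: str = "N"  # parent base A/C/G/U, or N when unknown

    def __post_init__(self):
        if not self.chain:
            raise ValueError("chain label must be non-empty")

    @property
    def known_base(self) -> bool:
        return self.base in STANDARD_BASES

    def label(self) -> str:
        ic = self.insertion_code or ""
        return f"{self.chain}{self.number}{ic}"


class Atom(NamedTuple):
    name: str
    coord: np.ndarray  # shape (3,), Angstrom


@dataclass
class StructureModel:
    """One RNA 3D model: ordered residues with their atoms."""

    model_id: str
    residues: list[ResidueRef]
    atoms: list[list[Atom]]  # parallel to residues

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"model {self.model_id!r} has no residues")
        if len(self.atoms) != len(self.residues):
            raise ValueError("atoms must parallel residues")

    @property
    def atom_count(self) -> int:
        return sum(len(a) for a in self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen

    def sequence_signature(self) -> tuple[tuple[str, str], ...]:
        """Per-chain base sequence, in chain order: ((chain, 'ACGU...'), ...)."""
        out: dict[str, list[str]] = {}
        for r in self.residues:
            out.setdefault(r.chain, []).append(r.base)
        return tuple((c, "".join(b)) for c, b in out.items())

    def get_atom(self, res_index: int, name: str) -> np.ndarray | None:
        for a in self.atoms[res_index]:
            if a.name == name:
                return a.coord
        return None


@dataclass
class ConsistencyReport:
    consistent: bool
    signatures: dict[str, tuple[tuple[str, str], ...]]
    divergent_models: list[str] = field(default_factory=list)
    first_divergence: str | None = None


# ---------------------------------------------------------------------------
# loading


def _sniff_format(text: str, path: Path) -> gemmi.CoorFormat:
    """Detect coordinate format from content, with extension fallback."""
    head = text[:20000]
    if "_atom_site." in head or head.lstrip().startswith("data_"):
        return gemmi.CoorFormat.Mmcif
    for line in head.splitlines():
        rec = line[:6].strip()
        if rec in {"ATOM", "HETATM", "MODEL", "HEADER", "CRYST1", "SEQRES"}:
            return gemmi.CoorFormat.Pdb
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".cif", ".mmcif", ".cif.gz")):
        return gemmi.CoorFormat.Mmcif
    if suffix.endswith((".pdb", ".ent")):
        return gemmi.CoorFormat.Pdb
    raise ParseError(f"{path}: not recognisable as PDB or PDBx/mmCIF")


def _parent_base(resname: str) -> str:
    name = resname.strip().upper()
    if name in STANDARD_BASES:
        return name
    return MODIFIED_BASES.get(name, "N")


def _models_from_structure(st: gemmi.Structure, stem: str) -> list[StructureModel]:
    models: list[StructureModel] = []
    multi = len(st) > 1
    for k, gm in enumerate(st, start=1):
        residues: list[ResidueRef] = []
        atoms: list[list[Atom]] = []
        for chain in gm:
            for res in chain:
                base = _parent_base(res.name)
                if base == "N":
                    # Non-nucleotide (protein, ion, water) or unmappable
                    # modified residue: excluded from analysis.
                    logger.warning(
                        "%s: skipping non-nucleotide residue %s %s%d",
                        stem, res.name, chain.name, res.seqid.num,
                    )
                    continue
                icode = res.seqid.icode.strip()
                residues.append(
                    ResidueRef(chain.name, res.seqid.num, icode, base)
                )
                seen: set[str] = set()
                res_atoms = []
                for at in res:
                    if at.is_hydrogen() or at.name in seen:
                        continue  # first altloc wins
                    seen.add(at.name)
                    res_atoms.append(
                        Atom(at.name, np.array([at.pos.x, at.pos.y, at.pos.z]))
                    )
                atoms.append(res_atoms)
        if not residues:
            continue
        model_id = f"{stem}#{k}" if multi else stem
        models.append(StructureModel(model_id, residues, atoms))
    return models


def _load_text(text: str, path: Path, stem: str) -> list[StructureModel]:
    fmt = _sniff_format(text, path)
    try:
        if fmt == gemmi.CoorFormat.Pdb:
            st = gemmi.read_pdb_string(text)
        else:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    models = _models_from_structure(st, stem)
    if not models:
        raise ParseError(f"{path}: no nucleotide residues found")
    return models


_ARCHIVE_SUFFIXES = (".zip", ".tar.gz", ".tgz", ".tar")


def _iter_archive(path: Path) -> Iterable[tuple[str, str]]:
    """Yield (member name, text) for regular members of a ZIP or TAR archive."""
    name = path.name.lower()
    if name.endswith(".zip"):
        with zipfile.ZipFile(path) as zf:
            for info in zf.infolist():
                if info.is_dir():
                    continue
                yield info.filename, zf.read(info).decode("utf-8", "replace")
    else:
        with tarfile.open(path, "r:*") as tf:
            for member in tf.getmembers():
                if not member.isfile():
                    continue
                fh = tf.extractfile(member)
                if fh is None:
                    continue
                yield member.name, fh.read().decode("utf-8", "replace")


def load_ensemble(paths: str | Path | Sequence[str | Path]) -> list[StructureModel]:
    """Load an ensemble from structure files and/or archives.

    Multi-model files are split into one :class:`StructureModel` per MODEL
    record; archives are unpacked one level deep; non-structure members are
    skipped with a warning.  Model ids are made unique by appending
    ``_1``, ``_2``, ... on clashes.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    models: list[StructureModel] = []
    for p in map(Path, paths):
        if not p.exists():
            raise EnsembleError(f"input path does not exist: {p}")
        if p.name.lower().endswith(_ARCHIVE_SUFFIXES):
            for member, text in _iter_archive(p):
                mpath = Path(member)
                if mpath.name.lower().endswith(_ARCHIVE_SUFFIXES):
                    logger.warning("%s: nested archive %s skipped", p, member)
                    continue
                try:
                    models.extend(_load_text(text, mpath, mpath.stem))
                except ParseError as exc:
                    logger.warning("%s: skipping member %s (%s)", p, member, exc)
        else:
            models.extend(_load_text(p.read_text(errors="replace"), p, p.stem))
    if not models:
        raise EmptyEnsembleError("no structure models found in the given inputs")
    # deduplicate ids
    seen: dict[str, int] = {}
    for i, m in enumerate(models):
        if m.model_id in seen:
            seen[m.model_id] += 1
            models[i] = replace_model_id(m, f"{m.model_id}_{seen[m.model_id]}")
        else:
            seen[m.model_id] = 0
    return models


def replace_model_id(model: StructureModel, new_id: str) -> StructureModel:
    return StructureModel(new_id, model.residues, model.atoms)


# ---------------------------------------------------------------------------
# unification


def unify_ensemble(
    models: Sequence[StructureModel], *, mapping_out: list[dict] | None = None
) -> list[StructureModel]:
    """Rename chains to A, B, C... and renumber residues 1..k per chain.

    Chains are renamed in order of first appearance within each model;
    insertion codes are cleared; coordinates are untouched.  Idempotent.
    If ``mapping_out`` is given, one dict per residue describing the
    old -> new identifier mapping is appended to it.
    """
    if not models:
        raise EnsembleError("unify_ensemble requires at least one model")
    unified = []
    for m in models:
        chain_map: dict[str, str] = {}
        counters: dict[str, int] = {}
        new_res: list[ResidueRef] = []
        for r in m.residues:
            if r.chain not in chain_map:
                if len(chain_map) >= len(CHAIN_ALPHABET):
                    raise EnsembleError(
                        f"model {m.model_id!r} has more than "
                        f"{len(CHAIN_ALPHABET)} chains"
                    )
                chain_map[r.chain] = CHAIN_ALPHABET[len(chain_map)]
            new_chain = chain_map[r.chain]
            counters[new_chain] = counters.get(new_chain, 0) + 1
            nr = ResidueRef(new_chain, counters[new_chain], "", r.base)
            new_res.append(nr)
            if mapping_out is not None:
                mapping_out.append(
                    {
                        "model_id": m.model_id,
                        "old_chain": r.chain,
                        "old_number": r.number,
                        "old_icode": r.insertion_code,
                        "new_chain": nr.chain,
                        "new_number": nr.number,
                    }
                )
        unified.append(StructureModel(m.model_id, new_res, m.atoms))
    return unified


def check_consistency(models: Sequence[StructureModel]) -> ConsistencyReport:
    """Compare per-chain base sequences across all (unified) models."""
    signatures = {m.model_id: m.sequence_signature() for m in models}
    ref_id = models[0].model_id
    ref = signatures[ref_id]
    divergent: list[str] = []
    first_div: str | None = None
    for m in models[1:]:
        sig = signatures[m.model_id]
        if sig != ref:
            divergent.append(m.model_id)
            if first_div is None:
                first_div = _describe_divergence(ref, sig, m.model_id)
    return ConsistencyReport(
        consistent=not divergent,
        signatures=signatures,
        divergent_models=divergent,
        first_divergence=first_div,
    )


def _describe_divergence(ref, sig, model_id: str) -> str:
    if len(ref) != len(sig):
        return (
            f"{model_id}: chain count {len(sig)} differs from reference "
            f"{len(ref)}"
        )
    for (rc, rseq), (sc, sseq) in zip(ref, sig):
        if rseq != sseq:
            n = min(len(rseq), len(sseq))
            for pos in range(n):
                if rseq[pos] != sseq[pos]:
                    return (
                        f"{model_id}: chain {sc} position {pos + 1}: "
                        f"{sseq[pos]} vs {rseq[pos]}"
                    )
            return f"{model_id}: chain {sc} length {len(sseq)} vs {len(rseq)}"
    return f"{model_id}: signatures differ"


def check_pdb_limits(model: StructureModel) -> list[str]:
    """Return violations of the legacy PDB format ceilings (empty if ok)."""
    violations = []
    if model.atom_count > MAX_PDB_ATOMS:
        violations.append(f"atom count exceeds {MAX_PDB_ATOMS:,}")
    if len(model.residues) > MAX_PDB_RESIDUES:
        violations.append(f"residue count exceeds {MAX_PDB_RESIDUES:,}")
    if len(model.chain_ids) > MAX_PDB_CHAINS:
        violations.append(f"chain count exceeds {MAX_PDB_CHAINS}")
    return violations


# ---------------------------------------------------------------------------
# output


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Emit a single-model PDB file for a (unified) model."""
    lines = []
    serial = 0
    prev_chain = None
    for res, res_atoms in zip(model.residues, model.atoms):
        if prev_chain is not None and res.chain != prev_chain:
            lines.append("TER")
        prev_chain = res.chain
        for at in res_atoms:
            serial += 1
            name = at.name if len(at.name) == 4 else f" {at.name:<3s}"
            elem = at.name.strip("'0123456789")[:1]
            x, y, z = at.coord
            lines.append(
                f"ATOM  {serial:5d} {name:4s} {res.base:>3s} {res.chain:1s}"
                f"{res.number:4d}{res.insertion_code or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {elem:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_unification_map(mapping: list[dict], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        mapping,
        columns=[
            "model_id", "old_chain", "old_number", "old_icode",
            "new_chain", "new_number",
        ],
    ).to_csv(path, index=False)
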