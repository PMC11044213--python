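"""Structure input and residue-level reduction.

Reads PDB/mmCIF files (via gemmi), reduces each amino-acid residue to a
single *effective atom* — the unweighted mean of its heavy-atom coordinates —
and attaches intrinsic hydrophobicities from a named scale.  Waters and
non-polymer heteroatoms never enter the profiles; altlocs are resolved to the
highest-occupancy conformer (ties broken by file order); only the first model
of multi-model files is read.

Unit selections use a small expression language resolved against author
numbering::

    "Q"            one chain
    "A-P"          an alphabetic chain range
    "A,B,C"        a chain list
    "A:250-461"    a residue range on one chain
    "7LUP:Q"       a leading structure tag (ignored) plus any of the above
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .scales import HydrophobicityScale, ScaleError, get_scale

__all__ = [
    "ResidueRecord", "Residue", "StructureModel", "UnitSelection",
    "parse_structure", "effective_atoms", "assign_hydrophobicity",
    "select", "StructureError", "SelectionError",
]

#: (chain_id, seq_id, insertion_code) — unique residue key after filtering.
ResKey = tuple[str, int, str]


class StructureError(ValueError):
    """Unreadable, empty or geometrically unusable structure input."""


class SelectionError(ValueError):
    """A unit selection does not resolve against the structure."""


@dataclass(frozen=True)
class ResidueRecord:
    """One residue reduced to its effective atom.

    ``position`` is the unweighted mean of the residue's heavy-atom
    coordinates in Å; ``h_intrinsic`` is the intrinsic hydrophobicity from
    the configured scale (NaN until assigned).
    """

    chain_id: str
    seq_id: int
    insertion_code: str
    aa_type: str
    position: np.ndarray
    h_intrinsic: float = math.nan

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"bad effective-atom position for {self.key}")
        if not math.isnan(self.h_intrinsic) and self.h_intrinsic < 0:
            raise StructureError(f"negative hydrophobicity for {self.key}")

    @property
    def key(self) -> ResKey:
        return (self.chain_id, self.seq_id, self.insertion_code)


@dataclass
class Residue:
    """Atom-level residue as deposited (heavy atoms only)."""

    chain_id: str
    seq_id: int
    insertion_code: str
    aa_type: str
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3)

    @property
    def key(self) -> ResKey:
        return (self.chain_id, self.seq_id, self.insertion_code)


@dataclass
class StructureModel:
    """Ordered polymer residues of one model, grouped by chain."""

    residues: list[Residue]
    source: str = ""
    model_number: int = 1
    _index: dict[ResKey, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for i, res in enumerate(self.residues):
            if res.key in self._index:
                raise StructureError(f"duplicate residue key {res.key}")
            self._index[res.key] = i

    @property
    def chain_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for res in self.residues:
            seen.setdefault(res.chain_id, None)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, key: ResKey) -> Residue:
        try:
            return self.residues[self._index[key]]
        except KeyError:
            raise SelectionError(f"residue {key} absent from structure") from None

    def __contains__(self, key: ResKey) -> bool:
        return key in self._index

    def chain(self, chain_id: str) -> list[Residue]:
        out = [r for r in self.residues if r.chain_id == chain_id]
        if not out:
            raise SelectionError(f"chain {chain_id!r} absent from structure")
        return out


@dataclass(frozen=True)
class UnitSelection:
    """The residues forming one analyzed structural unit.

    ``scope`` states whether the Gaussian envelope spans the unit itself or
    an enclosing complex; in the latter case ``complex_members`` holds the
    residues the envelope (and the profiles it normalizes) spans, and the
    members must be a subset of them.
    """

    members: tuple[ResKey, ...]
    scope: Literal["unit", "complex"] = "unit"
    complex_members: tuple[ResKey, ...] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise SelectionError("empty unit selection")
        if self.scope == "complex":
            if self.complex_members is None:
                raise SelectionError("scope='complex' requires complex_members")
            if not set(self.members) <= set(self.complex_members):
                raise SelectionError("members must be a subset of complex_members")
        elif self.scope != "unit":
            raise SelectionError(f"unknown gaussian scope {self.scope!r}")

    def __len__(self) -> int:
        return len(self.members)


# -- parsing ---------------------------------------------------------------

def _is_amino_acid(name: str) -> bool:
    import gemmi

    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def parse_structure(path: str | Path, fmt: str = "auto") -> StructureModel:
    """Read the polymer residues of the first model of a PDB/mmCIF file.

    Waters and non-amino-acid heteroatoms are dropped; hydrogens are dropped;
    altlocs resolve to the highest-occupancy conformer (ties: first in file).
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    try:
        if fmt == "auto":
            st = gemmi.read_structure(str(path))
        elif fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except StructureError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]

    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            if res.name == "HOH" or not _is_amino_acid(res.name):
                continue
            names, coords = _resolve_altlocs(res)
            if not names:
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_id=res.seqid.num,
                    insertion_code=(res.seqid.icode or " ").strip(),
                    aa_type=res.name.upper(),
                    atom_names=names,
                    coords=np.array(coords, dtype=float),
                )
            )
    if not residues:
        raise StructureError(f"{path}: no polymer residues")
    return StructureModel(residues, source=str(path), model_number=1)


def _resolve_altlocs(res) -> tuple[list[str], list[list[float]]]:
    """Keep one conformer per atom name: highest occupancy, ties first seen."""
    best: dict[str, tuple[float, int, list[float]]] = {}
    order: list[str] = []
    for i, atom in enumerate(res):
        if atom.is_hydrogen():
            continue
        pos = [atom.pos.x, atom.pos.y, atom.pos.z]
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = (atom.occ, i, pos)
            order.append(atom.name)
        elif atom.occ > prev[0]:
            best[atom.name] = (atom.occ, prev[1], pos)
    return order, [best[n][2] for n in order]


# -- selection language ----------------------------------------------------

def _expand_chain_expr(expr: str, chain_ids: Sequence[str]) -> list[str]:
    chains: list[str] = []
    for token in expr.split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token and len(token) == 3:  # "A-P"
            lo, hi = token.split("-")
            if len(lo) == 1 and len(hi) == 1 and lo <= hi:
                rng = [c for c in chain_ids if lo <= c <= hi and len(c) == 1]
                if not rng:
                    raise SelectionError(f"chain range {token!r} matches nothing")
                chains.extend(rng)
                continue
        chains.append(token)
    return chains


def _parse_ranges(expr: str) -> list[tuple[int, int]]:
    out = []
    for token in expr.split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token[1:]:  # allow negative seq ids
            lo_s, hi_s = token[1:].split("-", 1)
            lo, hi = int(token[0] + lo_s), int(hi_s)
        else:
            lo = hi = int(token)
        if hi < lo:
            raise SelectionError(f"bad residue range {token!r}")
        out.append((lo, hi))
    return out


def resolve_expression(model: StructureModel, expr: str) -> tuple[ResKey, ...]:
    """Resolve a selection expression to residue keys in deposited order."""
    parts = [p for p in expr.strip().split(":") if p != ""]
    # A leading tag that is not a chain expression of this structure (e.g. a
    # PDB id like "7LUP") is ignored.
    if len(parts) > 1:
        try:
            head = _expand_chain_expr(parts[0], model.chain_ids)
        except SelectionError:
            head = []
        if not head or not all(c in model.chain_ids for c in head):
            parts = parts[1:]
    if len(parts) == 0:
        raise SelectionError(f"empty selection expression {expr!r}")
    if len(parts) > 2:
        raise SelectionError(f"cannot parse selection {expr!r}")

    chains = _expand_chain_expr(parts[0], model.chain_ids)
    ranges = _parse_ranges(parts[1]) if len(parts) == 2 else None

    wanted = set(chains)
    missing = wanted - set(model.chain_ids)
    if missing:
        raise SelectionError(f"chains {sorted(missing)} absent from structure")

    keys = []
    for res in model.residues:
        if res.chain_id not in wanted:
            continue
        if ranges is not None and not any(lo <= res.seq_id <= hi for lo, hi in ranges):
            continue
        keys.append(res.key)
    if not keys:
        raise SelectionError(f"selection {expr!r} resolves to no residues")
    return tuple(keys)


def select(
    model: StructureModel,
    expr: str,
    scope: Literal["unit", "complex"] = "unit",
    complex_expr: str | None = None,
    label: str | None = None,
) -> UnitSelection:
    """Build a :class:`UnitSelection` from expression strings.

    With ``scope='complex'`` the Gaussian spans ``complex_expr`` (default:
    every polymer residue of the structure).
    """
    members = resolve_expression(model, expr)
    complex_members = None
    if scope == "complex":
        if complex_expr is None:
            complex_members = tuple(r.key for r in model.residues)
        else:
            complex_members = resolve_expression(model, complex_expr)
    return UnitSelection(
        members=members,
        scope=scope,
        complex_members=complex_members,
        label=label if label is not None else expr,
    )


# -- residue reduction -----------------------------------------------------

def effective_atoms(
    model: StructureModel, selection: UnitSelection | Iterable[ResKey]
) -> list[ResidueRecord]:
    """Reduce selected residues to effective atoms (mean heavy-atom position).

    Order follows the selection; hydrophobicities are left unassigned.
    """
    keys = selection.members if isinstance(selection, UnitSelection) else tuple(selection)
    records = []
    for key in keys:
        res = model[key]
        if res.coords.shape[0] == 0:
            raise StructureError(f"residue {key} has no heavy atoms")
        records.append(
            ResidueRecord(
                chain_id=res.chain_id,
                seq_id=res.seq_id,
                insertion_code=res.insertion_code,
                aa_type=res.aa_type,
                position=res.coords.mean(axis=0),
            )
        )
    return records


def assign_hydrophobicity(
    records: Sequence[ResidueRecord],
    scale: str | HydrophobicityScale | None = None,
    strict: bool = True,
) -> list[ResidueRecord]:
    """Attach intrinsic hydrophobicities from a scale; other fields unchanged.

    With ``strict=True`` (default) a residue type the scale does not cover
    raises :class:`~fodm.scales.ScaleError`; otherwise it gets 0.
    """
    sc = get_scale(scale) if scale is not None else get_scale()
    out = []
    for rec in records:
        if rec.aa_type in sc:
            h = sc[rec.aa_type]
        elif strict:
            raise ScaleError(
                f"residue type {rec.aa_type!r} at {rec.key} not covered by "
                f"scale {sc.name!r}"
            )
        else:
            h = 0.0
        out.append(replace(rec, h_intrinsic=h))
    return out
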