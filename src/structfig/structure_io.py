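"""PDB-format reading and writing into a hierarchical structure model.

Parsing is strictly column-positional (wwPDB v3.3 fixed columns), never
whitespace-tokenized: an alpha-carbon atom name ``" CA "`` and a calcium
heteroatom ``"CA  "`` occupy different columns and carry different element
symbols, and both survive a read -> write -> read round trip.

Only ATOM/HETATM records are interpreted; MODEL/ENDMDL delimit models and
the first model is returned unless another index is requested. All other
record types are ignored. Coordinates are written with 3 decimals and
B-factors with 2, so a model whose fields are quantized to that precision
round-trips losslessly (the fixture generators quantize for this reason).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    ChainNotFoundError,
    CoordinateOverflowError,
    EmptyStructureError,
    PDBParseError,
)

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "StructureModel",
    "CATrace",
    "read_pdb",
    "write_pdb",
    "ca_trace",
]


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record. Coordinates in Å, author residue numbering."""

    serial: int
    name: str
    altloc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    b_factor: float = 0.0
    element: str = ""
    seg_id: str = ""
    is_hetatm: bool = False

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Residue:
    res_name: str
    res_seq: int
    i_code: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.res_seq, self.i_code)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class StructureModel:
    """model -> chain -> residue -> atom hierarchy."""

    model_id: str = "1"
    chains: list[Chain] = field(default_factory=list)

    def atoms(self):
        """Iterate all atoms in file order."""
        for chain in self.chains:
            for res in chain.residues:
                yield from res.atoms

    def residues(self):
        """Iterate (chain, residue) in file order."""
        for chain in self.chains:
            for res in chain.residues:
                yield chain, res

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        raise ChainNotFoundError(
            f"chain {chain_id!r} not found; have "
            f"{[c.chain_id for c in self.chains]}"
        )

    def map_coords(self, func) -> "StructureModel":
        """Return a copy with every atom's coordinates passed through *func*
        (a callable mapping an (N, 3) array to an (N, 3) array)."""
        coords = np.array([[a.x, a.y, a.z] for a in self.atoms()], dtype=float)
        new = np.asarray(func(coords), dtype=float)
        out = StructureModel(model_id=self.model_id)
        i = 0
        for chain in self.chains:
            new_chain = Chain(chain.chain_id)
            for res in chain.residues:
                new_res = Residue(res.res_name, res.res_seq, res.i_code)
                for atom in res.atoms:
                    x, y, z = new[i]
                    new_res.atoms.append(replace(atom, x=float(x), y=float(y), z=float(z)))
                    i += 1
                new_chain.residues.append(new_res)
            out.chains.append(new_chain)
        return out


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(f"malformed {what} field {text!r}", lineno) from None


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise PDBParseError(f"malformed {what} field {text!r}", lineno) from None


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    line = line.rstrip("\n").ljust(80)
    x = _parse_float(line[30:38], "x", lineno)
    y = _parse_float(line[38:46], "y", lineno)
    z = _parse_float(line[46:54], "z", lineno)
    if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
        raise PDBParseError("non-finite coordinate", lineno)
    occ = line[54:60].strip()
    bfac = line[60:66].strip()
    return AtomRecord(
        serial=_parse_int(line[6:11], "serial", lineno),
        name=line[12:16].strip(),
        altloc=line[16].strip(),
        res_name=line[17:20].strip(),
        chain_id=line[21].strip(),
        res_seq=_parse_int(line[22:26], "resSeq", lineno),
        i_code=line[26].strip(),
        x=x,
        y=y,
        z=z,
        occupancy=_parse_float(occ, "occupancy", lineno) if occ else 1.0,
        b_factor=_parse_float(bfac, "bfactor", lineno) if bfac else 0.0,
        element=line[76:78].strip(),
        seg_id=line[72:76].strip(),
        is_hetatm=line[:6].strip() == "HETATM",
    )


def _group(model_id: str, atoms: list[AtomRecord]) -> StructureModel:
    model = StructureModel(model_id=model_id)
    chain: Chain | None = None
    res: Residue | None = None
    for atom in atoms:
        if chain is None or chain.chain_id != atom.chain_id:
            chain = next(
                (c for c in model.chains if c.chain_id == atom.chain_id), None
            )
            if chain is None:
                chain = Chain(atom.chain_id)
                model.chains.append(chain)
            res = chain.residues[-1] if chain.residues else None
        rkey = (atom.res_name, atom.res_seq, atom.i_code)
        if res is None or (res.res_name, res.res_seq, res.i_code) != rkey:
            res = Residue(atom.res_name, atom.res_seq, atom.i_code)
            chain.residues.append(res)
        res.atoms.append(atom)
    return model


def read_pdb(text: str, model_index: int = 0) -> StructureModel:
    """Parse PDB-format text and return one model (the first by default).

    Parameters
    ----------
    text:
        Full PDB file content.
    model_index:
        0-based index into the MODEL blocks of a multi-model file. Files
        without MODEL records contain exactly one implicit model.

    Raises
    ------
    EmptyStructureError
        If the selected model contains no ATOM/HETATM record.
    PDBParseError
        On a malformed numeric field (the message names the line number).
    """
    models: list[tuple[str, list[AtomRecord]]] = []
    current: list[AtomRecord] = []
    current_id = "1"
    in_model_block = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current and not in_model_block:
                models.append((current_id, current))
            current = []
            current_id = line[10:14].strip() or str(len(models) + 1)
            in_model_block = True
        elif rec == "ENDMDL":
            models.append((current_id, current))
            current = []
            current_id = str(len(models) + 1)
            in_model_block = False
        elif rec in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
    if current:
        models.append((current_id, current))
    if not models or not any(atoms for _, atoms in models):
        raise EmptyStructureError("no ATOM/HETATM records found")
    if model_index >= len(models):
        raise PDBParseError(
            f"model index {model_index} out of range ({len(models)} models)"
        )
    model_id, atoms = models[model_index]
    if not atoms:
        raise EmptyStructureError("no ATOM/HETATM records found")
    serials = [a.serial for a in atoms]
    if len(set(serials)) != len(serials):
        raise PDBParseError("duplicate atom serial numbers within one model")
    return _group(model_id, atoms)


def _format_name(atom: AtomRecord) -> str:
    # Atom-name column convention: 1-letter elements start in column 14,
    # 2-letter elements (and 4-char names) in column 13.
    name = atom.name
    if len(name) >= 4:
        return name[:4]
    if len(atom.element.strip()) == 2:
        return name.ljust(4)
    return (" " + name).ljust(4)


def format_atom_line(atom: AtomRecord) -> str:
    """Render one fixed-column ATOM/HETATM line (no trailing newline)."""
    for value in (atom.x, atom.y, atom.z):
        if not (-999.999 <= value <= 9999.999):
            raise CoordinateOverflowError(
                f"coordinate {value} does not fit the 8.3 PDB field"
            )
    record = "HETATM" if atom.is_hetatm else "ATOM"
    return (
        f"{record:<6s}{atom.serial:>5d} {_format_name(atom)}"
        f"{atom.altloc or ' ':1s}{atom.res_name:>3s} {atom.chain_id or ' ':1s}"
        f"{atom.res_seq:>4d}{atom.i_code or ' ':1s}   "
        f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
        f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}      "
        f"{atom.seg_id:<4s}{atom.element:>2s}"
    )


def write_pdb(model: StructureModel) -> str:
    """Serialize a model to PDB-format text (ATOM/HETATM lines + END).

    The B-factor column is written from each atom's ``b_factor`` field, so
    callers may use it as a carrier for per-residue distances or other
    attribute values.
    """
    if model.n_atoms == 0:
        raise EmptyStructureError("cannot write an empty model")
    lines = [format_atom_line(atom) for atom in model.atoms()]
    lines.append("END")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class CATrace:
    """Ordered alpha-carbon trace of one chain.

    ``entries`` holds (res_seq, xyz) per residue possessing a CA atom;
    ``skipped`` lists res_seq of residues lacking one.
    """

    entries: tuple[tuple[int, np.ndarray], ...]
    skipped: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def coords(self) -> np.ndarray:
        return np.array([xyz for _, xyz in self.entries], dtype=float)


def ca_trace(
    model: StructureModel, chain_id: str, include_het: bool = False
) -> CATrace:
    """Extract the CA trace of one chain, one entry per CA-bearing residue.

    When a residue lists several altlocs for CA, the first-listed altloc
    wins. HETATM CA atoms (e.g. calcium) are excluded unless *include_het*.
    """
    chain = model.chain(chain_id)
    entries: list[tuple[int, np.ndarray]] = []
    skipped: list[int] = []
    for res in chain.residues:
        ca = next(
            (
                a
                for a in res.atoms
                if a.name == "CA" and (include_het or not a.is_hetatm)
            ),
            None,
        )
        if ca is None:
            skipped.append(res.res_seq)
        else:
            entries.append((res.res_seq, ca.coords))
    return CATrace(entries=tuple(entries), skipped=tuple(skipped))
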