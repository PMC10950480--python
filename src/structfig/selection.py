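"""The ``type: target, target, ...`` selection expression language.

One expression names one structural level — atom, residue, position,
range, segment, chain or model — and a comma-separated target list; the
selected set is the union over targets of every atom belonging to a
matched element. Expressions compose by set operations on their results
(intersection restricts a position selection to one chain, for example).

Matching rules per level:

=========  ===========================================================
atom       atom name, case-insensitive exact match
residue    3-letter residue name, case-insensitive exact match
position   author residue number (res_seq) equality, any chain
range      res_seq within the closed interval "low-high"
segment    PDB segID (columns 73-76), exact match
chain      chain identifier, exact match
model      model_id label, exact match
=========  ===========================================================

Insertion codes take part in residue identity but the grammar has no
syntax for them; ``position``/``range`` match every insertion variant of
a residue number. An expression that matches nothing selects the empty
set — never an error.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import SelectionSyntaxError, UnknownSelectionTypeError
from .structure_io import StructureModel

__all__ = [
    "LEVELS",
    "SelectionExpr",
    "parse_selection",
    "format_selection",
    "evaluate_selection",
    "complement",
]

LEVELS = ("atom", "residue", "position", "range", "segment", "chain", "model")

Target = str | int | tuple[int, int]


@dataclass(frozen=True)
class SelectionExpr:
    """Parsed selection: a level keyword plus an ordered target tuple."""

    level: str
    targets: tuple[Target, ...]

    def __post_init__(self):
        if self.level not in LEVELS:
            raise UnknownSelectionTypeError(
                f"unknown selection type {self.level!r}; valid types: "
                + ", ".join(LEVELS)
            )
        if not self.targets:
            raise SelectionSyntaxError("target list must be non-empty")


def _parse_int(token: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise SelectionSyntaxError(
            f"expected an integer target, got {token!r}"
        ) from None


def _parse_range(token: str) -> tuple[int, int]:
    lo, sep, hi = token.partition("-")
    if not sep or not lo.strip() or not hi.strip():
        raise SelectionSyntaxError(
            f"malformed range {token!r}; expected 'low-high'"
        )
    low, high = _parse_int(lo.strip()), _parse_int(hi.strip())
    if low > high:
        raise SelectionSyntaxError(
            f"range {token!r} has low > high"
        )
    return (low, high)


def parse_selection(expr: str) -> SelectionExpr:
    """Parse ``"type: target, target, ..."`` into a :class:`SelectionExpr`.

    The level keyword is case-insensitive and whitespace-trimmed; targets
    are split on commas and trimmed. ``range`` targets are ``"A-B"``
    integer pairs, ``position`` targets integers; all others are strings.
    """
    head, sep, tail = expr.partition(":")
    if not sep:
        raise SelectionSyntaxError(
            f"missing ':' in selection expression {expr!r}"
        )
    level = head.strip().lower()
    if level not in LEVELS:
        raise UnknownSelectionTypeError(
            f"unknown selection type {level!r}; valid types: " + ", ".join(LEVELS)
        )
    raw = [t.strip() for t in tail.split(",")]
    if any(not t for t in raw):
        raise SelectionSyntaxError(f"empty target in expression {expr!r}")
    targets: list[Target]
    if level == "range":
        targets = [_parse_range(t) for t in raw]
    elif level == "position":
        targets = [_parse_int(t) for t in raw]
    else:
        targets = list(raw)
    return SelectionExpr(level=level, targets=tuple(targets))


def format_selection(sel: SelectionExpr) -> str:
    """Canonical text form; ``parse_selection(format_selection(s)) == s``."""
    parts = [
        f"{t[0]}-{t[1]}" if isinstance(t, tuple) else str(t) for t in sel.targets
    ]
    return f"{sel.level}: " + ", ".join(parts)


def _matches(atom, chain, res, model, sel: SelectionExpr) -> bool:
    if sel.level == "atom":
        return any(atom.name.upper() == str(t).upper() for t in sel.targets)
    if sel.level == "residue":
        return any(res.res_name.upper() == str(t).upper() for t in sel.targets)
    if sel.level == "position":
        return any(res.res_seq == t for t in sel.targets)
    if sel.level == "range":
        return any(lo <= res.res_seq <= hi for lo, hi in sel.targets)
    if sel.level == "segment":
        return any(atom.seg_id == str(t) for t in sel.targets)
    if sel.level == "chain":
        return any(chain.chain_id == str(t) for t in sel.targets)
    return any(model.model_id == str(t) for t in sel.targets)  # model


def _iter_models(models):
    if isinstance(models, StructureModel):
        return [models], False
    return list(models), True


def evaluate_selection(models, sel: SelectionExpr) -> frozenset:
    """Evaluate an expression and return the matched atom identifiers.

    For a single :class:`StructureModel` the identifiers are atom serial
    numbers; for a sequence of models they are ``(model_id, serial)``
    pairs. A selection matching nothing returns the empty set.
    """
    model_list, qualified = _iter_models(models)
    out = set()
    for model in model_list:
        for chain in model.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    if _matches(atom, chain, res, model, sel):
                        out.add(
                            (model.model_id, atom.serial)
                            if qualified
                            else atom.serial
                        )
    return frozenset(out)


def complement(models, sel: SelectionExpr) -> frozenset:
    """All atom identifiers minus the selection (used to hide elements)."""
    model_list, qualified = _iter_models(models)
    universe = frozenset(
        (m.model_id, a.serial) if qualified else a.serial
        for m in model_list
        for a in m.atoms()
    )
    selected = evaluate_selection(model_list if qualified else model_list[0], sel)
    return universe - selected
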