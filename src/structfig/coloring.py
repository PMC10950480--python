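"""Per-atom colors and per-residue radii from selections, attributes or
post-alignment distances.

Two schemes exist: *highlight* (two flat colors split by a selection,
per atom) and *gradient* (a value per residue mapped through a colormap,
all atoms of a residue sharing its color). Gradient values come from an
:class:`AttributeTable` — built-in physico-chemical scales, arbitrary
user values, or the per-residue CA distances of an alignment.

Degenerate-input rules, applied identically to colors and radii: a
residue with no value gets neutral mid-grey (0.5, 0.5, 0.5); an
attribute whose values are all identical maps everything to the colormap
midpoint (t = 0.5) when no explicit range is given; an explicit range
with lo == hi over >= 2 distinct values is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import AlignmentResult, Correspondence
from .errors import ColoringError
from .selection import SelectionExpr, evaluate_selection
from .structure_io import StructureModel

__all__ = [
    "RGB",
    "NEUTRAL_GREY",
    "ColorAssignment",
    "AttributeTable",
    "highlight_colors",
    "gradient_colors",
    "distance_colors",
    "radius_from_values",
    "builtin_property",
    "PROPERTY_TABLES",
]

RGB = tuple[float, float, float]
ResidueKey = tuple[str, int]  # (chain_id, res_seq)

NEUTRAL_GREY: RGB = (0.5, 0.5, 0.5)


@dataclass
class ColorAssignment:
    """Total per-atom color map plus optional per-residue radius factors."""

    colors: dict[int, RGB]  # atom serial -> RGB, every atom present
    radii: dict[ResidueKey, float] | None = None


@dataclass
class AttributeTable:
    """Real-valued per-residue attribute, keyed by (chain_id, res_seq)."""

    values: dict[ResidueKey, float]
    name: str = ""
    units: str = ""

    def __post_init__(self):
        bad = {k: v for k, v in self.values.items() if not np.isfinite(v)}
        if bad:
            raise ColoringError(f"non-finite attribute values: {bad}")


def highlight_colors(
    model: StructureModel,
    sel: SelectionExpr,
    base_rgb: RGB = (0.7, 0.7, 0.7),
    highlight_rgb: RGB = (0.9, 0.1, 0.1),
) -> ColorAssignment:
    """Two-color partition: selected atoms highlighted, the rest base."""
    selected = evaluate_selection(model, sel)
    colors = {
        a.serial: (highlight_rgb if a.serial in selected else base_rgb)
        for a in model.atoms()
    }
    return ColorAssignment(colors=colors)


def _normalize(values: np.ndarray, value_range) -> np.ndarray:
    """Map values to colormap parameter t in [0, 1] with the degenerate
    rules described in the module docstring."""
    if value_range is None:
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:
            return np.full(values.shape, 0.5)
    else:
        lo, hi = float(value_range[0]), float(value_range[1])
        if lo == hi:
            if len(np.unique(values)) >= 2:
                raise ColoringError(
                    f"degenerate range ({lo}, {hi}) with non-constant values"
                )
            return np.full(values.shape, 0.5)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def _interpolate(t: np.ndarray, stops) -> np.ndarray:
    stops = np.asarray(stops, dtype=float)
    if stops.ndim != 2 or stops.shape[0] < 2 or stops.shape[1] != 3:
        raise ColoringError("colormap needs >= 2 RGB stops")
    positions = np.linspace(0.0, 1.0, len(stops))
    return np.stack(
        [np.interp(t, positions, stops[:, ch]) for ch in range(3)], axis=-1
    )


def gradient_colors(
    model: StructureModel,
    attr: AttributeTable,
    colormap=((0.0, 0.0, 1.0), (1.0, 1.0, 1.0), (1.0, 0.0, 0.0)),
    value_range=None,
) -> ColorAssignment:
    """Map a per-residue attribute through equally spaced colormap stops.

    Values are scaled by ``t = (v - lo) / (hi - lo)`` clipped to [0, 1]
    (lo/hi defaulting to the observed extremes); each residue's atoms all
    take its interpolated color; residues without a value get mid-grey.
    """
    if not attr.values:
        raise ColoringError("attribute table is empty")
    keys = [k for k in attr.values]
    t = _normalize(np.array([attr.values[k] for k in keys], dtype=float), value_range)
    rgb = _interpolate(t, colormap)
    residue_color = {k: tuple(float(c) for c in rgb[i]) for i, k in enumerate(keys)}
    colors = {}
    for chain, res in model.residues():
        col = residue_color.get((chain.chain_id, res.res_seq), NEUTRAL_GREY)
        for atom in res.atoms:
            colors[atom.serial] = col
    return ColorAssignment(colors=colors)


def distance_colors(
    result: AlignmentResult,
    corr: Correspondence,
    model: StructureModel,
    colormap=((0.0, 0.0, 1.0), (1.0, 1.0, 1.0), (1.0, 0.0, 0.0)),
    value_range=None,
) -> ColorAssignment:
    """Color the reference model by per-residue CA distance after alignment.

    Builds an Å-valued attribute table from the alignment's distances and
    delegates to :func:`gradient_colors`; unpaired residues stay neutral.
    """
    if len(result.per_residue_distance) != len(corr):
        raise ColoringError(
            f"distance vector length {len(result.per_residue_distance)} "
            f"does not match correspondence length {len(corr)}"
        )
    attr = AttributeTable(
        values={
            key: float(d)
            for key, d in zip(corr.ref_keys, result.per_residue_distance)
        },
        name="ca_distance",
        units="angstrom",
    )
    return gradient_colors(model, attr, colormap=colormap, value_range=value_range)


def radius_from_values(
    attr: AttributeTable,
    r_min: float = 0.5,
    r_max: float = 2.0,
    value_range=None,
) -> dict[ResidueKey, float]:
    """Linear map of clipped-normalized attribute values to [r_min, r_max].

    Used to modulate backbone-trace width ("volume") so numerical
    differences are visible in cartoon-style renderings.
    """
    if not (0 < r_min < r_max):
        raise ColoringError(f"need 0 < r_min < r_max, got ({r_min}, {r_max})")
    keys = list(attr.values)
    t = _normalize(np.array([attr.values[k] for k in keys], dtype=float), value_range)
    return {k: float(r_min + (r_max - r_min) * ti) for k, ti in zip(keys, t)}


# Kyte-Doolittle hydropathy index (unitless).
_HYDROPATHY = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

# Formal side-chain charge at pH 7 (histidine mostly neutral).
_CHARGE = {aa: 0 for aa in _HYDROPATHY}
_CHARGE.update({"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1})

# Average residue (monomer-in-chain) masses, Da.
_MOLWEIGHT = {
    "GLY": 57.05, "ALA": 71.08, "SER": 87.08, "PRO": 97.12, "VAL": 99.13,
    "THR": 101.10, "CYS": 103.14, "LEU": 113.16, "ILE": 113.16,
    "ASN": 114.10, "ASP": 115.09, "GLN": 128.13, "LYS": 128.17,
    "GLU": 129.12, "MET": 131.19, "HIS": 137.14, "PHE": 147.18,
    "ARG": 156.19, "TYR": 163.18, "TRP": 186.21,
}

PROPERTY_TABLES = {
    "hydropathy": (_HYDROPATHY, ""),
    "charge": (_CHARGE, "e"),
    "molecular_weight": (_MOLWEIGHT, "Da"),
}


def builtin_property(name: str, model: StructureModel):
    """Per-residue values from a built-in physico-chemical scale.

    Returns ``(table, excluded)`` where *excluded* lists the
    (chain_id, res_seq, res_name) of residues absent from the scale.
    """
    if name not in PROPERTY_TABLES:
        raise ColoringError(
            f"unknown property {name!r}; available: "
            + ", ".join(sorted(PROPERTY_TABLES))
        )
    scale, units = PROPERTY_TABLES[name]
    values: dict[ResidueKey, float] = {}
    excluded: list[tuple[str, int, str]] = []
    for chain, res in model.residues():
        value = scale.get(res.res_name.upper())
        if value is None:
            excluded.append((chain.chain_id, res.res_seq, res.res_name))
        else:
            values[(chain.chain_id, res.res_seq)] = float(value)
    return AttributeTable(values=values, name=name, units=units), excluded
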