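"""Intrinsic amino-acid hydrophobicity scales.

The observed-hydrophobicity profile weighs pairwise residue contacts by the
intrinsic hydrophobicity of each partner, so the scale is a mandatory,
explicitly named input of every analysis.  Three widely used experimental
scales are shipped, each min-max normalized to [0, 1] so that the most
hydrophilic residue of a scale maps to 0 and the most hydrophobic to 1;
results are therefore comparable across scales up to an affine rescaling of
the raw table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STANDARD_AA = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# Raw published tables (free-energy-like units as printed by the authors).
_KYTE_DOOLITTLE = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}
_EISENBERG = {
    "ALA": 0.62, "ARG": -2.53, "ASN": -0.78, "ASP": -0.90, "CYS": 0.29,
    "GLN": -0.85, "GLU": -0.74, "GLY": 0.48, "HIS": -0.40, "ILE": 1.38,
    "LEU": 1.06, "LYS": -1.50, "MET": 0.64, "PHE": 1.19, "PRO": 0.12,
    "SER": -0.18, "THR": -0.05, "TRP": 0.81, "TYR": 0.26, "VAL": 1.08,
}
_FAUCHERE_PLISKA = {
    "ALA": 0.31, "ARG": -1.01, "ASN": -0.60, "ASP": -0.77, "CYS": 1.54,
    "GLN": -0.22, "GLU": -0.64, "GLY": 0.00, "HIS": 0.13, "ILE": 1.80,
    "LEU": 1.70, "LYS": -0.99, "MET": 1.23, "PHE": 1.79, "PRO": 0.72,
    "SER": -0.04, "THR": 0.26, "TRP": 2.25, "TYR": 0.96, "VAL": 1.22,
}


class ScaleError(ValueError):
    """A hydrophobicity scale is malformed or does not cover a residue."""


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named map from 3-letter residue codes to nonnegative hydrophobicities.

    Parameters
    ----------
    name : str
        Identifier recorded in run manifests.
    values : dict
        3-letter code -> nonnegative real.  Must cover all 20 standard
        residues and contain at least one strictly positive entry.
    """

    name: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [aa for aa in STANDARD_AA if aa not in self.values]
        if missing:
            raise ScaleError(f"scale {self.name!r} misses residues: {missing}")
        if any(v < 0 for v in self.values.values()):
            raise ScaleError(f"scale {self.name!r} has negative entries")
        if not any(v > 0 for v in self.values.values()):
            raise ScaleError(f"scale {self.name!r} is identically zero")

    def __getitem__(self, aa_type: str) -> float:
        try:
            return self.values[aa_type.upper()]
        except KeyError:
            raise ScaleError(
                f"residue type {aa_type!r} not covered by scale {self.name!r}"
            ) from None

    def __contains__(self, aa_type: str) -> bool:
        return aa_type.upper() in self.values


def _minmax(raw: dict[str, float]) -> dict[str, float]:
    lo, hi = min(raw.values()), max(raw.values())
    return {aa: (v - lo) / (hi - lo) for aa, v in raw.items()}


_REGISTRY: dict[str, HydrophobicityScale] = {
    "kyte_doolittle": HydrophobicityScale("kyte_doolittle", _minmax(_KYTE_DOOLITTLE)),
    "eisenberg": HydrophobicityScale("eisenberg", _minmax(_EISENBERG)),
    "fauchere_pliska": HydrophobicityScale(
        "fauchere_pliska", _minmax(_FAUCHERE_PLISKA)
    ),
}

#: Default scale used when the caller does not name one explicitly.
DEFAULT_SCALE = "fauchere_pliska"


def available_scales() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def get_scale(name: str | HydrophobicityScale = DEFAULT_SCALE) -> HydrophobicityScale:
    """Look up a shipped scale by name, or pass a custom scale through."""
    if isinstance(name, HydrophobicityScale):
        return name
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ScaleError(
            f"unknown scale {name!r}; available: {available_scales()}"
        ) from None
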