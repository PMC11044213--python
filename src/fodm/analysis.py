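"""Derived analyses on the T/O profiles.

Four procedures the status statistics support:

* greedy residue elimination until the remaining moiety has RD below a
  threshold (locating the residues that break the hydrophobic core),
* detection of contiguous excess / deficit segments of O relative to T,
* layer classification of residues by absolute profile thresholds
  (surface-polar / subsurface-conforming / core-deficit),
* interface extraction between two units by contact distance, with the FOD
  status of the interface and of its complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .field import HydroProfile, uniform_profile
from .metrics import (
    FodStatus, fragment_status, _status_from_profiles, rd_with_flag,
)
from .structure import ResKey, SelectionError, StructureModel, UnitSelection

__all__ = [
    "SegmentAnnotation", "EliminationResult", "eliminate_to_threshold",
    "excess_deficit_segments", "classify_layers", "interface_residues",
    "interface_status",
]

Label = Literal[
    "excess", "deficit", "surface_polar", "subsurface_conforming",
    "core_deficit", "interface", "eliminated",
]


@dataclass(frozen=True)
class SegmentAnnotation:
    """A labeled, ordered set of residues with its (T_i, O_i) evidence."""

    label: Label
    residues: tuple[ResKey, ...]
    indices: tuple[int, ...]
    evidence: tuple[tuple[float, float], ...]  # (T_i, O_i) per residue

    def __post_init__(self) -> None:
        if not self.indices:
            raise ValueError("empty segment annotation")

    @property
    def start(self) -> int:
        return self.indices[0]

    @property
    def stop(self) -> int:
        return self.indices[-1] + 1


@dataclass(frozen=True)
class EliminationResult:
    """Outcome of greedy elimination toward RD < threshold."""

    eliminated: tuple[ResKey, ...]      # in removal order
    eliminated_indices: tuple[int, ...]  # positions in the input profiles
    final_status: FodStatus
    converged: bool
    surviving_indices: tuple[int, ...]


def _keys_or_range(p: HydroProfile) -> tuple[ResKey, ...]:
    if p.keys is not None:
        return p.keys
    return tuple(("", i, "") for i in range(len(p)))


def eliminate_to_threshold(
    t: HydroProfile,
    o: HydroProfile,
    rd_threshold: float = 0.5,
    min_residues: int = 3,
) -> EliminationResult:
    """Greedily remove highest-|O - T| residues until RD < threshold.

    After each removal the surviving T and O are renormalized, R rebuilt and
    RD recomputed.  Ties go to the lower sequence position.  If the unit
    would shrink below ``min_residues`` without crossing the threshold a
    non-convergence result (not an exception) is returned.
    """
    if len(t) != len(o):
        raise ValueError("T and O must have equal length")
    if len(t) < min_residues:
        raise ValueError(f"need at least {min_residues} residues")
    keys = _keys_or_range(t)
    alive = list(range(len(t)))
    removed: list[int] = []

    def current_rd() -> tuple[float, bool]:
        o_sub = o.subset(alive)
        return rd_with_flag(o_sub, t.subset(alive), uniform_profile(len(alive)))

    rd_val, degen = current_rd()
    converged = True
    while rd_val >= rd_threshold and not degen:
        if len(alive) <= min_residues:
            converged = False
            break
        t_sub = t.subset(alive).values
        o_sub = o.subset(alive).values
        worst = int(np.argmax(np.abs(o_sub - t_sub)))  # argmax: first max wins
        removed.append(alive.pop(worst))
        rd_val, degen = current_rd()

    final_status = _status_from_profiles(
        o.subset(alive), t.subset(alive), "unit", "eliminated-moiety"
    )
    return EliminationResult(
        eliminated=tuple(keys[i] for i in removed),
        eliminated_indices=tuple(removed),
        final_status=final_status,
        converged=converged,
        surviving_indices=tuple(alive),
    )


def _runs(labels: list[str | None], min_len: int = 1):
    """Yield (label, start, stop) for maximal runs of identical non-None labels."""
    start = None
    current = None
    for i, lab in enumerate(labels + [None]):
        if lab != current:
            if current is not None and i - start >= min_len:
                yield current, start, i
            start, current = i, lab


def _annotate(label, idx_range, keys, tv, ov) -> SegmentAnnotation:
    idx = tuple(idx_range)
    return SegmentAnnotation(
        label=label,
        residues=tuple(keys[i] for i in idx),
        indices=idx,
        evidence=tuple((float(tv[i]), float(ov[i])) for i in idx),
    )


def excess_deficit_segments(
    t: HydroProfile,
    o: HydroProfile,
    min_len: int = 3,
    tol: float | None = None,
) -> list[SegmentAnnotation]:
    """Maximal runs (length >= min_len) of local hydrophobicity excess/deficit.

    Residue i is *excess* when O_i - T_i > tol and *deficit* when
    T_i - O_i > tol.  The default tolerance is 1/(4N) — a quarter of the
    uniform level, scale-free in profile units.
    """
    tv, ov = t.values, o.values
    if tv.shape != ov.shape:
        raise ValueError("T and O must have equal length")
    n = tv.size
    if tol is None:
        tol = 1.0 / (4.0 * n)
    keys = _keys_or_range(t)
    diff = ov - tv
    labels: list[str | None] = [
        "excess" if d > tol else "deficit" if d < -tol else None for d in diff
    ]
    return [
        _annotate(lab, range(start, stop), keys, tv, ov)
        for lab, start, stop in _runs(labels, min_len=min_len)
    ]


def classify_layers(
    t: HydroProfile,
    o: HydroProfile,
    t_low: float = 0.001,
    t_high: float = 0.0015,
) -> list[SegmentAnnotation]:
    """Classify residues into structural layers by absolute profile levels.

    surface_polar          : T_i < t_low  and O_i < t_low
    subsurface_conforming  : T_i > t_high and O_i > t_high
    core_deficit           : T_i > t_high and O_i < t_high
    Other residues stay unlabeled.  Thresholds apply to normalized profiles;
    contiguous equal labels are grouped into segments.
    """
    if t_low > t_high:
        raise ValueError("t_low must not exceed t_high")
    tv, ov = t.values, o.values
    if tv.shape != ov.shape:
        raise ValueError("T and O must have equal length")
    keys = _keys_or_range(t)
    labels: list[str | None] = []
    for ti, oi in zip(tv, ov):
        if ti < t_low and oi < t_low:
            labels.append("surface_polar")
        elif ti > t_high and oi > t_high:
            labels.append("subsurface_conforming")
        elif ti > t_high and oi < t_high:
            labels.append("core_deficit")
        else:
            labels.append(None)
    return [
        _annotate(lab, range(start, stop), keys, tv, ov)
        for lab, start, stop in _runs(labels, min_len=1)
    ]


def interface_residues(
    model: StructureModel,
    unit_a: UnitSelection,
    unit_b: UnitSelection,
    contact_cutoff: float = 5.0,
    basis: Literal["heavy_atom", "effective_atom"] = "heavy_atom",
) -> tuple[ResKey, ...]:
    """Residues of A with any atom within ``contact_cutoff`` Å of unit B.

    ``basis`` selects heavy-atom pair distances (default, the common
    interface convention) or effective-atom distances.  Units must be
    disjoint; the result is in A's residue order and grows monotonically
    with the cutoff.
    """
    a_keys, b_keys = unit_a.members, unit_b.members
    if set(a_keys) & set(b_keys):
        raise SelectionError("interface units must be disjoint")

    def coords(key: ResKey) -> np.ndarray:
        res = model[key]
        if basis == "effective_atom":
            return res.coords.mean(axis=0, keepdims=True)
        return res.coords

    b_pts = np.vstack([coords(k) for k in b_keys])
    tree = cKDTree(b_pts)
    out = []
    for key in a_keys:
        d, _ = tree.query(coords(key), k=1)
        if np.min(d) <= contact_cutoff:
            out.append(key)
    return tuple(out)


def interface_status(
    complex_t: HydroProfile,
    complex_o: HydroProfile,
    interface: Sequence[ResKey],
    chain: Sequence[ResKey] | None = None,
    complement: bool = False,
    label: str = "",
) -> FodStatus:
    """FOD status of an interface (P-P) or of the chain part outside it.

    With ``complement=True`` the status is computed for ``chain`` minus the
    interface residues (the "No P-P" part); ``chain`` is then required.
    """
    interface = list(interface)
    if complement:
        if chain is None:
            raise ValueError("complement=True requires the chain residue set")
        iface = set(interface)
        members = [k for k in chain if k not in iface]
        if not members:
            raise SelectionError("complement is empty")
        label = label or "no-interface"
    else:
        members = interface
        label = label or "interface"
    return fragment_status(complex_t, complex_o, members, label=label)
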