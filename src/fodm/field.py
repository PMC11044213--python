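"""The hydrophobicity field: Gaussian envelope and the T / O / R profiles.

A folded globule is idealized as a fuzzy micelle whose hydrophobicity density
is a 3D Gaussian spanning the molecule.  The *theoretical* profile T samples
that Gaussian at the effective atoms; the *observed* profile O collects
pairwise intrinsic-hydrophobicity interactions through Levitt's contact
function; the *uniform* profile R is 1/N per residue.  All three are
normalized to unit sum, which makes them comparable as discrete
distributions over residues.

Orientation (centering + principal-axis rotation) is internal, so every
profile is invariant under rigid-body motion of the input structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import ResidueRecord, ResKey, StructureError

__all__ = [
    "GaussianEnvelope", "HydroProfile", "orient_unit", "estimate_sigmas",
    "theoretical_profile", "observed_profile", "uniform_profile",
    "levitt_weight", "DEFAULT_CUTOFF", "ProfileError",
]

#: Default Levitt contact cutoff in Å, standard in the FOD literature.
DEFAULT_CUTOFF = 9.0

_NORM_TOL = 1e-9


class ProfileError(ValueError):
    """A profile violates its normalization or shape contract."""


@dataclass(frozen=True)
class GaussianEnvelope:
    """The 3D Gaussian fitted to a structural unit.

    ``rotation`` maps input-frame coordinates (after subtracting ``center``)
    into the principal frame in which the sigmas are defined; sigmas are
    sorted descending (x longest).
    """

    center: np.ndarray
    sigmas: tuple[float, float, float]
    rotation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        if min(self.sigmas) <= 0:
            raise StructureError(f"nonpositive sigma: {self.sigmas}")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise StructureError("rotation is not orthonormal")

    def to_principal(self, positions: np.ndarray) -> np.ndarray:
        """Map input-frame positions into the principal frame."""
        return (np.asarray(positions, dtype=float) - self.center) @ self.rotation.T


@dataclass(frozen=True)
class HydroProfile:
    """An ordered per-residue hydrophobicity distribution.

    ``kind`` is one of T (theoretical Gaussian), O (observed, Levitt),
    R (uniform), M (environment-modified) or ``opposite``.  When
    ``normalized`` the values are nonnegative and sum to 1 (±1e-9).
    ``keys`` optionally carries residue identities for serialization and
    fragment extraction.
    """

    kind: Literal["T", "O", "R", "M", "opposite"]
    values: np.ndarray
    normalized: bool = True
    keys: tuple[ResKey, ...] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ProfileError(f"{self.kind} profile must be a nonempty vector")
        if not np.all(np.isfinite(v)):
            raise ProfileError(f"{self.kind} profile has non-finite values")
        if np.any(v < 0):
            raise ProfileError(f"{self.kind} profile has negative values")
        if self.normalized and abs(v.sum() - 1.0) > _NORM_TOL:
            raise ProfileError(
                f"{self.kind} profile declared normalized but sums to {v.sum()!r}"
            )
        if self.keys is not None and len(self.keys) != v.size:
            raise ProfileError("keys length does not match values")

    def __len__(self) -> int:
        return self.values.size

    def normalize(self) -> "HydroProfile":
        """Return the unit-sum version of this profile."""
        s = self.values.sum()
        if s <= 0:
            raise ProfileError(f"cannot normalize zero-sum {self.kind} profile")
        return HydroProfile(self.kind, self.values / s, True, self.keys, self.label)

    def subset(self, idx: Sequence[int], renormalize: bool = True) -> "HydroProfile":
        """Extract positions ``idx`` and (by default) renormalize to sum 1."""
        idx = np.asarray(idx, dtype=int)
        keys = tuple(self.keys[i] for i in idx) if self.keys is not None else None
        sub = HydroProfile(self.kind, self.values[idx], False, keys, self.label)
        return sub.normalize() if renormalize else sub


def _positions(records: Sequence[ResidueRecord]) -> np.ndarray:
    return np.array([r.position for r in records], dtype=float)


def orient_unit(
    records: Sequence[ResidueRecord],
    sigma_convention: str = "max_extent_3",
) -> tuple[list[ResidueRecord], GaussianEnvelope]:
    """Center a unit, align it with its principal axes and fit the envelope.

    Axes are ordered by descending extent; each axis sign is chosen so the
    residue farthest along it sits at a positive coordinate, with the third
    axis sign then fixed to preserve handedness.  Requires >= 3 non-collinear
    effective atoms.
    """
    if len(records) < 3:
        raise StructureError("need at least 3 residues to orient a unit")
    pos = _positions(records)
    center = pos.mean(axis=0)
    centered = pos - center

    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise StructureError("degenerate (collinear) geometry")

    axes = evecs.T  # rows = principal axes
    proj = centered @ axes.T
    for k in range(2):
        if proj[np.argmax(np.abs(proj[:, k])), k] < 0:
            axes[k] = -axes[k]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]

    oriented = centered @ axes.T
    sigmas = estimate_sigmas(oriented, convention=sigma_convention)
    env = GaussianEnvelope(center=center, sigmas=sigmas, rotation=axes)
    new_records = [
        ResidueRecord(r.chain_id, r.seq_id, r.insertion_code, r.aa_type,
                      oriented[i], r.h_intrinsic)
        for i, r in enumerate(records)
    ]
    return new_records, env


def estimate_sigmas(
    oriented: np.ndarray | Sequence[ResidueRecord],
    convention: str = "max_extent_3",
) -> tuple[float, float, float]:
    """Per-axis Gaussian widths adapted to the unit's size and shape.

    ``max_extent_3`` (default): sigma = max |coordinate| / 3 per axis, so the
    molecular boundary sits at 3 sigma (~99.7% of the Gaussian mass).
    ``range_6``: sigma = (max - min) / 6, an alternative extent statistic for
    sensitivity checks.
    """
    if not isinstance(oriented, np.ndarray):
        oriented = _positions(oriented)
    if convention == "max_extent_3":
        ext = np.abs(oriented).max(axis=0)
    elif convention == "range_6":
        ext = (oriented.max(axis=0) - oriented.min(axis=0)) / 2.0
    else:
        raise ValueError(f"unknown sigma convention {convention!r}")
    if np.any(ext <= 0):
        raise StructureError(f"zero extent on an axis: {ext}")
    s = ext / 3.0
    return (float(s[0]), float(s[1]), float(s[2]))


def theoretical_profile(
    records: Sequence[ResidueRecord] | np.ndarray,
    envelope: GaussianEnvelope | tuple[float, float, float],
    in_principal_frame: bool = True,
) -> HydroProfile:
    """Theoretical (T) profile: the envelope Gaussian sampled per residue.

    T~_i = exp(-x_i^2/2 sx^2) exp(-y_i^2/2 sy^2) exp(-z_i^2/2 sz^2),
    normalized to unit sum.  All values are strictly positive.
    """
    keys = None
    if isinstance(records, np.ndarray):
        pos = records
    else:
        pos = _positions(records)
        keys = tuple(r.key for r in records)
    if isinstance(envelope, GaussianEnvelope):
        sig = np.asarray(envelope.sigmas)
        if not in_principal_frame:
            pos = envelope.to_principal(pos)
    else:
        sig = np.asarray(envelope, dtype=float)
    raw = np.exp(-0.5 * np.sum((pos / sig) ** 2, axis=1))
    return HydroProfile("T", raw, False, keys=keys).normalize()


def levitt_weight(r: np.ndarray, cutoff: float) -> np.ndarray:
    """Levitt's smooth contact function on [0, cutoff], zero beyond.

    w(0) = 1 and w(cutoff) = 0; the polynomial is
    1 - 1/2 (7 x^2 - 9 x^4 + 5 x^6 - x^8) with x = r / cutoff.
    """
    x2 = np.clip(np.asarray(r, dtype=float) / cutoff, 0.0, None) ** 2
    w = 1.0 - 0.5 * (7.0 * x2 - 9.0 * x2**2 + 5.0 * x2**3 - x2**4)
    return np.where(r <= cutoff, w, 0.0)


def observed_profile(
    records: Sequence[ResidueRecord],
    cutoff: float = DEFAULT_CUTOFF,
) -> HydroProfile:
    """Observed (O) profile from pairwise intrinsic-hydrophobicity contacts.

    O~_i = sum over j with r_ij <= cutoff of (H_i + H_j) w(r_ij), including
    the self term (r = 0, w = 1), then normalized to unit sum.  Requires
    hydrophobicities to be assigned and a strictly positive total.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    h = np.array([r.h_intrinsic for r in records], dtype=float)
    if np.any(~np.isfinite(h)):
        raise ProfileError("h_intrinsic not assigned on all records")
    pos = _positions(records)
    raw = 2.0 * h  # self terms: (H_i + H_i) * w(0)
    if len(records) > 1:
        pairs = cKDTree(pos).query_pairs(cutoff, output_type="ndarray")
        if pairs.size:
            i, j = pairs[:, 0], pairs[:, 1]
            d = np.linalg.norm(pos[i] - pos[j], axis=1)
            contrib = (h[i] + h[j]) * levitt_weight(d, cutoff)
            np.add.at(raw, i, contrib)
            np.add.at(raw, j, contrib)
    keys = tuple(r.key for r in records)
    if raw.sum() <= 0:
        raise ProfileError("degenerate scale: observed profile sums to zero")
    return HydroProfile("O", raw, False, keys=keys).normalize()


def uniform_profile(n: int, keys: tuple[ResKey, ...] | None = None) -> HydroProfile:
    """Uniform reference (R) profile: 1/n per residue."""
    if n < 1:
        raise ProfileError("empty unit")
    return HydroProfile("R", np.full(n, 1.0 / n), True, keys=keys)
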