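"""Synthetic structures with known hydrophobicity regimes.

Small artificial "proteins" whose construction pins the expected outcome of
the analysis, so every statistic is testable without downloading real
structures:

* ``ideal_micelle`` — residues sampled in a ball, residue types chosen so
  intrinsic hydrophobicity tracks the local Gaussian density: O follows T,
  low RD and K near 0 (folding shaped by water).
* ``inverted_micelle`` — the same geometry with the assignment reversed
  (hydrophobic outside): RD above 0.5 and K well above 1 (membrane-like).
* ``uniform_blob`` — one residue type everywhere: O near uniform.
* ``perturbed_micelle`` — ideal micelle plus a sequence-contiguous surface
  patch forced to maximal hydrophobicity (a localized O-T discrepancy).
* ``engineered_dimer`` — two separated micelles with one designed 4 Å
  contact pair, for interface extraction tests.

Every fixture emits one CA-labeled atom per residue, so the effective-atom
reduction is the identity and math tests are isolated from coordinate
averaging.  All randomness is driven by the seed (bit-reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .scales import get_scale
from .structure import Residue, StructureModel

__all__ = ["FixtureSpec", "make_fixture", "write_fixture_pdb"]

Regime = Literal[
    "ideal_micelle", "inverted_micelle", "uniform_blob",
    "perturbed_micelle", "engineered_dimer",
]

#: Declared analysis bounds per regime (checked by the property suite).
REGIME_BOUNDS: dict[str, dict[str, float]] = {
    "ideal_micelle": {"rd_max": 0.3, "k_max": 0.2},
    "inverted_micelle": {"rd_min": 0.5, "k_min": 1.0},
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic structure.

    radius is the sampling-ball radius in Å; patch_len shapes
    the perturbed-micelle discrepancy patch; separation is the chain-chain
    offset of the engineered dimer.
    """

    regime: Regime
    n_residues: int = 200
    seed: int = 0
    radius: float = 15.0
    patch_len: int | None = None  # None: n_residues // 12, at least 6
    contact_distance: float = 4.0
    separation: float = 120.0

    def __post_init__(self) -> None:
        if self.regime not in (
            "ideal_micelle", "inverted_micelle", "uniform_blob",
            "perturbed_micelle", "engineered_dimer",
        ):
            raise ValueError(f"unknown fixture regime {self.regime!r}")
        if self.n_residues < 3:
            raise ValueError("fixtures need n_residues >= 3")


def _ball_points(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of n points in a ball (rejection from the cube)."""
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-radius, radius, size=(2 * n, 3))
        keep = cand[np.linalg.norm(cand, axis=1) <= radius]
        pts.extend(keep.tolist())
    return np.array(pts[:n])


def _aa_for_level(level: np.ndarray, scale_name: str = None) -> list[str]:
    """Map target hydrophobicity levels in [0,1] to nearest scale residues."""
    sc = get_scale(scale_name) if scale_name else get_scale()
    names = sorted(sc.values)
    vals = np.array([sc.values[n] for n in names])
    idx = np.abs(level[:, None] - vals[None, :]).argmin(axis=1)
    return [names[i] for i in idx]


def _micelle(spec: FixtureSpec, invert: bool) -> tuple[np.ndarray, list[str]]:
    rng = np.random.default_rng(spec.seed)
    pos = _ball_points(spec.n_residues, spec.radius, rng)
    sigma = spec.radius / 3.0
    density = np.exp(-0.5 * np.sum((pos / sigma) ** 2, axis=1))
    target = (1.0 - density) if invert else density
    return pos, _aa_for_level(target)


def _residues(pos: np.ndarray, aas: list[str], chain: str = "A",
              start: int = 1) -> list[Residue]:
    return [
        Residue(chain_id=chain, seq_id=start + i, insertion_code="",
                aa_type=aa, atom_names=["CA"], coords=pos[i][None, :])
        for i, (aa) in enumerate(aas)
    ]


def make_fixture(spec: FixtureSpec) -> tuple[StructureModel, dict[str, float]]:
    """Build the structure for a spec; returns (model, declared regime bounds)."""
    bounds = dict(REGIME_BOUNDS.get(spec.regime, {}))
    if spec.regime in ("ideal_micelle", "inverted_micelle"):
        pos, aas = _micelle(spec, invert=spec.regime == "inverted_micelle")
        model = StructureModel(_residues(pos, aas), source=f"fixture:{spec.regime}")
    elif spec.regime == "uniform_blob":
        rng = np.random.default_rng(spec.seed)
        pos = _ball_points(spec.n_residues, spec.radius, rng)
        model = StructureModel(_residues(pos, ["ALA"] * spec.n_residues),
                               source="fixture:uniform_blob")
    elif spec.regime == "perturbed_micelle":
        pos, aas = _micelle(spec, invert=False)
        # a spatially coherent surface patch: the outermost residue plus its
        # patch_len-1 nearest neighbours, forced maximally hydrophobic and
        # reordered to be sequence-contiguous
        patch_len = spec.patch_len or max(6, spec.n_residues // 12)
        radii = np.linalg.norm(pos, axis=1)
        anchor = int(np.argmax(radii))
        dist = np.linalg.norm(pos - pos[anchor], axis=1)
        outer = list(np.argsort(dist)[:patch_len])
        # contract the patch toward its anchor so the mutual contacts pile a
        # large observed-hydrophobicity excess on a spot where T is lowest
        pos[outer] = pos[anchor] + 0.3 * (pos[outer] - pos[anchor])
        rest = [i for i in range(spec.n_residues) if i not in set(outer)]
        insert_at = len(rest) // 2
        order = rest[:insert_at] + outer + rest[insert_at:]
        pos = pos[order]
        aas = [aas[i] for i in order]
        sc = get_scale()
        top = max(sc.values, key=sc.values.get)
        for k in range(insert_at, insert_at + patch_len):
            aas[k] = top
        model = StructureModel(_residues(pos, aas),
                               source="fixture:perturbed_micelle")
        bounds["patch_start"] = insert_at
        bounds["patch_stop"] = insert_at + patch_len
    elif spec.regime == "engineered_dimer":
        half = FixtureSpec("ideal_micelle", max(spec.n_residues // 2, 3),
                           seed=spec.seed, radius=spec.radius)
        pos_a, aas_a = _micelle(half, invert=False)
        half_b = FixtureSpec("ideal_micelle", max(spec.n_residues // 2, 3),
                             seed=spec.seed + 1, radius=spec.radius)
        pos_b, aas_b = _micelle(half_b, invert=False)
        pos_b = pos_b + np.array([spec.separation, 0.0, 0.0])
        # engineered contact: one residue of each chain at the midpoint,
        # contact_distance apart, both maximally hydrophobic
        mid = spec.separation / 2.0
        pos_a[0] = np.array([mid - spec.contact_distance / 2.0, 0.0, 0.0])
        pos_b[0] = np.array([mid + spec.contact_distance / 2.0, 0.0, 0.0])
        sc = get_scale()
        top = max(sc.values, key=sc.values.get)
        aas_a[0] = top
        aas_b[0] = top
        model = StructureModel(
            _residues(pos_a, aas_a, chain="A") + _residues(pos_b, aas_b, chain="B"),
            source="fixture:engineered_dimer",
        )
        bounds["contact_seq_a"] = 1
        bounds["contact_seq_b"] = 1
    return model, bounds


# -- fixed-column PDB writing ---------------------------------------------

_PDB_ATOM = (
    "ATOM  {serial:5d} {name:^4s}{alt:1s}{res:>3s} {chain:1s}{seq:4d}{icode:1s}"
    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n"
)


def write_fixture_pdb(model: StructureModel, path: str | Path) -> Path:
    """Write a model as fixed-column PDB text that round-trips through parsing."""
    path = Path(path)
    lines = []
    serial = 0
    prev_chain = None
    for res in model.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER\n")
        prev_chain = res.chain_id
        for name, xyz in zip(res.atom_names, res.coords):
            serial += 1
            elem = name.strip()[0]
            lines.append(_PDB_ATOM.format(
                serial=serial, name=name if len(name) >= 4 else f" {name:<3s}",
                alt=" ", res=res.aa_type, chain=res.chain_id, seq=res.seq_id,
                icode=res.insertion_code or " ",
                x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0, elem=elem,
            ))
    lines.append("TER\nEND\n")
    path.write_text("".join(lines))
    return path
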