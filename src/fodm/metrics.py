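"""FOD-M statistics: divergence entropy, RD, the K-modified field and status.

The observed distribution O is scored against two references by
Kullback-Leibler divergence entropy: the Gaussian theoretical field T and
the uniform field R.  Their ratio

    RD = D_KL(O|T) / (D_KL(O|T) + D_KL(O|R))

is the *relative distance*; RD < 0.5 marks a structure with a micelle-like
hydrophobic core.  The environment-modified field

    M(K) = [T + K * (T_MAX - T)_n]_n        (subscript n: unit-sum)

interpolates from the aqueous Gaussian field (K = 0) toward its opposite,
membrane-like field; the K minimizing D_KL(O|M(K)) quantifies how strongly
a non-aqueous environment shaped the structure.  Both RD and the optimal K
are invariant to the logarithm base (base 2, i.e. bits, is used for
reported divergences).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .field import (
    DEFAULT_CUTOFF, GaussianEnvelope, HydroProfile, ProfileError,
    observed_profile, orient_unit, theoretical_profile, uniform_profile,
)
from .structure import (
    ResidueRecord, ResKey, SelectionError, StructureModel, UnitSelection,
    assign_hydrophobicity, effective_atoms,
)
from .scales import DEFAULT_SCALE, HydrophobicityScale

__all__ = [
    "kl_divergence", "rd", "opposite_profile", "m_profile", "optimize_k",
    "FodStatus", "FodParams", "fragment_status", "unit_status",
]

#: Default K search domain and grid step.
DEFAULT_K_MAX = 10.0
DEFAULT_K_STEP = 0.01


@dataclass(frozen=True)
class FodParams:
    """Tunable parameters of the full status pipeline (all logged in manifests).

    scale : name of the intrinsic hydrophobicity scale
    cutoff : Levitt contact cutoff, Å
    sigma_convention : envelope width rule ('max_extent_3' or 'range_6')
    k_max, k_step : K grid search domain [0, k_max] and step
    """

    scale: str | HydrophobicityScale = DEFAULT_SCALE
    cutoff: float = DEFAULT_CUTOFF
    sigma_convention: str = "max_extent_3"
    k_max: float = DEFAULT_K_MAX
    k_step: float = DEFAULT_K_STEP

    def as_dict(self) -> dict:
        name = self.scale if isinstance(self.scale, str) else self.scale.name
        return {
            "scale": name, "cutoff": self.cutoff,
            "sigma_convention": self.sigma_convention,
            "k_max": self.k_max, "k_step": self.k_step,
        }


@dataclass(frozen=True)
class FodStatus:
    """The FOD-M summary of one structural unit.

    Divergences are in bits.  ``degenerate`` flags the O = T = R corner where
    RD's denominator vanishes and RD is reported as 0 by convention.
    """

    dkl_ot: float
    dkl_or: float
    rd: float
    k_star: float
    dkl_om: float
    n_residues: int
    scope: str = "unit"
    label: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (0.0 <= self.rd <= 1.0):
            raise ValueError(f"RD out of [0,1]: {self.rd}")
        if self.k_star < 0:
            raise ValueError("k_star must be nonnegative")

    def as_dict(self) -> dict:
        return {
            "label": self.label, "scope": self.scope,
            "n_residues": self.n_residues,
            "dkl_OT": self.dkl_ot, "dkl_OR": self.dkl_or,
            "RD": self.rd, "K": round(self.k_star, 2), "dkl_OM": self.dkl_om,
            "degenerate": self.degenerate,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.as_dict(), **kwargs)

    def tsv_row(self) -> str:
        d = self.as_dict()
        return "\t".join(
            f"{d[c]:.6g}" if isinstance(d[c], float) else str(d[c])
            for c in ("label", "scope", "n_residues", "dkl_OT", "dkl_OR",
                      "RD", "K", "dkl_OM")
        )

    TSV_HEADER = "label\tscope\tn_residues\tdkl_OT\tdkl_OR\tRD\tK\tdkl_OM"


def _values(p: HydroProfile | np.ndarray) -> np.ndarray:
    if isinstance(p, HydroProfile):
        if not p.normalized:
            raise ProfileError(f"{p.kind} profile must be normalized")
        return p.values
    return np.asarray(p, dtype=float)


def kl_divergence(
    p: HydroProfile | np.ndarray, q: HydroProfile | np.ndarray, base: float = 2.0
) -> float:
    """Divergence entropy sum_i P_i log(P_i / Q_i); terms with P_i = 0 are 0.

    Requires equal lengths and Q_i > 0 wherever P_i > 0.
    """
    pv, qv = _values(p), _values(q)
    if pv.shape != qv.shape:
        raise ProfileError(f"length mismatch: {pv.shape} vs {qv.shape}")
    mask = pv > 0
    if np.any(qv[mask] <= 0):
        raise ProfileError("support error: P_i > 0 where Q_i = 0")
    val = float(np.sum(pv[mask] * np.log(pv[mask] / qv[mask])) / math.log(base))
    return max(val, 0.0)


def rd(
    o: HydroProfile | np.ndarray,
    t: HydroProfile | np.ndarray,
    r: HydroProfile | np.ndarray,
) -> float:
    """Relative distance of O between the T (micelle) and R (uniform) fields.

    Returns D_KL(O|T) / (D_KL(O|T) + D_KL(O|R)); the degenerate O = T = R
    case returns 0.0 (callers needing the flag use :func:`rd_with_flag`).
    """
    return rd_with_flag(o, t, r)[0]


def rd_with_flag(o, t, r) -> tuple[float, bool]:
    d_ot = kl_divergence(o, t)
    d_or = kl_divergence(o, r)
    denom = d_ot + d_or
    if denom == 0.0:
        return 0.0, True
    return d_ot / denom, False


def opposite_profile(t: HydroProfile) -> HydroProfile:
    """Membrane-like opposite field: normalized (T_MAX - T_i).

    The arg-max residue of T gets 0.  Constant T is degenerate (zero sum).
    """
    tv = _values(t)
    raw = tv.max() - tv
    s = raw.sum()
    if s <= 0:
        raise ProfileError("constant T profile: opposite field is degenerate")
    return HydroProfile("opposite", raw / s, True, keys=t.keys, label=t.label)


def m_profile(t: HydroProfile, k: float) -> HydroProfile:
    """Environment-modified field M(K) = [T + K (T_MAX - T)_n]_n.

    M(0) = T exactly; as K grows M converges to the opposite field.
    """
    if k < 0:
        raise ValueError("K must be nonnegative")
    tv = _values(t)
    if k == 0:
        return HydroProfile("M", tv, True, keys=t.keys, label=t.label)
    opp = opposite_profile(t).values
    raw = tv + k * opp
    return HydroProfile("M", raw / raw.sum(), True, keys=t.keys, label=t.label)


def optimize_k(
    o: HydroProfile,
    t: HydroProfile,
    k_max: float = DEFAULT_K_MAX,
    k_step: float = DEFAULT_K_STEP,
) -> tuple[float, float]:
    """Fit K by minimizing D_KL(O | M(K)) over [0, k_max].

    Grid scan at ``k_step`` resolution followed by bounded local refinement
    around the best grid point.  Returns (k_star, minimum divergence); the
    minimum never exceeds D_KL(O|T) since K = 0 is in the grid.
    """
    ov = _values(o)
    tv = _values(t)
    if ov.shape != tv.shape:
        raise ProfileError("O and T must have equal length")
    opp = opposite_profile(t).values

    mask = ov > 0
    ovm, tvm, oppm = ov[mask], tv[mask], opp[mask]
    p_logp = float(np.sum(ovm * np.log(ovm)))

    def objective(k: float) -> float:
        raw = tvm + k * oppm
        # full-vector sum for the normalizer (includes O_i = 0 positions)
        z = (tv + k * opp).sum()
        return p_logp - float(np.sum(ovm * np.log(raw / z)))

    grid = np.arange(0.0, k_max + 0.5 * k_step, k_step)
    vals = np.array([objective(k) for k in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    k_best, f_best = float(grid[i]), float(vals[i])
    if hi > lo:
        res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        if res.fun <= f_best:
            k_best, f_best = float(res.x), float(res.fun)
    # objective works in nats; report the minimum in bits
    return k_best, max(f_best / math.log(2.0), 0.0)


def _status_from_profiles(
    o: HydroProfile, t: HydroProfile,
    scope: str, label: str,
    k_max: float = DEFAULT_K_MAX, k_step: float = DEFAULT_K_STEP,
) -> FodStatus:
    n = len(o)
    r = uniform_profile(n, keys=o.keys)
    rd_val, degen = rd_with_flag(o, t, r)
    if degen:
        k_star, dkl_om = 0.0, 0.0
    else:
        k_star, dkl_om = optimize_k(o, t, k_max=k_max, k_step=k_step)
    return FodStatus(
        dkl_ot=kl_divergence(o, t), dkl_or=kl_divergence(o, r),
        rd=rd_val, k_star=k_star, dkl_om=dkl_om,
        n_residues=n, scope=scope, label=label, degenerate=degen,
    )


def fragment_status(
    complex_t: HydroProfile,
    complex_o: HydroProfile,
    fragment: UnitSelection | Sequence[ResKey] | Sequence[int],
    label: str = "",
    k_max: float = DEFAULT_K_MAX,
    k_step: float = DEFAULT_K_STEP,
) -> FodStatus:
    """Status of a fragment *as part of* its complex.

    The fragment's T_i and O_i are lifted from the complex-wide profiles,
    renormalized to unit sum, compared against a uniform field of the
    fragment's length, and RD / K are determined independently on that
    renormalized triple.
    """
    if complex_t.keys is None or complex_o.keys is None:
        idx = np.asarray(list(fragment), dtype=int)
    else:
        if isinstance(fragment, UnitSelection):
            keys: Sequence[ResKey] = fragment.members
            label = label or fragment.label
        else:
            keys = list(fragment)
        index = {k: i for i, k in enumerate(complex_t.keys)}
        try:
            idx = np.array([index[k] for k in keys], dtype=int)
        except KeyError as exc:
            raise SelectionError(
                f"fragment residue {exc.args[0]} absent from complex profiles"
            ) from None
    t_sub = complex_t.subset(idx)
    o_sub = complex_o.subset(idx)
    return _status_from_profiles(o_sub, t_sub, "complex", label,
                                 k_max=k_max, k_step=k_step)


def compute_profiles(
    model: StructureModel,
    keys: Sequence[ResKey],
    params: FodParams = FodParams(),
) -> tuple[HydroProfile, HydroProfile, GaussianEnvelope]:
    """T and O profiles (plus the fitted envelope) over an explicit residue set."""
    records = effective_atoms(model, keys)
    records = assign_hydrophobicity(records, params.scale)
    oriented, env = orient_unit(records, sigma_convention=params.sigma_convention)
    t = theoretical_profile(oriented, env)
    o = observed_profile(oriented, cutoff=params.cutoff)
    return t, o, env


def unit_status(
    model: StructureModel,
    unit: UnitSelection,
    params: FodParams = FodParams(),
    return_profiles: bool = False,
):
    """Full pipeline dispatch for one structural unit.

    scope='unit': envelope and profiles over the unit itself.
    scope='complex': envelope and profiles over the enclosing complex, then
    the unit's status extracted with :func:`fragment_status`.
    """
    if unit.scope == "complex":
        span = unit.complex_members
    else:
        span = unit.members
    t, o, env = compute_profiles(model, span, params)
    if unit.scope == "complex":
        status = fragment_status(t, o, unit, label=unit.label,
                                 k_max=params.k_max, k_step=params.k_step)
    else:
        status = _status_from_profiles(o, t, "unit", unit.label,
                                       k_max=params.k_max, k_step=params.k_step)
    if return_profiles:
        return status, {"T": t, "O": o, "envelope": env}
    return status
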