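"""Model / Results interface over the FOD-M pipeline.

:class:`FodModel` bundles a structure, a unit selection and the analysis
parameters; ``fit()`` computes the T/O/R profiles, the divergence statistics
and the optimal environment parameter K, returning a :class:`FodResults`
with the estimates, a ``summary()`` table, per-residue data frames, the
derived analyses (elimination, segments, layers) and profile plotting.

Example
-------
>>> from fodm import FixtureSpec, make_fixture
>>> from fodm.model import FodModel
>>> model, _ = make_fixture(FixtureSpec("ideal_micelle", 200, seed=1))
>>> res = FodModel.from_structure(model, "A").fit()
>>> res.rd < 0.5
True
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .analysis import (
    EliminationResult, SegmentAnnotation, classify_layers,
    eliminate_to_threshold, excess_deficit_segments,
)
from .field import HydroProfile, uniform_profile
from .metrics import FodParams, FodStatus, m_profile, unit_status
from .structure import (
    StructureModel, UnitSelection, parse_structure, select,
)

__all__ = ["FodModel", "FodResults"]


class FodModel:
    """The fuzzy-oil-drop model of one structural unit.

    Parameters
    ----------
    structure : StructureModel
        Parsed structure (see :func:`fodm.parse_structure`).
    unit : UnitSelection
        The analyzed unit and the Gaussian scope (unit vs enclosing complex).
    params : FodParams
        Scale, Levitt cutoff, sigma convention and K search grid.
    """

    def __init__(self, structure: StructureModel, unit: UnitSelection,
                 params: FodParams = FodParams()):
        self.structure = structure
        self.unit = unit
        self.params = params

    @classmethod
    def from_structure(cls, structure: StructureModel, selection: str,
                       scope: str = "unit", complex_selection: str | None = None,
                       **param_kwargs) -> "FodModel":
        """Build from a parsed structure and selection expressions."""
        unit = select(structure, selection, scope=scope,
                      complex_expr=complex_selection)
        return cls(structure, unit, FodParams(**param_kwargs))

    @classmethod
    def from_file(cls, path: str | Path, selection: str, scope: str = "unit",
                  complex_selection: str | None = None, fmt: str = "auto",
                  **param_kwargs) -> "FodModel":
        """Build from a PDB/mmCIF file path."""
        return cls.from_structure(parse_structure(path, fmt), selection,
                                  scope=scope, complex_selection=complex_selection,
                                  **param_kwargs)

    def fit(self) -> "FodResults":
        """Run the pipeline and return the fitted results."""
        status, prof = unit_status(self.structure, self.unit, self.params,
                                   return_profiles=True)
        if self.unit.scope == "complex":
            index = {k: i for i, k in enumerate(prof["T"].keys)}
            idx = [index[k] for k in self.unit.members]
            t = prof["T"].subset(idx)
            o = prof["O"].subset(idx)
        else:
            t, o = prof["T"], prof["O"]
        r = uniform_profile(len(t), keys=t.keys)
        m = m_profile(t, status.k_star) if not status.degenerate else t
        return FodResults(self, status, t=t, o=o, r=r, m=m,
                          envelope=prof["envelope"])


@dataclass
class FodResults:
    """Fitted FOD-M results for one structural unit."""

    model: FodModel
    status: FodStatus
    t: HydroProfile
    o: HydroProfile
    r: HydroProfile
    m: HydroProfile
    envelope: object

    # -- estimates --------------------------------------------------------
    @property
    def rd(self) -> float:
        """Relative distance D_KL(O|T) / (D_KL(O|T) + D_KL(O|R))."""
        return self.status.rd

    @property
    def k(self) -> float:
        """Optimal environment parameter K (argmin of D_KL(O|M(K)))."""
        return self.status.k_star

    @property
    def dkl_ot(self) -> float:
        return self.status.dkl_ot

    @property
    def dkl_or(self) -> float:
        return self.status.dkl_or

    @property
    def dkl_om(self) -> float:
        return self.status.dkl_om

    @property
    def has_hydrophobic_core(self) -> bool:
        """RD < 0.5: observed distribution closer to the micelle field."""
        return self.rd < 0.5

    # -- tabulation -------------------------------------------------------
    def profiles_frame(self) -> pd.DataFrame:
        """Per-residue T/O/R/M table (chain, seq_id, aa where available)."""
        data = {"T": self.t.values, "O": self.o.values,
                "R": self.r.values, "M": self.m.values}
        if self.t.keys is not None:
            recs = {r.key: r for r in self.model.structure.residues}
            data = {
                "chain": [k[0] for k in self.t.keys],
                "seq_id": [k[1] for k in self.t.keys],
                "aa": [recs[k].aa_type if k in recs else "" for k in self.t.keys],
                **data,
            }
        return pd.DataFrame(data)

    def summary(self) -> str:
        """Human-readable estimate table in the style of statsmodels results."""
        s = self.status
        core = "yes" if self.has_hydrophobic_core else "no"
        lines = [
            "FOD-M status" + (f" — {s.label}" if s.label else ""),
            "=" * 46,
            f"{'residues':<28}{s.n_residues:>18d}",
            f"{'gaussian scope':<28}{s.scope:>18s}",
            f"{'scale':<28}{self.model.params.as_dict()['scale']:>18s}",
            f"{'Levitt cutoff (A)':<28}{self.model.params.cutoff:>18.2f}",
            "-" * 46,
            f"{'D_KL(O|T)  [bits]':<28}{s.dkl_ot:>18.6f}",
            f"{'D_KL(O|R)  [bits]':<28}{s.dkl_or:>18.6f}",
            f"{'RD':<28}{s.rd:>18.3f}",
            f"{'K':<28}{s.k_star:>18.2f}",
            f"{'D_KL(O|M(K))  [bits]':<28}{s.dkl_om:>18.6f}",
            f"{'hydrophobic core (RD<0.5)':<28}{core:>18s}",
            "=" * 46,
        ]
        if s.degenerate:
            lines.insert(-1, "note: degenerate unit (O = T = R); RD set to 0")
        return "\n".join(lines)

    # -- derived analyses -------------------------------------------------
    def eliminate(self, rd_threshold: float = 0.5) -> EliminationResult:
        """Greedy residue elimination until the remainder has RD < threshold."""
        return eliminate_to_threshold(self.t, self.o, rd_threshold=rd_threshold)

    def segments(self, min_len: int = 3,
                 tol: float | None = None) -> list[SegmentAnnotation]:
        """Contiguous excess / deficit segments of O relative to T."""
        return excess_deficit_segments(self.t, self.o, min_len=min_len, tol=tol)

    def layers(self, t_low: float = 0.001,
               t_high: float = 0.0015) -> list[SegmentAnnotation]:
        """Surface / subsurface / core-deficit layer classification."""
        return classify_layers(self.t, self.o, t_low=t_low, t_high=t_high)

    # -- plotting ---------------------------------------------------------
    def plot_profiles(self, ax=None, show_m: bool = True):
        """Overlay the T, O (and M) profiles along the sequence."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        x = np.arange(len(self.t))
        ax.plot(x, self.t.values, label="T", color="tab:blue")
        ax.plot(x, self.o.values, label="O", color="tab:red")
        if show_m:
            ax.plot(x, self.m.values, label=f"M (K={self.k:.2f})",
                    color="tab:green")
        ax.axhline(1.0 / len(self.t), color="gray", lw=0.8, ls="--", label="R")
        ax.set_xlabel("residue index")
        ax.set_ylabel("normalized hydrophobicity")
        ax.legend(frameon=False, ncol=4)
        return ax
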