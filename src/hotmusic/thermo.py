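"""Two-state thermodynamics relating dTm and ddG.

A protein following a reversible two-state transition with a
temperature-independent folding heat capacity has the stability curve

    dG(T) = dHm (1 - T/Tm) + dCp (T - Tm - T ln(T/Tm)),

parameterised by the melting temperature Tm (where dG = 0), the folding
enthalpy dHm at Tm and the folding heat capacity dCp.  Folding sign
convention: dG < 0 for a stable fold, dHm < 0, dCp < 0.

For a mutation that is a small perturbation (ddHm = ddCp = 0), the shift
of the zero of dG gives the linear relation

    dTm = Tm ddG / dHm,

so dTm and ddG are anticorrelated (dHm < 0).  In general the mutant
enthalpy and heat capacity change too and the relation is lost; the
general case is handled numerically by constructing the mutant stability
curve and re-solving for its melting temperature.

All quantities in this module are in Kelvin and kcal/mol; the model
layers convert to Celsius at their boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

DEFAULT_BRACKET = (250.0, 450.0)
REFERENCE_TEMPERATURE = 298.0  # K


@dataclass
class StabilityCurve:
    """Gibbs-Helmholtz stability curve of a two-state folder."""

    tm: float            # K
    dhm: float           # folding enthalpy at tm, kcal/mol (negative)
    dcp: float = 0.0     # folding heat capacity, kcal/(mol K)

    def __post_init__(self) -> None:
        if self.tm <= 0:
            raise ValueError("Tm must be positive (Kelvin)")
        if self.dhm >= 0:
            raise ValueError(
                "folding enthalpy must be negative under the folding sign convention"
            )

    def __call__(self, T: float | np.ndarray):
        return gibbs_free_energy(self, T)


def gibbs_free_energy(curve: StabilityCurve, T: float | np.ndarray):
    """dG(T) in kcal/mol; zero at T = Tm by construction."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    out = curve.dhm * (1.0 - T / curve.tm) + curve.dcp * (
        T - curve.tm - T * np.log(T / curve.tm)
    )
    return float(out) if out.ndim == 0 else out


def solve_tm(
    dg,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    near: float | None = None,
    tol: float = 1e-9,
) -> float:
    """Temperature at which a dG(T) function crosses zero.

    Scans the bracket on a fine grid, refines every sign change by Brent's
    method to |dG| < ``tol`` kcal/mol, and returns the root nearest to
    ``near`` (a wild-type Tm, say) when several exist — a curve with cold
    denaturation has two zeros.
    """
    lo, hi = bracket
    grid = np.linspace(lo, hi, 2001)
    vals = np.asarray([dg(t) for t in grid])
    roots: list[float] = []
    sign = np.sign(vals)
    for k in range(len(grid) - 1):
        if sign[k] == 0:
            roots.append(float(grid[k]))
        elif sign[k] * sign[k + 1] < 0:
            roots.append(float(brentq(dg, grid[k], grid[k + 1], xtol=1e-12)))
    if sign[-1] == 0:
        roots.append(float(grid[-1]))
    if not roots:
        raise ValueError(
            f"dG does not change sign on [{lo}, {hi}] K; no melting "
            "temperature in the search bracket"
        )
    roots = [t for t in roots if abs(dg(t)) < tol] or roots
    if near is not None:
        root = min(roots, key=lambda t: abs(t - near))
    else:
        root = roots[0]
    assert abs(dg(root)) < tol
    return root


def dtm_small_perturbation(ddg: float, tm_wild: float, dhm: float) -> float:
    """Linear small-perturbation estimate dTm = Tm ddG / dHm (Kelvin).

    Valid when the mutation leaves the folding enthalpy and heat capacity
    unchanged; with dHm < 0 a destabilising mutation (ddG > 0) lowers Tm.
    """
    if dhm == 0:
        raise ValueError("dHm must be nonzero")
    return tm_wild * ddg / dhm


def mutant_curve(
    wt: StabilityCurve,
    ddg_at_tr: float,
    ddhm: float = 0.0,
    ddcp: float = 0.0,
    t_ref: float = REFERENCE_TEMPERATURE,
):
    """dG(T) of the mutant: the wild-type curve with shifted enthalpy and
    heat capacity, offset so that dG_mut(Tr) = dG_wt(Tr) + ddG."""
    shifted = StabilityCurve(tm=wt.tm, dhm=wt.dhm + ddhm, dcp=wt.dcp + ddcp)
    offset = gibbs_free_energy(wt, t_ref) + ddg_at_tr - gibbs_free_energy(shifted, t_ref)

    def dg(T):
        return gibbs_free_energy(shifted, T) + offset

    return dg


def dtm_general(
    wt: StabilityCurve,
    ddg_at_tr: float,
    ddhm: float = 0.0,
    ddcp: float = 0.0,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
) -> float:
    """Numeric dTm (Kelvin) without the small-perturbation assumption.

    Constructs the mutant stability curve and re-solves its melting
    temperature; a mutation with ddG(Tr) = 0 but ddHm != 0 still shifts Tm
    (the stability curves cross at room temperature, not at Tm).
    """
    dg_mut = mutant_curve(wt, ddg_at_tr, ddhm, ddcp)
    return solve_tm(dg_mut, bracket=bracket, near=wt.tm) - wt.tm
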