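"""Four-microstate equilibrium model of two transcription factors on a DNA probe.

A DNA element that carries adjacent half-sites for a Sox factor (S) and a
Pax factor (P) partitions, at equilibrium, into four microstates: free DNA,
the two binary complexes S·D and P·D, and the ternary complex S·P·D.  With
dissociation constants ``kd_sox`` and ``kd_pax`` for the binary complexes,
the ternary complex is governed by the cooperativity factor ``omega``:

    [SD]  = [S][D] / kd_sox
    [PD]  = [P][D] / kd_pax
    [SPD] = omega * [S][P][D] / (kd_sox * kd_pax)

omega > 1 means the two proteins recruit each other to the element
(cooperative binding), omega = 1 means they bind independently (additive),
and omega < 1 means they compete.  The solver finds the free concentrations
[S], [P], [D] satisfying conservation of all three species and returns the
probe's occupancy fractions — the quantities a quantified gel lane reports.

All concentrations are in nM throughout; no unit conversion happens here.
The full mass-balance system is always solved: no trace-probe approximation
is made, because the experiments this models use probe concentrations
comparable to (or exceeding) the protein concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "BindingParameters",
    "SpeciesTotals",
    "MicrostateFractions",
    "TwoProbeSystem",
    "EquilibriumError",
    "solve_equilibrium",
    "solve_two_probe",
    "titration_series",
    "fraction_bound_single",
]

DEFAULT_REL_TOL = 1e-10
MAX_ITER = 10_000


class EquilibriumError(ValueError):
    """Raised for invalid parameters or a solver that fails mass balance."""


def _require_positive_finite(value: float, name: str) -> None:
    if not (math.isfinite(value) and value > 0):
        raise EquilibriumError(f"{name} must be strictly positive and finite, got {value!r}")


def _require_nonnegative_finite(value: float, name: str) -> None:
    if not (math.isfinite(value) and value >= 0):
        raise EquilibriumError(f"{name} must be non-negative and finite, got {value!r}")


@dataclass(frozen=True)
class BindingParameters:
    """Energetics of one DNA element: two dissociation constants and omega.

    Parameters
    ----------
    kd_sox, kd_pax : float
        Dissociation constants (nM, > 0) of the Sox and Pax binary complexes.
    omega : float
        Dimensionless cooperativity factor (> 0); ratio of the ternary-complex
        association constant to the product of the binary ones.
    label : str
        Free-text element name (e.g. "DC5").
    """

    kd_sox: float
    kd_pax: float
    omega: float
    label: str = ""

    def __post_init__(self) -> None:
        _require_positive_finite(self.kd_sox, "kd_sox")
        _require_positive_finite(self.kd_pax, "kd_pax")
        _require_positive_finite(self.omega, "omega")


@dataclass(frozen=True)
class SpeciesTotals:
    """Total (bound + free) concentrations of probe and both proteins, nM."""

    dna_tot: float
    sox_tot: float
    pax_tot: float

    def __post_init__(self) -> None:
        _require_nonnegative_finite(self.dna_tot, "dna_tot")
        _require_nonnegative_finite(self.sox_tot, "sox_tot")
        _require_nonnegative_finite(self.pax_tot, "pax_tot")


@dataclass(frozen=True)
class MicrostateFractions:
    """Occupancy fractions of a probe over its four microstates.

    ``f_free + f_sox + f_pax + f_dimer = 1`` within 1e-9; each in [0, 1].
    The four fields correspond, in order, to the free-DNA, Sox-bound,
    Pax-bound and ternary (Sox+Pax) bands of a gel lane.
    """

    f_free: float
    f_sox: float
    f_pax: float
    f_dimer: float

    def __post_init__(self) -> None:
        for name in ("f_free", "f_sox", "f_pax", "f_dimer"):
            v = getattr(self, name)
            if not (math.isfinite(v) and -1e-12 <= v <= 1 + 1e-12):
                raise EquilibriumError(f"{name} out of [0, 1]: {v!r}")
        total = self.f_free + self.f_sox + self.f_pax + self.f_dimer
        if abs(total - 1.0) > 1e-9:
            raise EquilibriumError(f"microstate fractions sum to {total!r}, expected 1")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.f_free, self.f_sox, self.f_pax, self.f_dimer)


@dataclass(frozen=True)
class TwoProbeSystem:
    """Two differently labelled probes competing for shared protein pools."""

    probe_a: BindingParameters
    probe_b: BindingParameters
    dna_tot_a: float
    dna_tot_b: float
    sox_tot: float
    pax_tot: float

    def __post_init__(self) -> None:
        _require_positive_finite(self.dna_tot_a, "dna_tot_a")
        _require_positive_finite(self.dna_tot_b, "dna_tot_b")
        _require_nonnegative_finite(self.sox_tot, "sox_tot")
        _require_nonnegative_finite(self.pax_tot, "pax_tot")


def fraction_bound_single(kd: float, protein_free: float) -> float:
    """Single-site binding isotherm: fraction of probe bound at a given free
    protein concentration, ``protein_free / (protein_free + kd)``.

    Closed-form limit of the full solver when only one protein is present and
    the probe is in trace amounts; used as an independent cross-check.
    """
    _require_positive_finite(kd, "kd")
    _require_nonnegative_finite(protein_free, "protein_free")
    return protein_free / (protein_free + kd)


def _free_dna(probes, s_free: float, p_free: float) -> list[float]:
    """Free concentration of every probe given free protein concentrations."""
    out = []
    for params, dna_tot in probes:
        denom = (
            1.0
            + s_free / params.kd_sox
            + p_free / params.kd_pax
            + params.omega * s_free * p_free / (params.kd_sox * params.kd_pax)
        )
        out.append(dna_tot / denom)
    return out


def _protein_balance(probes, s_free: float, p_free: float) -> tuple[float, float]:
    """Total Sox and Pax implied by the free concentrations (bound + free)."""
    s_tot = s_free
    p_tot = p_free
    for (params, _), d_free in zip(probes, _free_dna(probes, s_free, p_free)):
        coop = params.omega * s_free * p_free * d_free / (params.kd_sox * params.kd_pax)
        s_tot += s_free * d_free / params.kd_sox + coop
        p_tot += p_free * d_free / params.kd_pax + coop
    return s_tot, p_tot


def _solve_free_proteins(probes, sox_tot: float, pax_tot: float, rel_tol: float):
    """Find free [S], [P] by nested bracketed root-finding.

    DNA balance is satisfied identically by eliminating each [D] in closed
    form, so only the two protein balances remain.  Both residuals change
    sign over the physical bracket [0, total], guaranteeing a root; the
    inner solve (Pax balance at fixed [S]) is nested inside the outer solve
    on the Sox balance.  Derivative-free and robust for any omega > 0.
    """
    xtol = max(rel_tol * max(sox_tot, pax_tot, 1.0) * 1e-3, 1e-300)

    def p_free_at(s_free: float) -> float:
        if pax_tot == 0:
            return 0.0

        def p_resid(p_free: float) -> float:
            return _protein_balance(probes, s_free, p_free)[1] - pax_tot

        if p_resid(pax_tot) <= 0:  # proteins saturate nothing: free = total
            return pax_tot
        return brentq(p_resid, 0.0, pax_tot, xtol=xtol, rtol=8.9e-16, maxiter=MAX_ITER)

    if sox_tot == 0:
        return 0.0, p_free_at(0.0)

    def s_resid(s_free: float) -> float:
        return _protein_balance(probes, s_free, p_free_at(s_free))[0] - sox_tot

    if s_resid(sox_tot) <= 0:
        s_free = sox_tot
    else:
        s_free = brentq(s_resid, 0.0, sox_tot, xtol=xtol, rtol=8.9e-16, maxiter=MAX_ITER)
    return s_free, p_free_at(s_free)


def _validate_solution(probes, totals_dna, sox_tot, pax_tot, s_free, p_free, rel_tol, what):
    s_implied, p_implied = _protein_balance(probes, s_free, p_free)
    checks = [(sox_tot, s_implied, "Sox"), (pax_tot, p_implied, "Pax")]
    for stated, computed, name in checks:
        scale = stated if stated > 0 else 1.0
        if abs(computed - stated) / scale > max(rel_tol, 1e-12) * 10:
            raise EquilibriumError(
                f"solver failed {name} mass balance for {what}: "
                f"stated {stated} nM, recovered {computed} nM"
            )


def solve_equilibrium(
    params: BindingParameters,
    totals: SpeciesTotals,
    rel_tol: float = DEFAULT_REL_TOL,
) -> MicrostateFractions:
    """Solve the four-microstate equilibrium for one probe.

    Returns the probe's occupancy fractions.  Mass balance for DNA, Sox and
    Pax holds to within ``rel_tol`` (relative), and the complex
    concentrations obey the binding polynomials at the returned free
    concentrations.

    Raises
    ------
    EquilibriumError
        If ``dna_tot`` is zero, parameters are invalid, or the bracketed
        root search fails to satisfy mass balance.
    """
    if totals.dna_tot <= 0:
        raise EquilibriumError("dna_tot must be > 0 to define microstate fractions")
    probes = [(params, totals.dna_tot)]
    s_free, p_free = _solve_free_proteins(probes, totals.sox_tot, totals.pax_tot, rel_tol)
    _validate_solution(
        probes, [totals.dna_tot], totals.sox_tot, totals.pax_tot,
        s_free, p_free, rel_tol, params.label or "probe",
    )
    return _fractions_for(params, s_free, p_free)


def _fractions_for(params: BindingParameters, s_free: float, p_free: float) -> MicrostateFractions:
    w_free = 1.0
    w_sox = s_free / params.kd_sox
    w_pax = p_free / params.kd_pax
    w_dimer = params.omega * s_free * p_free / (params.kd_sox * params.kd_pax)
    z = w_free + w_sox + w_pax + w_dimer
    return MicrostateFractions(w_free / z, w_sox / z, w_pax / z, w_dimer / z)


def solve_two_probe(
    system: TwoProbeSystem, rel_tol: float = DEFAULT_REL_TOL
) -> tuple[MicrostateFractions, MicrostateFractions]:
    """Solve two probes sharing one Sox pool and one Pax pool.

    Models the differential-assembly experiment in which two differently
    labelled elements compete for the same proteins; the free-protein pool
    is identical across probes and combined mass balance holds.
    """
    probes = [(system.probe_a, system.dna_tot_a), (system.probe_b, system.dna_tot_b)]
    s_free, p_free = _solve_free_proteins(probes, system.sox_tot, system.pax_tot, rel_tol)
    _validate_solution(
        probes, [system.dna_tot_a, system.dna_tot_b], system.sox_tot, system.pax_tot,
        s_free, p_free, rel_tol, f"{system.probe_a.label}/{system.probe_b.label}",
    )
    return (
        _fractions_for(system.probe_a, s_free, p_free),
        _fractions_for(system.probe_b, s_free, p_free),
    )


def titration_series(
    params: BindingParameters,
    base_totals: SpeciesTotals,
    varying_species: str,
    grid: list[float],
    rel_tol: float = DEFAULT_REL_TOL,
) -> list[tuple[float, MicrostateFractions]]:
    """Solve the equilibrium along a titration of one protein.

    ``varying_species`` is ``"sox"`` or ``"pax"``; ``grid`` is the series of
    total concentrations (nM) of that species, solved in the given order.
    Along an increasing grid, the total bound fraction 1 - f_free is
    non-decreasing.
    """
    if varying_species not in ("sox", "pax"):
        raise EquilibriumError(f"varying_species must be 'sox' or 'pax', got {varying_species!r}")
    if not grid:
        raise EquilibriumError("titration grid must be non-empty")
    out = []
    for conc in grid:
        _require_nonnegative_finite(conc, "grid concentration")
        totals = SpeciesTotals(
            dna_tot=base_totals.dna_tot,
            sox_tot=conc if varying_species == "sox" else base_totals.sox_tot,
            pax_tot=conc if varying_species == "pax" else base_totals.pax_tot,
        )
        try:
            out.append((conc, solve_equilibrium(params, totals, rel_tol)))
        except EquilibriumError as err:
            raise EquilibriumError(f"at {varying_species}_tot={conc} nM: {err}") from err
    return out
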