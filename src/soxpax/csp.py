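"""Chemical shift perturbation (CSP) mapping between two titration states.

Amide resonances move when a protein binds a ligand; the per-residue
perturbation between two 2D [15N,1H] correlation spectra is combined into a
single weighted distance

    delta = sqrt(delta_H**2 + (alpha * delta_N)**2),    alpha = 0.1

where delta_H and delta_N are the 1H and 15N shift changes in ppm.  The
nitrogen scaling compensates for the ~10x wider 15N ppm range; 0.1 is used
here exactly (not the 0.154 variant sometimes seen), configurable.
Residues whose weighted CSP exceeds a threshold (conventionally 0.1 ppm)
are classified as significantly perturbed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PeakAssignment",
    "CSPRecord",
    "CSPError",
    "DEFAULT_N_WEIGHT",
    "weighted_csp",
    "compare_states",
    "classify_perturbed",
    "read_peak_list",
    "write_csp_table",
]

DEFAULT_N_WEIGHT = 0.1


class CSPError(ValueError):
    pass


@dataclass(frozen=True)
class PeakAssignment:
    """One assigned amide cross-peak: residue plus its 1H/15N shifts (ppm)."""

    residue_index: int
    residue_code: str
    h_ppm: float
    n_ppm: float

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise CSPError(f"residue_index must be >= 1, got {self.residue_index}")
        if not (math.isfinite(self.h_ppm) and math.isfinite(self.n_ppm)):
            raise CSPError(f"residue {self.residue_index}: shifts must be finite")


@dataclass(frozen=True)
class CSPRecord:
    """Per-residue shift changes between two states and their weighted CSP.

    ``status`` is ``ok`` for residues present in both states; residues seen
    in only one state carry ``missing_in_a``/``missing_in_b`` and NaN values.
    """

    residue_index: int
    delta_h: float
    delta_n: float
    weighted: float
    status: str

    def __post_init__(self) -> None:
        if self.status not in ("ok", "missing_in_a", "missing_in_b"):
            raise CSPError(f"invalid status {self.status!r}")
        if self.status == "ok" and not self.weighted >= 0:
            raise CSPError("weighted CSP must be >= 0 for matched residues")


def weighted_csp(delta_h: float, delta_n: float, n_weight: float = DEFAULT_N_WEIGHT) -> float:
    """Weighted CSP in ppm: sqrt(delta_h^2 + (n_weight * delta_n)^2).

    Sign-insensitive in both arguments; reduces to |delta_h| when delta_n=0
    and to n_weight*|delta_n| when delta_h=0.
    """
    if not (math.isfinite(delta_h) and math.isfinite(delta_n)):
        raise CSPError("shift differences must be finite")
    return math.hypot(delta_h, n_weight * delta_n)


def compare_states(
    state_a: list[PeakAssignment],
    state_b: list[PeakAssignment],
    n_weight: float = DEFAULT_N_WEIGHT,
) -> list[CSPRecord]:
    """Match peak lists by residue index and compute per-residue CSPs (b - a).

    Residues present in only one list are emitted with a missing status so
    that exchange-broadened (disappearing) peaks stay visible downstream.
    """
    for name, state in (("state_a", state_a), ("state_b", state_b)):
        indices = [p.residue_index for p in state]
        if len(indices) != len(set(indices)):
            dupes = sorted({i for i in indices if indices.count(i) > 1})
            raise CSPError(f"duplicate residue indices in {name}: {dupes}")
    a_by_idx = {p.residue_index: p for p in state_a}
    b_by_idx = {p.residue_index: p for p in state_b}
    records = []
    for idx in sorted(set(a_by_idx) | set(b_by_idx)):
        if idx in a_by_idx and idx in b_by_idx:
            dh = b_by_idx[idx].h_ppm - a_by_idx[idx].h_ppm
            dn = b_by_idx[idx].n_ppm - a_by_idx[idx].n_ppm
            records.append(
                CSPRecord(idx, dh, dn, weighted_csp(dh, dn, n_weight), "ok")
            )
        elif idx in a_by_idx:
            records.append(CSPRecord(idx, math.nan, math.nan, math.nan, "missing_in_b"))
        else:
            records.append(CSPRecord(idx, math.nan, math.nan, math.nan, "missing_in_a"))
    return records


def classify_perturbed(records: list[CSPRecord], threshold: float = 0.1) -> list[int]:
    """Residue indices with status ok and weighted CSP strictly above the
    threshold (ppm), sorted by index."""
    return sorted(
        r.residue_index for r in records if r.status == "ok" and r.weighted > threshold
    )


def read_peak_list(path) -> list[PeakAssignment]:
    """Read a TSV peak list: columns residue_index, residue_code, h_ppm, n_ppm."""
    df = pd.read_csv(path, sep="\t")
    required = ["residue_index", "residue_code", "h_ppm", "n_ppm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CSPError(f"peak list {path} missing columns: {missing}")
    return [
        PeakAssignment(
            residue_index=int(r.residue_index),
            residue_code=str(r.residue_code),
            h_ppm=float(r.h_ppm),
            n_ppm=float(r.n_ppm),
        )
        for r in df.itertuples()
    ]


def write_csp_table(records: list[CSPRecord], path) -> None:
    pd.DataFrame(
        {
            "residue_index": [r.residue_index for r in records],
            "delta_h": [r.delta_h for r in records],
            "delta_n": [r.delta_n for r in records],
            "weighted": [r.weighted for r in records],
            "status": [r.status for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
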