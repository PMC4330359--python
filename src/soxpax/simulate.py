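"""Synthetic-data generators with full ground truth.

Every input the pipeline consumes can be generated here: noisy four-band
gel quantifications drawn from the equilibrium model, random genomes with
planted composite sox-pax sites, and paired NMR peak lists with controlled
per-residue perturbations.  All generators are deterministic under a fixed
seed and return the truth needed to test the downstream estimators.

Gel band noise is multiplicative lognormal with median 1 (sigma chosen so
the factor's coefficient of variation equals ``noise_cv``), reflecting
densitometry's intensity-proportional error.  Because the cooperativity
statistic is a ratio of four equal-CV lognormal factors, this noise model
leaves the estimator median-unbiased.

The element presets encode the qualitative outcome of each studied DNA
element: strong cooperativity for the native degenerate elements (DC5
omega=25, N3 omega=50), additive binding on the SELEX-consensus element
(DC5con omega=1), competition with a barely detectable ternary band (LE9
omega=0.2 at low pax affinity), and an order-of-magnitude cooperativity
drop for all artificial spacer variants.  The omega values follow the
published qualitative ranges; the absolute dissociation constants are this
package's own choices (100-1000 nM, flagged in each preset's note) since no
absolute affinities are reported for these elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cooperativity import LaneQuantification
from .csp import PeakAssignment
from .equilibrium import BindingParameters, SpeciesTotals, solve_equilibrium
from .motifs import IUPAC_CODES, CompositeMotif, MotifHit, scan_composite

__all__ = [
    "GelSimConfig",
    "ElementPreset",
    "SimulationError",
    "simulate_gel_replicates",
    "preset_registry",
    "get_preset",
    "plant_composite_motifs",
    "simulate_peak_lists",
]

_KD_NOTE = "Kd magnitudes are this package's synthetic choices, not measured values."


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GelSimConfig:
    """Configuration of one simulated replicate series of gel lanes."""

    params: BindingParameters
    totals: SpeciesTotals
    n_replicates: int
    noise_cv: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")
        if not (math.isfinite(self.noise_cv) and self.noise_cv >= 0):
            raise SimulationError("noise_cv must be finite and >= 0")


@dataclass(frozen=True)
class ElementPreset:
    """A named DNA element with its binding parameterization and provenance note."""

    name: str
    params: BindingParameters
    note: str


def _lognormal_median1_sigma(cv: float) -> float:
    # CV of a lognormal depends only on sigma: CV^2 = exp(sigma^2) - 1
    return math.sqrt(math.log(1.0 + cv * cv))


def simulate_gel_replicates(config: GelSimConfig) -> list[LaneQuantification]:
    """Simulate quantified gel lanes from the equilibrium model.

    Each replicate solves the noise-free equilibrium, then multiplies every
    band fraction by an independent lognormal factor with median 1 and the
    configured CV.  Identical seed and config give identical lanes.
    """
    fractions = solve_equilibrium(config.params, config.totals)
    base = np.asarray(fractions.as_tuple())
    rng = np.random.default_rng(config.seed)
    sigma = _lognormal_median1_sigma(config.noise_cv)
    lanes = []
    for rep in range(1, config.n_replicates + 1):
        factors = np.exp(rng.normal(0.0, sigma, size=4)) if sigma > 0 else np.ones(4)
        bands = base * factors
        lanes.append(
            LaneQuantification(
                lane_id=f"{config.params.label or 'element'}_rep{rep}",
                i_free=float(bands[0]),
                i_sox=float(bands[1]),
                i_pax=float(bands[2]),
                i_dimer=float(bands[3]),
            )
        )
    return lanes


def preset_registry() -> list[ElementPreset]:
    """Named element presets spanning the studied binding regimes.

    DC5/N3: native degenerate elements, strongly cooperative (omega 25/50,
    low pax affinity).  DC5con: consensus pax half-site, additive (omega 1,
    high pax affinity).  LE9: competitive with a sub-threshold ternary band
    (omega 0.2, low pax affinity).  Spacer variants: cooperativity collapsed
    by at least an order of magnitude relative to DC5 (omega 2 for
    insertions, 0.3 for deletions).
    """
    degenerate = dict(kd_sox=100.0, kd_pax=1000.0)
    consensus = dict(kd_sox=100.0, kd_pax=100.0)
    presets = [
        ElementPreset(
            "DC5",
            BindingParameters(omega=25.0, label="DC5", **degenerate),
            "Native degenerate element; cooperative (omega in the 20-50 band). " + _KD_NOTE,
        ),
        ElementPreset(
            "N3",
            BindingParameters(omega=50.0, label="N3", **degenerate),
            "Native degenerate element; cooperative (omega in the 20-50 band). " + _KD_NOTE,
        ),
        ElementPreset(
            "DC5con",
            BindingParameters(omega=1.0, label="DC5con", **consensus),
            "Consensus pax half-site; additive binding (omega ~ 1). " + _KD_NOTE,
        ),
        ElementPreset(
            "LE9",
            BindingParameters(kd_sox=1000.0, kd_pax=1000.0, omega=0.2, label="LE9"),
            "Competitive element; ternary band below detectability at the "
            "standard 300/300/300 nM conditions. " + _KD_NOTE,
        ),
    ]
    for d in (1, 2, 3, 4, 5):
        presets.append(
            ElementPreset(
                f"spacer+{d}",
                BindingParameters(omega=2.0, label=f"spacer+{d}", **degenerate),
                "Increased half-site spacing; cooperativity collapsed >10-fold. " + _KD_NOTE,
            )
        )
    for d in (1, 2):
        presets.append(
            ElementPreset(
                f"spacer-{d}",
                BindingParameters(omega=0.3, label=f"spacer-{d}", **degenerate),
                "Reduced half-site spacing; competitive (omega < 1). " + _KD_NOTE,
            )
        )
    return presets


def get_preset(name: str) -> ElementPreset:
    for preset in preset_registry():
        if preset.name == name:
            return preset
    known = ", ".join(p.name for p in preset_registry())
    raise KeyError(f"unknown element preset {name!r}; known presets: {known}")


def plant_composite_motifs(
    genome_length: int,
    n_sequences: int,
    motif: CompositeMotif,
    sites_per_sequence: int,
    seed: int,
    max_tries: int = 1000,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Random genomes with planted composite motif instances and full truth.

    Background bases are i.i.d. uniform ACGT.  Each planted instance is an
    independent uniform draw from the IUPAC expansion of each half-site
    letter, placed without overlap on a uniformly chosen strand and offset.
    Because background (or instance juxtaposition) can create accidental
    matches, the returned truth table is post-corrected by an exhaustive
    scan of the final sequences; the raw planted table is returned alongside.

    Returns (sequences, planted, truth) where both tables have columns
    seq_id/offset/strand/start/end and truth equals the exhaustive scan.
    """
    if genome_length < motif.span_length:
        raise SimulationError("genome_length shorter than the motif span")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    sequences: dict[str, str] = {}
    planted_rows = []
    for s in range(n_sequences):
        seq_id = f"synth_{s}"
        seq = rng.choice(bases, size=genome_length)
        occupied: list[tuple[int, int]] = []
        for _ in range(sites_per_sequence):
            placed = False
            for _try in range(max_tries):
                start = int(rng.integers(0, genome_length - motif.span_length + 1))
                end = start + motif.span_length
                if any(start < e and s0 < end for s0, e in occupied):
                    continue
                instance = _draw_instance(motif, rng)
                strand = "+" if rng.integers(2) == 0 else "-"
                if strand == "-":
                    from .motifs import reverse_complement

                    instance = reverse_complement(instance)
                seq[start:end] = list(instance)
                occupied.append((start, end))
                planted_rows.append(
                    {"seq_id": seq_id, "offset": start, "strand": strand, "start": start, "end": end}
                )
                placed = True
                break
            if not placed:
                raise SimulationError(
                    f"could not place {sites_per_sequence} non-overlapping sites "
                    f"in {seq_id} after {max_tries} tries"
                )
        sequences[seq_id] = "".join(seq)

    truth_rows = []
    for seq_id, seq in sequences.items():
        for hit in scan_composite(motif, seq, both_strands=True, seq_id=seq_id):
            truth_rows.append(
                {
                    "seq_id": hit.seq_id,
                    "offset": hit.offset,
                    "strand": hit.strand,
                    "start": hit.matched_span[0],
                    "end": hit.matched_span[1],
                }
            )
    columns = ["seq_id", "offset", "strand", "start", "end"]
    planted = pd.DataFrame(planted_rows, columns=columns)
    truth = pd.DataFrame(truth_rows, columns=columns)
    return sequences, planted, truth


def _draw_instance(motif: CompositeMotif, rng: np.random.Generator) -> str:
    from .motifs import reverse_complement

    sox = _expand_word(motif.sox_word.letters, rng)
    pax_letters = motif.pax_word.letters
    if motif.pax_orientation == "flipped":
        pax = reverse_complement(_expand_word(pax_letters, rng))
    else:
        pax = _expand_word(pax_letters, rng)
    spacer = "".join(rng.choice(list("ACGT")) for _ in range(motif.gap))
    return sox + spacer + pax


def _expand_word(letters: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(sorted(IUPAC_CODES[c])) for c in letters.upper())


def simulate_peak_lists(
    n_residues: int,
    perturbed_subset: dict[int, tuple[float, float]],
    jitter_sd: float,
    seed: int,
) -> tuple[list[PeakAssignment], list[PeakAssignment], dict[int, tuple[float, float]]]:
    """Paired NMR peak lists with known per-residue perturbations.

    State A amide shifts are drawn uniformly from realistic ranges (1H
    6-10 ppm, 15N 100-135 ppm); state B adds the specified (delta_h,
    delta_n) for perturbed residues plus Gaussian jitter of ``jitter_sd``
    ppm on every shift.  Returns (state_a, state_b, truth deltas).
    """
    if n_residues < 1:
        raise SimulationError("n_residues must be >= 1")
    bad = [r for r in perturbed_subset if not (1 <= r <= n_residues)]
    if bad:
        raise SimulationError(f"perturbed residues outside 1..{n_residues}: {bad}")
    rng = np.random.default_rng(seed)
    state_a, state_b = [], []
    for idx in range(1, n_residues + 1):
        h = float(rng.uniform(6.0, 10.0))
        n = float(rng.uniform(100.0, 135.0))
        dh, dn = perturbed_subset.get(idx, (0.0, 0.0))
        jh, jn = (rng.normal(0.0, jitter_sd, size=2) if jitter_sd > 0 else (0.0, 0.0))
        state_a.append(PeakAssignment(idx, "X", h, n))
        state_b.append(PeakAssignment(idx, "X", h + dh + float(jh), n + dn + float(jn)))
    return state_a, state_b, dict(perturbed_subset)
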