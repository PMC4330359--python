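#!/usr/bin/env python
"""Chemical-shift-perturbation mapping of a DNA-binding titration.

Simulates paired amide peak lists for an 81-residue DNA-binding domain in
its free and DNA-bound states, planting weighted CSPs above 0.1 ppm at ten
residues (indices 4, 16, 20, 24, 25, 34, 42, 43, 56, 65 — the strongly
perturbed set of the free-vs-bound comparison this emulates) plus small
sub-threshold perturbations elsewhere, computes per-residue weighted CSPs
(Δδ = sqrt(Δδ_H² + (0.1·Δδ_N)²)) and classifies residues above threshold.

Writes results/05_csp_records.tsv and prints the classified residue set.
"""

from pathlib import Path

import numpy as np

from soxpax.csp import classify_perturbed, compare_states, write_csp_table
from soxpax.simulate import simulate_peak_lists

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_RESIDUES = 81
STRONG = (4, 16, 20, 24, 25, 34, 42, 43, 56, 65)
SEED = 11


def main() -> None:
    rng = np.random.default_rng(SEED)
    perturbed = {r: (float(rng.uniform(0.12, 0.3)), float(rng.uniform(-2, 2)))
                 for r in STRONG}
    # weak background perturbations, kept below the 0.1 ppm threshold
    for r in range(1, N_RESIDUES + 1):
        if r not in perturbed:
            perturbed[r] = (float(rng.uniform(-0.03, 0.03)), float(rng.uniform(-0.3, 0.3)))

    state_free, state_bound, _ = simulate_peak_lists(
        N_RESIDUES, perturbed, jitter_sd=1e-4, seed=SEED
    )
    records = compare_states(state_free, state_bound)
    hits = classify_perturbed(records, threshold=0.1)

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "05_csp_records.tsv"
    write_csp_table(records, out)
    print(f"residues with weighted CSP > 0.1 ppm: {hits}")
    print(f"planted strong set recovered exactly: {tuple(hits) == STRONG}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
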