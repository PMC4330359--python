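#!/usr/bin/env python
"""Element series construction: spacer variants and nucleotide-switch mutants.

Two constructions on the composite-element architecture:

1. Spacer series. The full -2..+5 bp spacing series on a synthetic
   composite template with a 2-bp native spacer (the packaged native-element
   annotation has abutting half-sites, so reduced-spacing cuts are only
   possible on a spacered template).  Verifies both half-sites are preserved
   verbatim in every variant, and attaches the preset omega for each
   spacing to show the expected cooperativity collapse.

2. Switch-mutant series. All 1-, 2- and 3-position consensus substitutions
   of the four switch positions (3, 8, 9, 11) in a degenerate half-site,
   labelled conventionally (T3, G8C9, T3G8C9, ...), after recovering those
   positions from a high-information/deviation screen of a toy consensus
   PFM against the degenerate half-site.

Writes results/03_spacer_series.tsv and results/03_switch_mutants.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from soxpax.motifs import (
    PositionFrequencyMatrix,
    SwitchPositionSet,
    enumerate_spacer_variants,
    enumerate_switch_mutants,
    high_ic_deviations,
)
from soxpax.simulate import get_preset

RESULTS = Path(__file__).resolve().parents[1] / "results"

# synthetic composite template: sox CATTGT, 2-bp spacer, degenerate pax
TEMPLATE = "GGCATTGTAATGTTGCGG"
SOX_SPAN, PAX_SPAN = (2, 8), (10, 16)

# degenerate pax half-site vs a toy consensus differing at 3, 8, 9, 11
WILD_HALFSITE = "AACAACAATGAA"
CONSENSUS_HALFSITE = "AATAACAGCGTA"


def spacer_series() -> pd.DataFrame:
    deltas = [-2, -1, 0, 1, 2, 3, 4, 5]
    rows = []
    for delta, seq in enumerate_spacer_variants(
        TEMPLATE, SOX_SPAN, PAX_SPAN, deltas, insert_bases="CTGCA"
    ):
        omega = (
            get_preset("DC5").params.omega
            if delta == 0
            else get_preset(f"spacer{delta:+d}").params.omega
        )
        rows.append({"delta_bp": delta, "length": len(seq), "sequence": seq,
                     "preset_omega": omega})
    return pd.DataFrame(rows)


def switch_series() -> pd.DataFrame:
    # build a toy PFM whose informative columns encode the consensus at the
    # four switch positions; recover them by the IC/deviation screen
    cols = []
    for pos in range(1, len(CONSENSUS_HALFSITE) + 1):
        if WILD_HALFSITE[pos - 1] != CONSENSUS_HALFSITE[pos - 1]:
            col = [0.0] * 4
            col["ACGT".index(CONSENSUS_HALFSITE[pos - 1])] = 100.0
        else:
            col = [25.0] * 4
        cols.append(col)
    pfm = PositionFrequencyMatrix(np.array(cols).T, "toy_consensus")
    recovered = high_ic_deviations(pfm, WILD_HALFSITE, ic_threshold=1.0, pseudocount=0)
    print(f"high-IC deviating positions recovered: {sorted(recovered)}")

    variants = enumerate_switch_mutants(
        WILD_HALFSITE, CONSENSUS_HALFSITE, SwitchPositionSet(frozenset(recovered)), 3
    )
    return pd.DataFrame(
        {"label": [v.label for v in variants],
         "order": [len(v.positions) for v in variants],
         "sequence": [v.sequence for v in variants]}
    )


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spacers = spacer_series()
    spacers.to_csv(RESULTS / "03_spacer_series.tsv", sep="\t", index=False)
    native = spacers[spacers.delta_bp == 0].iloc[0]
    collapsed = spacers[spacers.delta_bp != 0].preset_omega.max()
    print(f"spacer series: native omega {native.preset_omega}, all altered spacings "
          f"<= {collapsed} (>= {native.preset_omega / collapsed:.0f}-fold collapse)")

    mutants = switch_series()
    mutants.to_csv(RESULTS / "03_switch_mutants.tsv", sep="\t", index=False)
    print(f"switch mutants: {len(mutants)} variants "
          f"({(mutants.order == 1).sum()} single, {(mutants.order == 2).sum()} double, "
          f"{(mutants.order == 3).sum()} triple)")
    print(f"wrote {RESULTS / '03_spacer_series.tsv'} and {RESULTS / '03_switch_mutants.tsv'}")


if __name__ == "__main__":
    main()
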