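# soxpax

Quantitative tools for **DNA-mediated transcription-factor cooperativity**,
built around the Sox–Pax paradigm: pairs of developmental transcription
factors (a Sox HMG domain and a Pax paired domain) that co-select composite
enhancer elements not through protein–protein contacts but through the DNA
sequence itself. The package is for biochemists and regulatory genomicists
who quantify such partnerships with gel-shift (EMSA) titrations, want to
model the underlying binding equilibria, scan genomes for composite
"cryptic" motifs, or map binding interfaces by NMR chemical shift
perturbation.

## The model and statistic

A composite element D with a sox and a pax half-site populates four
microstates at equilibrium — free DNA, Sox·DNA, Pax·DNA, and the ternary
Sox·Pax·DNA complex — governed by two dissociation constants and one
cooperativity factor ω:

    [SD] = [S][D]/K_S      [PD] = [P][D]/K_P      [SPD] = ω[S][P][D]/(K_S·K_P)

ω > 1: cooperative; ω = 1: additive (independent); ω < 1: competitive.
From a quantified gel lane with band fractions (f_free, f_sox, f_pax,
f_dimer), ω is estimated by the plug-in statistic

    ω̂ = (f_dimer · f_free) / (f_sox · f_pax)

which recovers the model's ω exactly for equilibrium fractions (the free
protein concentrations cancel) and is invariant to lane exposure.

Modules: `soxpax.equilibrium` (mass-balance solver, single and two-probe),
`soxpax.cooperativity` (ω estimation, replicate summaries, Kd fits),
`soxpax.motifs` (IUPAC composite-motif scanning, spacer/switch mutagenesis,
JASPAR PFM information content), `soxpax.peaks` (BED intersection into
co-bound regions, region motif fractions), `soxpax.csp` (weighted NMR CSP
mapping), `soxpax.simulate` (synthetic gels/genomes/peak lists with ground
truth). See `docs/methods.md` for the full model description and design
choices.

## Worked example

Simulate ten noisy replicate gel lanes of the cooperative native element
(preset `DC5`: ω = 25, 300 nM each of probe, Sox and Pax, band-noise
CV 0.1) and estimate ω:

```python
from soxpax.cooperativity import estimate_omega, normalize_lane, summarize_replicates
from soxpax.equilibrium import SpeciesTotals
from soxpax.simulate import GelSimConfig, get_preset, simulate_gel_replicates

lanes = simulate_gel_replicates(GelSimConfig(
    params=get_preset("DC5").params,
    totals=SpeciesTotals(300, 300, 300),
    n_replicates=10, noise_cv=0.1, seed=42,
))
summary = summarize_replicates([estimate_omega(normalize_lane(l)) for l in lanes])
print(f"median omega {summary.median:.2f} (IQR {summary.iqr_low:.2f}-{summary.iqr_high:.2f}, n={summary.n})")
```

```
median omega 25.21 (IQR 22.54-27.06, n=10)
```

The median lands near the true ω = 25: ten replicates at 10% band noise
recover strong cooperativity comfortably inside the 20–50 cooperative band.
Running the same protocol over every preset
(`python analysis/01_cooperativity_by_element.py`) prints the full element
panel — cooperative native elements, additive consensus element, collapsed
spacers — and flags the competitive element LE9 as unquantifiable because
its ternary band falls below the 1% detectability threshold:

```
       DC5: median omega  25.21 (IQR 22.54-27.06, n=10)
        N3: median omega  43.22 (IQR 37.07-51.51, n=10)
    DC5con: median omega   1.07 (IQR 0.95-1.24, n=10)
       LE9: not quantifiable (ternary band barely detectable)
```

## Analysis drivers

Numbered scripts under `analysis/` re-run each stage of the workflow on
synthetic data and write tables to `results/`:

1. `01_cooperativity_by_element.py` — ω across all element presets
2. `02_differential_assembly.py` — two competing probes sharing protein pools
3. `03_spacer_and_switch_series.py` — spacer series −2…+5 and nucleotide-switch mutants
4. `04_mutant_affinity_fits.py` — Kd recovery for reduced-affinity variants
5. `05_csp_mapping.py` — weighted CSPs and >0.1 ppm classification
6. `06_cobound_region_scan.py` — peak intersection and composite-word fractions

A `soxpax` console script exposes the same operations on files
(`soxpax --help`; e.g. `soxpax estimate-omega --lanes lanes.tsv`,
`soxpax scan --fasta seqs.fa --motif motif.yaml`, `soxpax csp --state-a
free.tsv --state-b bound.tsv`).

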