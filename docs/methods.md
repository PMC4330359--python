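# Methods

## The four-microstate equilibrium model

A composite DNA element carrying a sox half-site and a pax half-site
populates four microstates at equilibrium: free DNA (D), the binary
complexes S·D and P·D, and the ternary complex S·P·D. With dissociation
constants K_S and K_P (nM) for the binary complexes, the ternary complex is
governed by a single dimensionless cooperativity factor ω:

    [SD]  = [S][D] / K_S
    [PD]  = [P][D] / K_P
    [SPD] = ω [S][P][D] / (K_S K_P)

ω is the ratio of the ternary-complex association constant to the product
of the binary ones: ω > 1 means each protein stabilizes the other's binding
(cooperative), ω = 1 means independent (additive) binding, ω < 1 means
competition. The model has no kinetics, at most two proteins, and no
explicit DNA-deformation energetics — ω absorbs whatever DNA-mediated
allostery or protein contact produces the coupling.

**Solver.** Given total concentrations (D_tot, S_tot, P_tot), the free DNA
concentration is eliminated in closed form from the DNA balance, leaving two
protein balances in the free concentrations [S] and [P]. Both residuals
change sign over the physical bracket [0, total], so the solver nests two
bracketed Brent root searches (inner: Pax balance at fixed [S]; outer: Sox
balance). This is derivative-free, needs no starting guess, and cannot leave
the physical region, at the cost of a few hundred function evaluations —
negligible at this problem size. Default relative tolerance 1e-10, iteration
cap 10 000; every accepted solution is re-validated against all three mass
balances. No trace-probe approximation is ever made: the experiments this
emulates deliberately use probe concentrations comparable to or exceeding
the protein concentrations, so the full system is always solved. The
two-probe variant shares one [S], [P] pool across two probes whose free DNA
concentrations are both eliminated in closed form; the same nested bracketing
applies unchanged.

**Units** are nM throughout; nothing converts units internally.

## The cooperativity statistic

A quantified gel lane gives the four band fractions (f_free, f_sox, f_pax,
f_dimer). The cooperativity estimate is the plug-in statistic

    ω̂ = (f_dimer · f_free) / (f_sox · f_pax)

For fractions generated by the model above this recovers the model's ω
*exactly*, for any totals — an algebraic identity, since the free-protein
concentrations cancel in the ratio of ratios. The identity is the package's
primary correctness oracle (tested across ω ∈ [0.1, 100] and random
parameter draws at relative tolerance 1e-6) and also makes ω̂ invariant to
lane exposure (any common scaling of the intensities cancels).

**Detectability.** The statistic blows up when a denominator band is faint.
Lanes with f_sox or f_pax below a threshold ε are flagged "monomer band
below detectability", and lanes with f_dimer < ε "ternary band barely
detectable"; flagged lanes are excluded from replicate summaries but never
silently dropped. Default ε = 0.01 (1% of lane signal) — a reproducible
encoding of "barely detectable" bands; configurable. A zero denominator at
ε = 0 yields a flagged infinite estimate, not an exception. "Negative
cooperativity" is reported as log2(ω) < 0, since a ratio of non-negative
fractions cannot be negative; both ω and log2(ω) are emitted.

**Replicates** are summarized by median and IQR (boxplot convention; the
noise model below is skewed, so the median is the honest center), with
mean ± sd alongside for barplot-style reporting. Whether published per-element
values are means or medians is generally unstated; this package uses medians.

## Kd fitting

Reduced-affinity variants are characterized by an 8-point titration fit of
the single-site isotherm bound = P/(P + Kd), least squares in log Kd
(Levenberg–Marquardt), under the trace-probe assumption that the protein
total approximates its free concentration. Requires ≥ 3 distinct
concentrations and non-degenerate bound fractions. At multiplicative noise
CV 0.05 the fit recovers Kd within 10% (simulation-calibrated).

## Synthetic gel lanes

`simulate_gel_replicates` solves the noise-free equilibrium once, then
multiplies each band fraction by an independent lognormal factor with
median 1 and coefficient of variation `noise_cv` (σ² = ln(1 + CV²), μ = 0).
Multiplicative noise reflects densitometry's intensity-proportional error;
median-1 factors make the ω̂ estimator median-unbiased (the ratio of four
equal-CV lognormals has median 1), which the suite verifies empirically at
2000 replicates for ω ∈ {1, 25, 50}. Default CV 0.1. What this generator
does *not* emulate: band-overlap cross-talk, background subtraction error,
gel-to-gel transfer efficiency, partial complex dissociation during
electrophoresis — so passing tests show estimator correctness under the
stated noise model, not robustness to every gel artifact.

## Element presets

Each preset fixes (K_S, K_P, ω) for one studied element class at the
standard 300/300/300 nM conditions:

| preset | ω | K_S (nM) | K_P (nM) | regime |
|---|---|---|---|---|
| DC5 | 25 | 100 | 1000 | cooperative, degenerate pax site |
| N3 | 50 | 100 | 1000 | cooperative, degenerate pax site |
| DC5con | 1 | 100 | 100 | additive, consensus pax site |
| LE9 | 0.2 | 1000 | 1000 | competitive, ternary band sub-threshold |
| spacer+1…+5 | 2 | 100 | 1000 | cooperativity collapsed ≥ 10-fold |
| spacer−1/−2 | 0.3 | 100 | 1000 | competitive (steric clash) |

The ω values encode the published qualitative regimes (cooperative 20–50,
additive ~1, collapsed spacers, competitive LE9). The absolute Kd values are
this package's own choices within a realistic 100–1000 nM band — no absolute
affinities were reported for these elements — and every preset's `note`
field says so. The degenerate-site presets use weak pax affinity (1000 nM)
and the consensus preset strong (100 nM), reflecting that the consensus site
is the high-affinity one. LE9 uses weak affinities on both sides so that its
ternary fraction at standard conditions (0.0082) falls below the 1%
detectability threshold, making its ω unquantifiable by construction — the
behaviour the preset exists to reproduce.

## Composite motif scanning

A composite motif is sox word + fixed gap + pax word, both degenerate IUPAC
words, required on the same strand in that order. Scanning semantics:

- Coordinates 0-based half-open internally; minus-strand hits are reported
  in forward-strand coordinates with a strand field. Hits sort by span,
  '+' before '−' at ties.
- "Flipped" motifs reverse-complement only the pax word (the construction
  used for flipped-consensus control elements); flipping twice is the
  identity.
- Matching is case-insensitive by default; `respect_mask` excludes
  soft-masked lowercase bases. Ambiguous sequence bases match by subset
  semantics (the base's IUPAC class must be contained in the word letter's).
- Negative gaps (overlapping half-sites) are construction-only and refused
  in scanning: overlapping arrangements abolish binding, so they are not a
  meaningful scanning state.
- The scanner is verified against an exhaustive position-by-position oracle
  on hundreds of random words/sequences and obeys strand symmetry (hits on
  the reverse complement are the mirrored hits with strands swapped).

The shipped default word set (`soxpax/data/dc5_words.yaml`) is a **synthetic
reconstruction**: the manually assembled words used in the original genomic
search were never published, so the packaged words are anchored only on the
DC5 architecture and labelled accordingly. Likewise the packaged DC5
half-site spans (`dc5_element.yaml`) are figure-derived annotations.

**Spacer variants** insert bases at the half-site junction (insert bases
must be supplied explicitly — the historically used inserts are not in the
main published record, so there is no silent default) or delete spacer bases
adjacent to the pax half-site, refusing to cut into a half-site; both
half-sites are preserved verbatim for every delta. **Switch mutants**
enumerate all consensus substitutions of a chosen position set up to a given
order, labelled consensus-base + 1-based position (T3, G8C9, T3G8C9, …).

## PFM information content

JASPAR-format PFMs are parsed (via Biopython, with validation) and scored
per position as IC = 2 − H(column) bits, after adding a pseudocount
(default 0.25 per base for real count matrices; use 0 for exact toy
arithmetic). Candidate switch positions are the 1-based positions where
IC ≥ threshold *and* the degenerate half-site differs from the PFM's
majority base (ties broken toward A<C<G<T order, documented, and irrelevant
for informative columns).

## Peak intersection

Co-bound regions are defined conservatively as the intersection spans of
every overlapping peak pair (≥ `min_overlap` bp, default 1), merged when the
spans themselves overlap — each reported region is a subset of both factors'
evidence. The union-of-pair convention would give larger regions; the
original convention is unstated, so the conservative choice is documented
here and implemented behind one function. Backed by pyranges; verified
against a quadratic all-pairs oracle on hundreds of random instances.
Chromosome names match by exact string equality unless `normalize_chr` is
requested.

## Chemical shift perturbation

Weighted CSP between two titration states: Δδ = sqrt(Δδ_H² + (0.1·Δδ_N)²),
with the nitrogen weight fixed at 0.1 (the 0.154 variant is *not* used;
the weight is configurable). Peak lists are matched by residue index;
residues present in only one state are carried with a missing status (they
are often the most interesting — exchange-broadened peaks), and the
classifier returns residues with weighted CSP strictly above the threshold
(default 0.1 ppm). Intensity/line-broadening analysis is out of scope: only
peak positions are modelled. The synthetic peak-list generator draws state-A
shifts uniformly from realistic amide ranges (¹H 6–10 ppm, ¹⁵N 100–135 ppm)
and adds specified per-residue deltas plus Gaussian jitter for state B; it
does not emulate peak overlap or missing assignments.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed and is fully
deterministic under it. The test suite's simulation sizes (≤ 2000 gel
replicates, 600-instance oracle sweeps, 100-region synthetic genomes) are
chosen to characterize the estimators' behaviour at desk scale; the
analysis drivers use 10 replicates per element — the replicate count typical
of the quantitative binding studies this emulates.

## Known limitations

- ω is a single scalar per element: no position-resolved energetics, no
  more-than-two-protein assemblies, no explicit DNA bending term.
- The Kd fit assumes trace probe; it is not valid for the probe-excess
  regime (use the full solver there).
- The scanner is consensus/degenerate-word based by design; probabilistic
  (log-odds) scoring of composite sites and de novo motif discovery are out
  of scope.
- All preset affinities and the default word set are synthetic stand-ins,
  as flagged above; conclusions about real elements require measured inputs.
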