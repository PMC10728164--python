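# Methods

This note records the models, conventions and numerical choices behind
`ntdms`, and what the synthetic-data suite does and does not establish.

## Mass conventions

Neutral proteoform mass = Σ residue masses + H₂O + Σ modification deltas +
adduct deltas. Residue and elemental masses come from pyteomics; the proton
mass is fixed at 1.007276 Da and the electron mass is neglected, consistent
with reporting nominal-Da molecular weights of large ions. Reported masses
are monoisotopic by default (the deconvolution assigns monoisotopic masses);
the average scale is available for cross-checks.

**Ca²⁺ adduct mass.** Two conventions are supported. The default is
*charge-displacement*: a bound divalent cation displaces two protons from
acidic side chains, so each Ca adds 39.96259 − 2 × 1.00728 = +37.94604 Da to
the neutral species. This is the physically appropriate picture for native
ESI of a folded acidic protein. *Neutral-addition* (+39.96259 Da) is a
configuration switch, and the active mode is carried in outputs. The printed
subunit masses of the troponin system do not unambiguously adjudicate the
convention, so both remain first-class.

**Numbering.** All residue positions use full UniProt numbering including
Met1. This is forced by self-consistency of the fragment indices on the
161-residue TnC chain (e.g. y₉₄ starting at residue 68, y₅₂ at 110). Met1
excision, when enabled, changes mass only — never reported indices.

**Truncations** are terminal only (e.g. C-terminal Lys loss); internal
deletions are out of scope.

**The 18,520 Da ejected-TnC mass.** No single combination of {Met1 excision,
N-terminal acetylation, 0–3 Ca in either adduct mode} on the P63316 chain
reproduces this printed value exactly (TnC + 3 Ca is 18,504.4 Da
monoisotopic / 18,516.2 Da average under charge displacement). The package
deliberately does not force agreement: `matching.nearest_candidate` reports
the closest composition and its signed ppm distance, and the matcher leaves
the species unassigned at assignment tolerance.

## Candidate grammars

A `CompositionGrammar` is a Cartesian product of per-subunit ranges
(phosphorylation count, Ca count, optional acetylation / Met excision /
named truncations). Enumeration is deduplicated and sorted
lexicographically by (phospho count, Ca count, flags), capped at 10⁵
species. Where a subunit's sequence is unavailable, a fixed-mass
pseudo-subunit carries the printed mass plus deltas; these stand-ins are
labelled synthetic in the fixture docstrings and contribute bookkeeping, not
sequence information. The packaged intact-complex composition list is
figure-derived (the four assigned heterotrimer compositions are itemized in
figure annotations, not running text) and is flagged as such in
`fixtures.intact_complex_species`.

## Isotope envelopes and deconvolution

Aggregated isotope distributions are computed by exact convolution of
per-element neutron-count distributions (exponentiation by squaring with
pruning at 10⁻¹² relative probability), tracking the abundance-weighted mean
mass per neutron bin, then truncated to a cumulative-probability target and
renormalized. For unknown compositions the averagine average-residue formula
(C₄.₉₃₈₄H₇.₇₅₈₃N₁.₃₅₇₇O₁.₄₇₇₃S₀.₀₄₁₇ per 111.1254 Da) is scaled to the
target mass and rounded; the constants are fixed so results are
bit-reproducible. During deconvolution, envelopes are cached on a 25 Da mass
grid — envelope shape varies negligibly over that scale and the cache keeps
the charge scan fast.

Deconvolution proceeds greedily from the most intense unassigned centroid
(profile data are first centroided by local maxima with 3-point parabolic
interpolation). For each candidate charge 1–30, peaks coherent with the
1.00235/z isotope grid are collected; candidate monoisotopic masses are slid
over a ±4-bin window around the envelope apex and scored by the cosine
(normalized dot product) between observed intensities and theoretical
probabilities. Species are accepted when they pass three thresholds with
defaults 0.4 / 3.0 / 500:

- **quality factor** — fraction of theoretical envelope peaks above 1%
  relative probability found in the spectrum (a declared surrogate; the
  vendor definition is proprietary and not claimed to be equivalent);
- **S/N** — peak height over 1.4826 × MAD of centroid intensities in a
  ±5 m/z window (the noise estimator is likewise unspecified upstream and is
  defined here explicitly);
- **intensity** — apex height in counts.

When two candidate monoisotopic masses score within 1% relative, the lower
mass wins and the species is flagged (`isotope-tie`) — the classic
off-by-one-isotope ambiguity resolved deterministically. Species whose
masses agree within 5 ppm across charge states are merged, summing
abundance. Low-level residual clusters (envelope tails under noise) that
pass the thresholds are reported as faithful threshold semantics; they
remain unassigned at candidate-matching tolerance and do not perturb
grouped quantification.

Tolerances for candidate matching default to 2 ppm for intact-complex
assignments, 16 ppm for monomer isolation spectra, and 20 ppm for fragment
ions, each overridable per run and echoed in outputs.

## Adduct localization

For the k-th adduct counted from the N-terminus, b-series evidence brackets
its position between the largest index still carrying k−1 adducts and the
smallest carrying k; y-series evidence does the same in C-terminal
coordinates given the species' total adduct count (taken from the evidence
maximum unless stated). The raw interval is the intersection; an empty
intersection raises a structured inconsistency error naming both intervals,
and adduct counts that decrease with index within a series are flagged and
rejected in strict mode. The trimmed interval clips the raw interval to its
first and last D/E residue — the side chains with the highest Ca²⁺ affinity
at neutral pH — and is returned untrimmed-flagged when the window contains
no acidic residue. Ordinals are positional; the energetic binding order
(domain III → IV → II for TnC) is separate metadata, since binding order and
chain order need not coincide. Only b/y ions are modelled (CAD); c/z ions
are out of scope. Bond j counts as cleaved when any matched b_j or y_{L−j}
exists; coverage is reported to 0.1%.

## Mason–Schamps conversion

CCS = (3/16)·√(2π/(μ k_B T))·z e/(N₀ K₀) with μ = mM/(m+M) in kg, K₀ in
m²/(V·s) (inputs in the TIMS-native 1/K₀, V·s/cm²), output in Å². N₀ is
fixed at the Loschmidt value 2.68678 × 10²⁵ m⁻³ consistent with the
*reduced*-mobility convention; supplying an instantaneous gas density is
deliberately unsupported to prevent double normalization. The drift-region
temperature defaults to 305 K — a typical trapped-ion-mobility drift
temperature, since source gas temperature is not the drift temperature — and
is configurable and recorded. Calibration against tune-mix ions and
structure-based theoretical CCS (projection-approximation methods) are out
of scope; the module consumes calibrated 1/K₀ values. At the anchor point
(77,136 Da, z = 20, N₂, 305 K, CCS 4880 Å²) the implied 1/K₀ is 1.218
V·s/cm², inside the typical 1.05–1.55 scan range — a useful dimensional
sanity check.

Mobilogram conformers are detected with scipy's prominence-filtered peak
finder (default prominence 5% of the maximum), apexes refined parabolically,
and shares computed as trapezoid areas between midpoints of adjacent apexes
so they sum to 1. Two Gaussians closer than the prominence threshold merge
into one reported conformer — a documented limitation of any
prominence-based detector.

## Synthetic data: what it does and does not show

Generators are pure functions of (config, seed). MS1 spectra place each
species' theoretical envelope at every charge of a discrete-Gaussian charge
envelope (defaults: 18–21 centred at 19 for the ~77 kDa complex, 6–8 for the
~18.4 kDa monomer), with Gaussian peak shapes set by resolving power
(default 150,000), additive baseline noise and multiplicative per-peak
scatter (defaults in study conditions: baseline σ 50 counts, CV 5%, total
intensity 10⁸). CAD MS2 generation cleaves each backbone bond independently
(Bernoulli at the stated efficiency) and applies position-faithful adduct
retention — a fragment carries exactly the adducts whose true residue lies
in its span, with an optional gas-phase loss probability (default 0).
Mobilograms are sums of Gaussians at the 1/K₀ implied by each conformer CCS.

These synthetics validate the *inference chain*: envelope fitting, charge
inference, mass assignment, interval algebra, conversion formulas. They do
not model FTICR line shapes, space charge, chemical noise, isotope fine
structure, adduct scrambling, or real gas-phase lability — so passing tests
demonstrate correctness of the algorithms under the stated generative
assumptions, not instrument-level performance on real data. Quantities from
the original experiments that depend on unprinted raw data (experimental
monomer/dimer CCS values, the ~63% cleavage map, sub-2-ppm assignment of
real spectra) are covered by generator-roundtrip property suites at matched
scale rather than by re-deriving the printed numbers.

## Problem sizes and determinism

The test suite runs mixtures of four ~18.4 kDa species over three charge
states (~5 × 10⁵ profile points) for deconvolution, 200 random
(sequence, site) draws of length 25–60 for localization soundness, and
4-level titration series for conformer monotonicity — sizes chosen so the
whole suite completes in well under a minute per stage on one CPU while
exercising every code path at realistic m/z scales. All stochastic tests and
`scripts/acceptance.py` derive every random stream from an explicit seed.
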