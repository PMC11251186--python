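# Methods

## The system

Human C4b-binding protein (C4BP) is a spider-shaped complement
inhibitor assembled from 6–8 α-chains and usually one β-chain,
disulfide-linked at a C-terminal oligomerization core.  The β-chain
binds protein S (ProS) non-covalently and with high affinity, coupling
complement regulation to coagulation.  The package's chain masses are
fixed at Mα = 72.9, Mβ = 40.7, MProS = 79.8 kDa — the unique least-squares
solution consistent with the four resolved complex peaks (α7β1 551,
α6β1 478, α7β1+ProS ≈ 631, α6β1+ProS ≈ 558 kDa).  The defining
analytical difficulty is that Mα ≈ MProS: all observed populations are
spaced ~80 kDa apart, so a native mass histogram cannot distinguish
α7β1 from α6β1+ProS.

## Single-particle calibration

CDMS ion events carry (m/z, normalized single-ion intensity).  Charge
is `factor_k × intensity` with factor_k = 14.713 (instrument
calibration constant), rounded half-up to an integer ≥ 1 by default —
physical charges are integral and rounding sharpens mass histograms;
rounding is configurable off since raw pipelines differ.  Mass follows
the positive-ionization identity M(Da) = z·(m/z − 1.007276).

MP contrasts are linear in mass.  The calibration line is fitted by
ordinary least squares to per-calibrant *median* contrasts (robust to
aberrant landing events) over a ladder of 73/149/483/800 kDa (or
335/670/1340 kDa for the high-mass instrument; the "670" value in the
source ladder listing carries an apparent typographical artifact and is
read as 670 kDa).  Events inverting to non-positive mass are dropped
and counted.

## Mixture deconvolution

Mass histograms are fitted with 1-D Gaussian mixtures by EM:
quantile-spaced mean initialization (deterministic), component SDs
floored at 1e−3 kDa, convergence at Δlog-likelihood < 1e−8 or 500
iterations, with a hard internal assertion that the log-likelihood
never decreases.  `k="auto"` scans k = 1…6 and takes the minimum BIC.
Two abundance readouts are computed per component: the raw mixture
weight, and an event-count weight (events hard-assigned by maximum
responsibility, restricted to ±2σ of the component mean, renormalized)
corresponding to quantifying by counting single-particle events per
population; they agree to well under a point on well-separated data and
the event-count variant is the default for occupancy inference.

### Occupancy inference

Native complexes above a 200 kDa floor (separating complexes from free
ProS; configurable) are fitted with k = 3, acidified complexes with
k = 2.  With native weights (a₁ heavy, a₂ middle, a₃ light) and
acidified heavy-component weight f₇:

    x = f₇ − a₁,   ProS-bound = 2a₁ + a₂ − f₇,   feasible iff 0 ≤ x ≤ a₂.

Infeasible inputs are clamped and flagged rather than rejected, since
sampling noise can push x marginally outside [0, a₂].  Because the
unconstrained k = 3 fit will split a real peak whenever one population
is nearly absent (occupancy near 0 or 1), fitted components are
anchored to the three expected population centers — m₆, the
overlap midpoint, m₇ + MProS, derived from the acidified means — by
nearest mean before weights are attributed.  In the normal regime the
mapping is one-to-one and changes nothing; at the extremes it keeps the
algebra consistent.

### Shift detection

Native and acidified components are paired greedily from the heaviest
native mean down, each taking the nearest remaining acidified mean
(ties toward the smaller shift).  Pairs shifted by MProS ± 15 kDa are
flagged as ProS dissociation.

## Stoichiometry assignment

Exhaustive enumeration over n_α ≤ 8 (admitting the historical 8-arm
hypothesis), n_β ≤ 1, n_ProS ≤ 1; candidates within 2σ of the observed
mass are ranked by |error|, ties broken by fewer subunits then label.
An assignment is *ambiguous* when ≥ 2 candidates survive — deliberately
not resolved by the code, because the α/ProS near-degeneracy is a fact
of the system, not a numerical artifact.  Glycan masses use dehydrated
monosaccharide residues (glycosidic-bond convention), with monoisotopic
and average values computed from elemental compositions (HexNAc
C₈H₁₃NO₅, Hex C₆H₁₀O₅, dHex C₆H₁₀O₄, NeuAc C₁₁H₁₇NO₈); peptide masses
come from pyteomics.

## Glyco profiling

Filters are strict inequalities as printed (score > 150,
|log prob| > 1.5); the log-probability column is treated as opaque.
Site numbering is taken verbatim from the input (precursor numbering);
no renumbering is attempted.  Dominant-glycoform ties resolve toward
higher sialylation, then lexicographically.  The > 20 % unoccupancy
flag is strict.

## Cross-link validation

Links are kept when score > 40 and identified in ≥ 2 of 3 replicates
(replicates counted as distinct ids among rows passing the score cut;
rows deduplicated by canonicalized endpoints + linker).  Distances are
Cα–Cα, minimized over all chain-copy pairings; self-links (same protein
and site on both ends) require two physical copies — with one copy they
are unmappable, never zero.  Alternative pairings within 2 Å of the
minimum are reported alongside it.  Overlength caps default to DSS
30 Å and DMTMM 25 Å Cα–Cα (community conventions; configurable and
always reported).  Linker chemistry (DSS K–K, DMTMM E/D–K) is checked
against residue types with warnings, not errors, since numbering
offsets are common.  Disulfide plausibility is Sγ–Sγ distance < 2.05 Å.

## Plasma stoichiometry

Each sample gets its own calibration: ordinary least squares of
log₁₀(MaxLFQ) on log₁₀(known concentration, g/L) over a 22-protein
reference panel (base-10 logs; ≥ 3 usable panel proteins required;
missing proteins excluded and logged).  Concentrations invert through
the fitted line and convert to molar with chain molecular weights
(defaults: the mechanistic chain masses).  Ratios are **molar** — a
mass-based α/β ratio would sit near 12–13 for α7β1 and could not match
the expected 6–7 band.  `in_expected_range` is 6 ≤ r ≤ 7;
`variation_flag` is r > 7.  CRP is reported alongside but never used as
a gate.  Unbound ProS is max(0, [ProS] − [C4BPβ]), assuming
ProS-saturated β-chains; negative intermediates are clamped and logged.
iBAQ purity profiles merge the C4 isotypes C4A + C4B as "C4b",
normalize to 100 % and report groups strictly above 1 %.  SEC profiles
sum triplicates per fraction, smooth with a centered window-3 rolling
mean (edges use the available fractions), and score co-elution by
Pearson correlation of the smoothed curves.

## Synthetic data: what it emulates and what it does not

Generators are bit-reproducible given (parameters, seed).

* **Observed presets** encode the resolved population means/SDs:
  native CDMS (633 ± 22, 553 ± 20, 481 ± 20 kDa), acidified CDMS
  (551 ± 22, 478 ± 23, free ProS 80 ± 6), native MP (630 ± 29, 553 ± 22,
  487 ± 22, free ProS 68 ± 9).  Native weights (0.374, 0.482, 0.144)
  follow from the occupancy algebra at f₇ = 0.55, q = 0.68 — f₇ is not
  directly observable and was chosen so the inferred ProS-bound
  fraction is the 68 % reported by CDMS.  The acidified free-ProS event
  fraction q/(1+q) ≈ 0.405 follows from each bound particle emitting
  one extra event on dissociation; the MP free-ProS weight (0.05)
  represents the small unbound-ProS population that technique resolves.
* **The mechanistic preset** draws latent particles: α7 with
  probability f₇ = 0.55, ProS bound with probability q = 0.68, complex
  mass ~ Normal at the chain-arithmetic mean, ProS part ~ N(79.8, 6),
  total species SD 20 kDa.  Acidification re-draws the same latent
  population (same seed) and splits every bound particle into complex +
  free ProS, with a detection-efficiency parameter (default 1.0) for
  the low-mass channel.
* **Ionization** uses a Rayleigh-limit-like charge model z̄ = c·√(M Da)
  with c = 0.1 and σ_z = 2 — any positive mass-monotone model serves,
  since the inversion only needs the recorded intensity; intensity
  noise is Gaussian with σ = 0.05 charge equivalents.  With both noises
  zero the calibration chain inverts events exactly (< 1e−9 relative).
* **Glyco PSMs** draw per-site compositions from fixed categoricals
  (biantennary HexNAc4Hex5NeuAc1/2-dominated everywhere; triantennary
  HexNAc5Hex6NeuAc2/3 at ProS N509) over the 11-site panel (C4BPα
  N221/N506/N528, C4BPβ N64/N71/N98/N117/N154, ProS N499/N509/N530),
  with 25 % unoccupancy at N221/N528/N71 and 5 % elsewhere.
* **The plasma cohort** simulates equimolar α6β1+ProS and α7β1+ProS at
  0.175 µM each (healthy; molar α/β exactly 6.5), constant free ProS at
  0.12 µM, acute timepoints replacing half the complexes with 7α and
  spiking CRP, and a log-linear LFQ response with slope 1 and σ = 0.05
  decades.  The 22 reference-panel concentrations are synthetic,
  literature-plausible values; real analyses must supply the reported
  ones.

Not emulated: instrument transients and peak-shape asymmetry, mass
drift, charge-state artifacts, glycan micro-heterogeneity beyond
categorical compositions, inter-donor biological variation beyond the
scenario switch, and label-free quantification biases (shared peptides,
missingness mechanisms).  Passing tests therefore demonstrate that the
inversion chain is correct under the stated statistical assumptions,
not that those assumptions hold for any particular instrument.

## Numerical choices and problem sizes

Event counts default to 5000 per single-particle experiment and 200
PSMs per glycosite — enough that binomial sampling error (~0.7 points
on a weight at n = 5000) sits well inside the reported tolerances while
keeping the full suite and the acceptance script in seconds.  EM is
deterministic given the event set; the only seeds are the generators'.
Ties anywhere (assignment ranking, dominant glycoforms, shift pairing)
break deterministically as described above.

## Known limitations

* The occupancy algebra assumes exactly three native and two acidified
  complex populations; substantial 7α or α8 content in a native sample
  would violate it (the feasibility flag catches gross violations).
* Low-mass (free ProS) quantification is intrinsically less reliable on
  both CDMS and MP; the monomer fit is kept separate from the complex
  fits and never enters the occupancy algebra.
* Whether the molar or mass concentration ratio was intended by the
  6–7 band is not stated in the source material; molar is adopted here
  for the consistency argument given above.
* Cross-link overlength caps are conventions, not measurements; the
  2 Å alternate window is applied per link.
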