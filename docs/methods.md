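# Methods

## Mass model

All masses are monoisotopic, computed from a fixed internal atomic-mass
table (C 12.000000, H 1.0078250319, O 15.9949146, N 14.0030740,
P 30.9737615, ¹³C 13.0033548, ²H 2.0141018); anion m/z is neutral mass
minus the proton mass 1.007276 (electron included), which reproduces
the instrument-method display values (283.26 for deprotonated FA 18:0,
297.24 for the FA 18:1 epoxide, and so on) on half-up rounding to two
decimals. Free fatty acids are CnH(2n−2d)O₂; diacyl glycerophospholipids
are assembled as glycerol-3-phosphate + head-group alcohol + two fatty
acids minus one water per condensation, which matches an independent
atom-by-atom bond-graph enumeration (tests/oracle.py) and pyteomics'
NIST masses to < 1e−4 Th across the supported space.

Negative-mode PC is modeled as the demethylated [M−CH₃]⁻ anion and
flagged experimental; acetate adducts and positive-mode chemistry are
out of scope. Glycerophospholipid diagnostic pairs apply the neutral
loss to the intact deprotonated epoxide (charge stays with the head
group); a switch computes the pair on the released epoxy-fatty-acylate
instead.

## Fragmentation rule and isotope labels

Mono-epoxidation adds one oxygen regardless of which bond reacts and of
geometry. For an epoxide at Δn on an N-carbon chain the aldehyde ion is
the precursor minus the neutral alkene C_m H_{2m−2d'} (m = N − n, d' =
distal double bonds); the alkene ion is the aldehyde minus one oxygen.
Mass conservation (aldehyde + lost neutral = precursor) and the 16-Da
pair spacing hold exactly by construction and are asserted property-wise.
Polyunsaturated species get one mono-epoxide channel per bond;
di-epoxide products are not modeled.

Isotope labels carry an optional carbon-position set. A label whose
positions lie entirely on the carboxylate side of the cleavage shifts
both fragments; entirely distal labels leave with the neutral; a set
that straddles the cleavage (or an unpositioned label on the cleaved
chain) raises rather than guessing — the ¹³C₅ tracer, whose printed
m/z 190 diagnostic implies all five labels within C1–C10, must be given
explicit positions (`[13C5@1-10]`). No natural-abundance isotope
correction is applied to M+n fractions.

## Chromatogram processing

Retention times are minutes everywhere (seconds converted on read).
Defaults follow the instrument classes of the emulated acquisition:
MS1 extraction ±10 ppm (Orbitrap-class survey scans), MS2 ±0.3 Th
(ion-trap fragments), isolation width 2.0 Th. Peak detection smooths
with a 5-scan moving average, thresholds local maxima at median + 3·MAD
of the trace (anything above zero on a noiseless trace), walks
boundaries to flanking minima or baseline, requires ≥4 points, and
integrates trapezoidally on the raw trace. Aldehyde and alkene peaks
are paired greedily by nearest apex within 0.1 min — tight enough to
separate isomer peaks (adjacent positions are ≥0.3 min apart under the
default RT law) while tolerating scan-grid jitter; candidate pairs are
consumed in distance order, making the matching symmetric. Unmatched
singletons are reported and excluded from confident assignments.

mzML is read and written by the package itself: the writer emits plain
mzML 1.1 with uncompressed 64-bit base64 arrays and the controlled
vocabulary needed for scan routing; the reader (stdlib XML) handles
that subset plus 32-bit and zlib-compressed arrays. Identical inputs
yield byte-identical files, which the determinism tests rely on.

## Position and geometry assignment

Position needs no model: each Δ has a unique pair m/z, so the targeted
search queries every channel of the target (for sum-composition
monounsaturated targets such as "FA 18:1", candidate channels Δ2..Δn−2
are scanned; unannotated polyunsaturated targets are refused since
their enumeration is combinatorial). Geometry uses the retention-time
index: ordinary least squares RT = slope·Δ + intercept per (class,
chain length, bond count, geometry) series, requiring ≥2 distinct Δ.
Inverting the fit snaps to the nearest integer Δ; a residual above 40%
of |slope| — the natural midline between adjacent positions — flags the
snap as ambiguous. Models are not extrapolated more than 3 Δ units past
their fitted range.

Elution order alone ("cis before trans") is trusted only when exactly
two events share a pair m/z; single events stay unknown unless an RT
model places them on the Z or E line within threshold, and with more
than two events only model proximity is used, never order. Unresolvable
cases are labeled unknown rather than guessed.

## Quantification

Isomer fraction = (aldehyde + alkene pair area of the isomer) / (summed
pair areas of all isomers of the species); a flag restricts to
aldehyde-only. Response factors are assumed equal across isomers —
supported by the calibration slope ≈ 1 — with a per-isomer override
table. Calibration fits area fraction (%) against molar E fraction (%)
by OLS on replicate means (per-replicate fitting optional). Tracer
enrichment is the label-shifted-over-total pair-area fraction, and
abundances are normalized per time point to a co-spiked deuterated
internal standard; a missing or zero standard raises rather than
silently passing unnormalized values.

## Synthetic data

The simulator is the test bed standing in for instrument runs. It
emulates the targeted acquisition — interleaved MS1 and per-channel MS2
scan grids (2.4 s intervals, phase-offset channels), Gaussian peaks of
σ = 3 s, apexes on the linear RT law (default slope −0.30 min/Δ,
intercept 18.0 min so Δ9 elutes mid-window, trans offset +0.6 min —
plumbing values chosen for sign and ordering realism, not read from any
instrument), diagnostic pairs at exactly computed m/z split 60:40
aldehyde:alkene, per-isomer molar fractions and response factors,
multiplicative log-normal amplitude noise, Poisson baseline, ppm-scale
m/z jitter — all driven by one recorded seed. The default standard
panel holds 14 monounsaturated isomers across FA 16:1/18:1/20:1
channels; the calibration series uses the five molar ratios 99/90/50/
10/1% E at 1% noise in triplicate; the tracer time course converts a
¹³C₁-labeled 9Z pool to labeled 10E at a fixed fraction per sampling
interval over 0/5/10/24 h with a d17 internal standard (deuteriums on
the methyl-side segment, so its diagnostic pair is unshifted but its
precursor channel is distinct).

Residual underivatized parents appear at MS1 level one oxygen below the
epoxide precursor, eluting 1.5 min later by default — epoxidation lowers
hydrophobicity, so derivatized peaks lead their parents. What the
simulator does not emulate: peak tailing and overlap, retention drift
between runs, full isotopologue envelopes (only labeled/unlabeled
channels), chimeric MS2 background, and detector saturation. Passing tests therefore demonstrate correctness of
the arithmetic, signal processing, assignment logic and statistics under
clean-to-moderately-noisy conditions, not robustness to pathological
chromatography.

## Numerical choices and problem sizes

Simulated windows span 12–19 min (≈175 scans per channel), sized so
every default-panel peak is fully contained; trapezoidal quadrature on
the 2.4 s grid recovers Gaussian areas to ≪0.5%. The acceptance script
sweeps all methylene-interrupted FA channels for 14–22 carbons and 1–3
bonds (540 channels) and one calibration series of 15 measurements —
sizes chosen so the whole sweep runs in seconds while covering the full
supported mass space. Ties in peak pairing resolve by apex distance
then list order; zero-slope RT models, empty compositions, saturated
species, all-zero area vectors and missing internal standards raise
typed errors. Known limitations: geometry calls inherit any RT-index
misfit; PC handling is experimental; sn-position assignment and
di-epoxides of polyunsaturated lipids are out of scope.
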