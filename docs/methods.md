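# Methods

## The analysis in brief

Phycobiliproteins assemble from αβ dimer building blocks into (αβ)₃
hexamers.  In native electrospray mass spectra each complex appears as a
charge-state envelope — a series of peaks at m/z = (M + z·m_p)/z for
consecutive integer proton counts z (m_p = 1.00728 Da).  The analysis
answers two questions: *which* dimer compositions (pure or heterologous,
i.e. mixing strains within a family) are present in a spectrum, and *how
conserved* are the residues at the dimer–dimer contact interfaces that
make such mixing possible within a family but forbid it between
allophycocyanin (APC) and phycocyanin (PC).

## Proteoform masses

Subunit neutral masses are average (not monoisotopic) masses: at the
simulated resolving power (7500 FWHM at m/z 400) a ~110 kDa complex shows
only its average-mass envelope.  The residue-chain mass is the sum of
standard average residue masses plus one water (18.0153 Da), accumulated
with compensated summation so the result is independent of order to below
1 µDa.  Family/chain PTM rules then add:

| family/chain | phycocyanobilins (+586.7 Da each) | methylations (+14 Da) | initiator Met (−131.2 Da) |
|---|---|---|---|
| APC α (and the ApcD-type αB) | 1 | 0 | always lost |
| APC β | 1 | 1 | retained |
| PC α | 1 | 0 | retained |
| PC β | 2 | 1 | 0–1 losses, both proteoforms present |

The αB rule is not separately specified anywhere authoritative; mirroring
the APC α rule is this package's declared default (configurable by passing
an explicit rule).  The methylation is applied as the nominal +14.0 Da; all
mass constants live in `MassConstants` and can be overridden from JSON.

A non-covalent complex carries exactly the sum of its subunit proteoform
masses.  Variable Met loss on PC β makes a PC dimer a 2-mass and a PC
hexamer a 4-mass ladder with 131.2 Da spacing; distinct compositions are
enumerated as multisets of dimer units (hexamer = 3 units, fixed), so k
strains give C(k+n−1, n) compositions of n dimers.  Decoy compositions —
hexamers mixing APC and PC units, and αβ dimers pairing the α of one
strain with the β of another — are generated with the same machinery,
flagged, and matched identically; they are the negative controls for the
experimental observations that neither cross-family hexamers nor
cross-strain dimers occur.

## Spectrum simulation

The synthetic instrument renders profile spectra on a uniform m/z grid
(default 0.25 m/z over 1000–8000) with Gaussian peaks of FWHM = m/z / R,
R = 7500·√(400 / m/z) — the square-root resolution decay of an Orbitrap
from its reference point.  Charge envelopes are discrete Gaussians in z
centred on the native-ESI scaling z₀ = 0.078·√M (configurable scale and
width, default width 1.5 charges, truncated at ±4 widths and at the m/z
window).  Peak area is abundance × envelope weight, so total integrated
signal equals total normalized abundance.  Baseline noise is seeded
Gaussian, relative to the tallest peak, clipped at zero.  A spectrum is a
pure function of (mixture, instrument model, seed).

Strain families are generated by per-site substitution of fixed synthetic
base sequences (invented sequences with typical phycobiliprotein lengths
and residue composition; they are not the sequences of any organism) at a
given divergence, keeping position 1 (the initiator Met) fixed.  With
`min_relative_gap` set, strain sets are redrawn until every pair of
distinct candidate species — all compositions, all Met-loss variants,
decoys included — differs in mass by at least that fraction.  The default
study value, 0.001, is the assignment criterion itself: it defines the
regime in which composition assignment is well-posed, and implies spectral
resolvability too (the mass-domain FWHM at hexamer charges is ≈0.05% of
mass).  Cross-family decoy masses form a near-continuum between the APC
and PC hexamer blocks, so they are only required to stay a quarter of the
gap (tens of daltons, several times the instrument's mass precision) away
from genuine masses.  Strain pairs whose complexes coincide in mass are
real — they are the genuinely ambiguous case, which the assignment stage
reports as such rather than resolving.

What the simulator deliberately does *not* emulate: isotope structure,
adduction (ammonium acetate adducts), in-source dissociation, detector
saturation, ionization-efficiency differences between species, and
chemical (non-white) baseline.  Passing the recovery study therefore
shows the combinatorial assignment logic and the quantification are
correct under idealized peak shapes, not that the pipeline is robust to
every artifact of real spectra.

## Deconvolution

Peak picking detects local maxima on a lightly Savitzky–Golay-smoothed
trace (window 7 points, quadratic; baseline-noise ripple otherwise
fragments low peaks into several maxima) against a floor of
`snr_threshold` × a robust noise scale (median nonzero first difference of
the raw profile, calibrated for a zero-clipped Gaussian baseline, scaled
by the filter's variance reduction).  Position and area are then measured
on the *raw* profile by a weighted least-squares log-parabola over the
apex neighbourhood — the log of a Gaussian is exactly quadratic at any
sampling density, so this is unbiased for both the ~3-point-per-FWHM dimer
region and the ~9-point hexamer region, while inverse-variance weights
average the noise.  Half-max-crossing and watershed estimates serve as
fallbacks for degenerate apexes.

Charge-series inference turns every (centroid, z) pair in the charge range
into a neutral-mass hypothesis M = z·(m/z − m_p), single-links hypotheses
within `cluster_tol_ppm` (default 50 ppm), and accepts clusters greedily by
(distinct-charge support, intensity), each centroid backing at most one
series.  Two guards handle the harmonic degeneracy of charge envelopes —
a species at M produces *exact* ghost clusters at k·M (from charges k·z)
and at M/k (from its charges divisible by k; a hexamer is exactly three
dimer masses, so its M/3 image lands on the genuine dimer cluster):

1. eligibility requires at least `min_states` *consecutive* charges —
   super-harmonic ghosts arrive with charge gaps of k;
2. hypotheses are dropped when their charge is further than 4.5 from the
   ESI expectation 0.078·√M — sub-harmonic images sit at k-fold-off
   charges (disable with `envelope_z_window=None` for non-native data).

After acceptance, members deviating more than 25 ppm from the series
median are discarded (and consumed): peaks shifted by overlap with another
species carry corrupted positions and areas, and the envelope fit bridges
the missing charge.  The series mass is the intensity-weighted mean of the
remaining hypotheses.

## Assignment and quantification

A series matches every candidate whose percent mass error,
100·|M_obs − M_theo|/M_theo, is at or below the criterion (0.1% default).
Exactly one sub-criterion candidate → *unique*; several → *ambiguous*
(surfaced, never collapsed — with a 131.2 Da Met ladder on a ~110 kDa
hexamer, some cross-composition variant pairs are always within 0.1%);
none → *unassigned*.

For abundances, each series' intensity is the integral of a robustly
fitted charge envelope (log-parabola over the detected (z, area) profile,
members off by more than ×1.8 dropped and refit): the detection threshold
truncates a weak species' envelope asymmetrically relative to a strong
one, and the fitted integral is threshold-independent.  The raw summed
centroid intensity is retained (`intensity_mode="summed"`, and always in
`ChargeSeries.intensity_sum`).  Ambiguous intensity is divided by a
Gaussian likelihood of the mass error at instrument precision
(`mass_sigma_ppm`, default 50 ppm) — deconvolved masses are ppm-precise,
so candidates tens of daltons away receive essentially nothing while the
ambiguity itself remains on record; an equal-share split is available.
Relative abundance is the intensity share within each family (decoys
excluded and reported separately); the dimer:hexamer ratio is
100 × dimer/hexamer intensity per family, NaN when no hexamer was
assigned.  No ionization-efficiency correction is applied.

The UV-vis check is the linear-mixing prediction: a 1:1 mixture's
absorbance profile should equal the pointwise mean of the component
profiles; the function reports the RMS deviation of a measured mixture
from that prediction.

## Recovery study (the central validation)

50 seeded simulations: two strains per family at 5% divergence
(resolvable per the gap rule above), the four hexamer compositions per
family at uniform random weights plus 5% total dimers, one spectrum per
family (as when purified complexes are mixed; overlaying both families
stacks the APC z≈26 and PC z≈27–28 envelopes on the same m/z range),
baseline noise 0.2% of the tallest peak, picking at 4× the noise floor.
The noise level sits inside the ≤1% study envelope at a point where the
weakest reportable composition — 2% of a family, split over four Met
variants — still yields peaks at usable SNR; at 1% noise such peaks are
at SNR ≈ 1 and no method could recover them.  Every composition with
≥2% true weight must be recovered within ±20% relative abundance, and
decoys must collect <1% of assigned intensity.  Across 110 independent
master seeds during development the worst observed relative error was
3.6–8.6% (median below 1%) with decoy intensity indistinguishable from
zero; `scripts/acceptance.py` re-measures this for any seed.

## Interface conservation

Contacts are residue pairs from different αβ dimer groups with minimum
heavy-atom distance ≤ 3.0 Å (inclusive; hydrogens excluded; non-amino-acid
residues excluded by default since predicted models carry no bilins),
computed with a k-d tree and reported once per pair in canonical order.
Interface confidence averages PAE over both orientations of every
cross-group interface residue pair and pLDDT (read from the B-factor
column, the predictor convention) over the interface residues.  PAE JSON
is accepted in the matrix, wrapped-list and flat paired-list dialects.

Sequence conservation is mean pairwise identity per alignment column over
non-gap residues (gaps excluded pairwise), and similarity the same count
with matches extended to a physicochemical partition — default
{GAVLI}, {FYW}, {CM}, {ST}, {KRH}, {DENQ}, {P}, explicitly configurable
since no single grouping is canonical; a modal-frequency mode exists for
sensitivity analysis.  Columns and unaligned positions are 1-based;
`map_position` and `position_to_column` convert between them.
`derive_interface_columns` composes contacts → interface residues →
column map, after verifying residue-by-residue that each chain's sequence
equals its alignment row.

## Numerical choices and limitations

- Theoretical masses closer than 1 µDa are merged as one species;
  degenerate candidates above that are retained and left to the
  ambiguity machinery.
- The ESI plausibility window assumes native-like charging; strongly
  supercharged or charge-reduced spectra need the window widened or
  disabled.
- The envelope-fit intensity assumes a unimodal (Gaussian-like) charge
  envelope; bimodal envelopes (coexisting conformers) would be split into
  separate series only if their charge ranges are disjoint.
- Equal splitting of a composition's weight across its Met-loss variants
  in the simulator is a convention; real Met-processing stoichiometry
  varies.
- The pipeline consumes predicted structures and their confidence files;
  it does not run structure prediction, build alignments, or infer trees.
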