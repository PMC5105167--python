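# Methods

## Proteoform model

A glycoprotein is modelled as a polypeptide backbone plus `n` independent
modification sites. The independence assumption — the isoform chosen at
one site does not condition the isoform at another — is what lets the
site-level data predict the intact-protein distribution; it is also the
model's main simplification, since real glycan processing can be
correlated across sites. Under it, proteoform masses are sums of per-site
deltas and proteoform probabilities are products of per-site normalized
abundances. Abundances enter as raw XIC areas and are normalized per site
(`P_ij = A_ij / Σ_j' A_ij'`); a site whose areas are all zero is an error,
not a silent uniform.

The zero-charge spectrum is computed either by exhaustive enumeration of
all isoform combinations (exact, capped at 2×10⁶ combinations) or by
iterated per-site convolution, which merges isobaric intermediates after
every site and therefore scales to properdin-like proteins (17 binary
C-mannosylation sites, four O-sites, one N-site ≈ 4×10⁷ combinations
collapsing to a few hundred resolved masses). The two routes agree to
1e-9 on every enumerable model; this equivalence is a standing test.

Merging uses a tolerance of 0.01 Da by default — far below native-MS peak
widths, so it only collapses positional isomers and float-level
duplicates, at the probability-weighted mean mass. Pruning (default 1e-8)
drops negligible proteoforms during convolution; the surviving probability
mass is reported as `retained_probability` and is deliberately *not*
renormalized, so conservation losses stay visible.

Backbone masses come from the amino-acid sequence via average atomic
masses (pyteomics), minus two hydrogen atoms (2 × 1.00794 Da) per
disulfide bridge. For the stored mature des-Arg166 erythropoietin chain
(UniProt P01588, residues 28–192, two disulfides) this gives 18,235.73 Da,
within 0.3 Da of the conventionally quoted 18,235.99 Da; the difference
reflects slightly different average-mass element tables and is negligible
at native-MS accuracy (~16 ppm ≈ 0.5 Da at 30 kDa).

## Residue masses and composition algebra

All PTM arithmetic uses average residue masses (Hex 162.1424, HexNAc
203.1950, dHex 146.1430, Neu5Ac 291.2579, Neu5Gc 307.2573, Pho 79.9799,
Acetyl 42.0373, Hydroxyl 15.9994 Da), since intact-glycoprotein peaks are
isotopically unresolved centroids. Neu5Gc can be written either as its own
block or as Neu5Ac + Hydroxyl — the masses coincide exactly by
construction, and both encodings parse. Acetyl (+42 Da) and Hydroxyl
(+16 Da) are counted as separate blocks attachable on top of sialic acids,
matching how the satellite peaks are annotated in site tables. The table
is overridable from a two-column text file (e.g. for monoisotopic
variants).

## In-silico enzymes

* **Sialidase** zeroes Neu5Ac/Neu5Gc counts — and the Acetyl/Hydroxyl
  decorations that ride on them — in every composition isoform, merging
  isoforms that become identical. Raw-mass isoforms carry no composition
  to edit and pass through with a warning.
* **PNGase F** collapses every N-site. Because enzymatic release converts
  the glycosylated Asn to Asp, each *occupied* isoform leaves a +0.9840 Da
  scar by default (switchable off, as annotation pipelines differ on
  whether they fold this in); a partially occupied site thus becomes a
  0 / +0.9840 Da mixture weighted by occupancy rather than a single clean
  state.

## Projection and peak shapes

m/z values use the proton mass 1.007276 Da (the actual ESI charge
carrier, not the hydrogen atom — a 0.0007 Da distinction that is
irrelevant at native accuracy but fixed for reproducibility). The default
charge envelope for ~30 kDa glycoproteins is 8+, 9+, 10+ with uniform
weights; envelope weights can instead be estimated from an experimental
spectrum by summing intensity over each charge state's m/z window.
Profile rendering gives each stick a Gaussian of FWHM = (m/z)/R(m/z) with
R(m/z) = R_ref·(mz_ref/mz)^0.5 (Orbitrap-like; R_ref = 17,500 at m/z 200,
exponent overridable since only the reference resolution is ever quoted
for an instrument). Gaussians are area-normalized and evaluated on a
uniform grid of step ≤ FWHM/4 (default FWHM/6; coarser requests are
refined with a warning), conserving total area to well under 0.1%.
Isotope fine structure is out of scope by design: average masses
throughout.

## Similarity scoring

Spectra are compared over the *intersection* of their m/z ranges, binned
on a shared grid (origin = floor of the range start, left-closed
right-open bins); zero-filling beyond either spectrum's data is refused
because shared padding zeros inflate r. Pearson r is computed on the
paired bin vectors; a zero-variance vector raises an error rather than
returning NaN or 0. Profile spectra are binned directly; centroids are
binned as sticks; peak picking for pair matching takes local maxima above
1% of the base peak.

The bin width is selected from the data: the top 20 peak pairs (greedy
nearest-neighbour matching, ranked by summed intensity) are projected to
three charge states, giving per pair and charge a candidate width
W = 2·|ΔM|/z — the smallest width that guarantees the pair lands in one
bin at the worst-case bin phase. With 20 pairs × 3 charges there are
exactly 60 candidates, and their median is the working width (floored at
a configured minimum, 1 Th, which is also returned for identical spectra
where every Δ is zero). The factor 2 is this package's explicit
interpretation of the co-binning requirement; |ΔM|/z is available as an
alternative rule. The selector takes zero-charge (mass-domain) peak
lists, since pair mass differences are charge-independent there and
project cleanly to any charge state.

Verification scans r over widths 1–20 Th in 0.1 steps (191 points),
smooths with LOESS (span 0.3 — no span is standard, this one tracks the
knee without chasing noise), and reports the maximum-curvature point of
the smoothed curve via second differences. A flat scan (identical
spectra) is flagged instead of yielding a spurious inflection.

## Composition assignment

A measured intact mass is explained as backbone + Σ count·residue mass by
depth-first search over building blocks in descending mass order with
remaining-mass pruning — exact and complete with respect to the count
bounds (verified against brute-force enumeration). Default bounds
(Hex ≤ 30, HexNAc ≤ 25, Fuc ≤ 6, Sia ≤ 20, Acetyl ≤ 4, Hydroxyl ≤ 4,
Pho ≤ 2) cover an rhEPO-scale protein; the default tolerance of 50 ppm
leaves headroom over the ~16 ppm agreement typical of the modal peak.
Candidates are ranked by |ppm error| (rounded to 1e-6 ppm so exactly
isobaric candidates — Hex vs Fuc+Hydroxyl, Neu5Gc vs Neu5Ac+Hydroxyl —
compare as ties), then by total residue count, then lexicographically;
co-ranked isobars are all returned, never silently resolved.

At realistic tolerances the unconstrained search returns many isobaric
count tuples closer to the measured mass than the biologically correct
one — mass alone cannot rank them. Two optional structural constraints
encode what site-level data licenses: Acetyl+Hydroxyl ≤ sialic acids
(these decorations sit on sialic acids; on by default), and
Hex − HexNAc = number of occupied complex N-glycosylation sites (each
complex N-glycan contributes one more Hex than HexNAc and a core-1
O-glycan contributes equally; off by default, preset for rhEPO). With the
rhEPO preset both reference peaks rank top-1.

Per-peak annotation of a zero-charge spectrum also reports adjacent-peak
mass deltas against single residue masses, flagging e.g. the 162.14 Da
hexose ladders that betray variable C-mannosylation occupancy.

## Synthetic data

The generator emulates what middle-down glycoproteomics delivers, at the
scale of the studied proteins: N-sites carry distinct complex N-glycans
(Man₃GlcNAc₂ core + 2–4 LacNAc antennae, 0–1 core fucose, sialylation
never exceeding the antenna count), O-sites carry a core-1 series with
0–2 sialic acids plus the unoccupied state, C-mannosylation sites are
binary Hex/unoccupied with occupancies drawn from 0.3–1.0. Site
abundances are Dirichlet(1) — uniform over the simplex, imposing no
favoured glycoform. The rhEPO preset has 10/9/8 N-glycoforms on its three
N-sites and an O-site, matching the site-table sizes of the real protein;
the properdin preset has 17 C + 4 O + 1 N sites on a ~46 kDa backbone.

Measurement noise on simulated spectra is multiplicative log-normal
intensity scatter (heteroscedastic and positive, like real peak areas;
parameterized by CV), Gaussian ppm-scaled m/z jitter (mass-accuracy-like),
per-peak dropout, and a flat baseline fraction. Noise acts on the
centroid sticks before profile rendering, and the rendering grid is
anchored to the noise-free construction so a zero-noise simulation is
bit-identical to it. Everything is deterministic in the seed.

`perturb_sialylation` builds a "different product, same repertoire"
counterpart: within each group of isoforms sharing a desialylated core,
abundance is reallocated by log-normal factors (σ = strength × Sia count)
and the group total is preserved. Desialylating both models therefore
removes the disagreement exactly — the construction used to test that
in-silico sialidase raises the correlation, mirroring the behaviour of
sialidase-treated product comparisons.

What passing these tests does *not* show: agreement with real instrument
data. The generator has no chemical noise, adducts, charge-state bias
against sialylation, deconvolution artifacts, or cross-site correlation;
correlations against real native spectra will be lower than the synthetic
ones, and validating against the original raw spectra would require data
not distributable with this package.

## Problem sizes and numerical choices

Test and acceptance runs use the rhEPO-scale preset (2,160 combinations,
~270 resolved masses, ~18,000 profile points), 200 random ≤6-site models
for the convolution oracle, 20 seeds per stochastic claim, and 40 planted
assignment queries — sizes chosen so the full suite runs in well under a
minute while every claim is still exercised end to end. Scoring in these
runs uses a fixed 2 Th bin width (comfortably above the rendered peak
widths, below the peak spacing). Ties in peak merging break toward the
probability-weighted mean; empty spectra and empty compositions are legal
identities everywhere; every error path (degenerate site, zero-variance
correlation, unknown residue, malformed file row) raises a typed,
located exception rather than propagating NaNs.
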