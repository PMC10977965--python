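# Methods

## Exchange model

Backbone amide exchange is simulated in the EX2 limit only: the observed
rate of each residue is `k_obs = k_int / PF` with protection factor
`PF ≥ 1`, and deuterium occupancy after labeling time `t` is
`f_D2O · (1 − exp(−k_obs t))`. EX2 is the standard interpretive regime for
native-state HX; EX1 correlated exchange (bimodal envelopes) is out of
scope. Prolines and each chain's first residue carry no exchangeable amide
deuterium (`k_int = 0` there).

Two intrinsic-rate models are exposed and recorded in output metadata:

- `uniform` (default, used throughout the tests): every competent amide
  exchanges at 0.01 /s at pD 7.5, 298 K — chosen so an unprotected residue
  is ~63% exchanged at the 100 s timepoint, the midpoint of the
  experimental series — scaled as 10^(pD−7.5) and by an Arrhenius factor
  (Ea = 17 kcal/mol). Uniform rates make peptide sums single-exponential
  and every downstream quantity analytic, which is what the oracle tests
  exploit.
- `neighbor`: the empirical poly-alanine-referenced scheme with acid, base
  and water catalysis, side-chain neighbor factors, and per-pathway
  activation energies (14/17/19 kcal/mol). The coefficient table follows
  the values commonly distributed with HX analysis tools and is
  approximate; since all reported quantities are normalized to a measured
  FD reference, absolute intrinsic rates never reach any output. Only
  structural properties of this mode (positivity, proline/first-residue
  zeros, determinism, pD direction) are asserted.

## Synthetic experiment (the simulator's stated world)

Defaults mirror the experimental design the pipeline targets: two states
(`free`, `droplet`); timepoints 10, 100, 300, 1000, 3000 s; triplicates;
f_D2O = 0.75; a full-deuteration reference per peptide; Gaussian noise of
0.05 deuterons (sd) on peptide deuteron counts, truncated at zero;
per-peptide back exchange drawn once from uniform(0.10, 0.26) — median
18%, the level reported for well-behaved datasets — and applied
multiplicatively and identically to time-course and FD records of that
peptide. Peptide maps are overlapping sliding windows (lengths 8–20, step
3, 1–2 charge states), emulating pepsin redundancy; maps, back-exchange
draws and noise are all deterministic functions of one seed via separate
child streams.

The default protection scenario places PF = 50 on residues 30–47 of the
INCENP-like 58-mer, PF = 20 on Borealin-like 30–60 and PF = 8 on 140–150,
droplet state only, PF = 1 elsewhere — localized interface protection over
an otherwise unstructured background. The synthetic chains
(`synthetic_sequences`) are pseudo-random stand-ins with protein-like
composition, not the real UniProt sequences; the pinned identities
(INCENP D27/E35/E36/E39/E40/E42, Borealin K37/K63, a basic 140–150 patch)
are the only sequence facts downstream analysis consults.

What a green test does establish: correctness of the arithmetic chain
(closed-form kinetics → sums → normalization → differences → consensus)
and of the statistical calibration under i.i.d. Gaussian replicate noise.
What it does not: chromatographic artifacts, envelope overlap and
deconvolution, retention-time drift, EX1 behavior, D2O-content differences
between phases — none of which are modeled.

## Quantification conventions

- maxD convention: residues minus one N-terminal residue minus prolines
  past it, times f_D2O. Whether one or two N-terminal residues lose their
  label is not settled usage; both are supported (`n_term_excluded` 1 or
  2), default 1, and the choice is written into every output header.
- Percent exchange is normalized to the peptide's **measured FD level**
  (FD replicates averaged; outliers > 3 sd flagged), not to theoretical
  maxD; maxD enters only the back-exchange report `1 − FD/maxD`. Peptides
  without a usable FD reference are dropped and logged.
- Centroid deuteron counts may be fractional; centroid-difference values
  within −0.2 D of zero are clamped to 0 with a warning (early-timepoint
  noise), more negative values raise (swapped inputs).
- Charge states are carried as separate measurement series through
  normalization and differencing, merging only at the consensus stage —
  their agreement is itself a quality signal.
- Dataset back-exchange statistics are medians over peptides (charge
  series of one peptide averaged first), not over records.

## Differential statistics

`Δ%D = mean(state_b) − mean(state_a)` per series and timepoint; the
perturbed (droplet) state is `state_b`, so protection on phase separation
is negative. Replicates are compared with a two-sided unpaired Welch
t-test by default (pooled-variance Student available); zero-variance
ties give p = 1, zero-variance separations p = 0 and a degenerate flag.
Multiple-testing correction defaults to `none`, mirroring per-test star
conventions; Holm across timepoints within a peptide is available. Display
bins are ±{3, 6, 10, 20} percentage points, configurable and recorded in
metadata.

Time-shift factors: replicate-averaged curves are made monotone
(cumulative maximum), then for each requested level (default 30–70% of
FD) the crossing time is interpolated on the log-time axis after the
first-order linearization `w = log(−log(1 − %D/100))`, under which a
single-exponential curve is exactly a straight line — so the inversion is
exact for such curves and a controlled approximation for multi-exponential
peptides; plain log-linear interpolation on the five sparse experimental
timepoints misestimates a constructed threefold slowdown by ~18%, which
motivated this choice. The factor is the geometric mean of
`t_droplet/t_free` over usable levels; levels outside either curve's range
are skipped and logged.

## Consensus and structure export

The consensus at a residue is the plain mean of Δ%D over all peptide
measurements spanning it. Span semantics default to the full peptide
extent `start..end` — matching how peptide bars are drawn — even though
the first residue retains no label; an amide-span mode (`start+1..end`)
is exposed. Uncovered residues carry no value, never zero. Structure
export rewrites only the B-factor field (clamped to ±99.99) of ATOM
records in mapped chains, preserving every other byte of the PDB;
uncovered residues get a sentinel (−199 by default) outside any plausible
color range so missing data cannot masquerade as "no change".

## Lattice contacts

Operators are resolved in precedence order: explicit fractional strings,
REMARK 290 records (Cartesian 3×4 matrices), then an internal table for a
few common space groups keyed by the CRYST1 symbol. Copies are every
operator combined with lattice translations within ±`shell` unit cells
(identity/zero excluded); the fractional↔Cartesian transform comes from
the CRYST1 cell. Contacts are heavy-atom pairs within the cutoff, found
with a KD-tree (near-linear in atom count) and verified against all-pairs
scans in the tests. Salt bridges keep Asp OD1/OD2 and Glu OE1/OE2 against
Lys NZ and Arg NE/NH1/NH2 within 4.0 Å (the conventional ~2–4 Å window);
histidine is excluded by default because its protonation state in a
crystal is ambiguous; hydrogens are never inferred; alternate locations
resolve to the highest-occupancy conformer; waters and heteroatoms are
excluded. Candidate ranking puts bridges whose both residues are protected
below the threshold (−5 points) first, then sorts by distance; unmapped or
uncovered residues are flagged, not dropped.

Because the deposited ISB crystal structure cannot be redistributed here,
`synthetic_structure` builds a labelled synthetic stand-in: chains on
spherical spirals in an orthorhombic P 2₁2₁2₁ cell, with exactly two
geometric facts engineered — the inter-copy E42–K37 carboxylate–amine
distance of 2.90 Å and an E40–K63 separation of 6.5 Å. Everything else
(which contacts exist, their reciprocity under inverse operators, the
ranking) is detected, not asserted.

## Numerical choices and degenerate inputs

- Envelope sticks carry exact masses; near-coincident sticks merge with
  probability-weighted mean masses, which preserves the centroid exactly
  (the mean-additivity identity `Δcentroid = Σp_i·Δm_D` holds to < 1e-6).
  Sticks below 1e-12 probability are pruned.
- Noise truncation at zero deuterons; replicates i.i.d.
- Seeds: one integer seed; child streams (back exchange, uptake noise, FD
  noise, map geometry) derived via `SeedSequence` so stages are
  independently reproducible.
- Degenerate peptides (all-proline → maxD 0) are legal inputs for maxD
  (floor 0) but rejected at normalization (FD ≤ 0).

## Known limitations

- The neighbor-factor coefficient table is approximate (see above).
- Time-shift estimation assumes curves saturate at ~100% of FD; strongly
  sub-saturating peptides rely on the cumulative-maximum monotonization.
- The lattice stage reads PDB only (no mmCIF assemblies) and the internal
  space-group table covers a handful of groups — real files are expected
  to carry REMARK 290.
- No instrument-resolution, peak-overlap or retention modeling; the
  simulator's spectra are idealized sticks.
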