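# hxdiff

Differential hydrogen/deuterium-exchange mass spectrometry (HDX-MS)
analysis for localizing the contacts a protein complex forms when it
undergoes liquid–liquid phase separation, together with a crystal-lattice
salt-bridge analysis that cross-references the protected regions with
packing contacts.

The motivating system is the ISB heterotrimer — INCENP(1–58), Survivin and
Borealin, the regulatory core of the chromosome passenger complex — whose
droplet state shows localized backbone protection on the interacting
α-helices of INCENP and Borealin. The package is generic: any two-state
peptide-level HDX comparison with a full-deuteration (FD) reference fits
the same pipeline.

## What it computes

**Forward model (synthetic data).** Exchange at each backbone amide follows
the Linderstrøm-Lang EX2 limit,

    k_obs = k_int / PF,     D_i(t) = f_D2O · (1 − e^(−k_obs·t)),

with per-residue intrinsic rates `k_int` (uniform baseline, or a
sequence-dependent neighbor-factor model), state-specific protection
factors `PF ≥ 1`, labeling fraction `f_D2O` (default 0.75). Peptide
deuteron counts sum residue occupancies over residues `start+1..end`
excluding prolines, attenuated by a per-peptide back-exchange factor, with
Gaussian measurement noise. Optional stick spectra convolve the peptide's
natural isotopic envelope (from its elemental formula) with the
Poisson-binomial distribution of incorporated deuterons.

**Quantification.** Envelope centroids → deuteron counts (centroid mass
shift ÷ Δm_D); percent exchange normalized to each peptide's measured FD
level; back exchange reported as `1 − FD/maxD` where
`maxD = (length − 1 − prolines) · f_D2O`.

**Differential comparison.** Per peptide × charge × timepoint,
`Δ%D = mean(droplet) − mean(free)` (protection negative), Welch t-tests
across replicates with the conventional star bands, categorical binning at
±{3, 6, 10, 20} points, and time-shift factors: how many times longer the
droplet state takes to reach the same deuteration level.

**Residue consensus.** The consensus value at a residue is the mean Δ%D of
every peptide measurement spanning it (charge states counted separately);
the track exports onto a PDB structure's B-factor column.

**Lattice contacts.** Symmetry mates from REMARK 290 operators (or a named
space-group table / explicit override) plus lattice translations; KD-tree
contact search between the asymmetric unit and every copy; salt bridges =
acidic side-chain O to basic side-chain N within 4.0 Å; bridges ranked by
whether both partners fall in HX-protected regions. The deposited ISB
crystal structure is not bundled; a synthetic stand-in lattice
(`hxdiff.synthetic_structure`) reproduces its reported packing geometry —
an inter-trimer INCENP E42–Borealin K37 bridge at 2.9 Å and an E40–K63
pair too distant to bond.

## Worked example

Run the numbered analysis drivers from the repository root (seed optional,
default 1); artifacts land under `results/run/`:

```sh
python analysis/01_simulate.py
python analysis/02_quantify_uptake.py
python analysis/03_differential.py
python analysis/04_consensus.py
python analysis/05_lattice_contacts.py
```

Output of a complete run:

```
simulated 143 peptides (5580 uptake records) -> results/run
normalized 143 peptide series
back exchange: median 18.08% (IQR 14.1-21.87%)
930 peptide x timepoint comparisons, 230 significant at p<0.05
median time-shift factor of strongly protected peptides: 7.77x slower in the droplet state
coverage: 480/480 residues
protected intervals (mean delta <= -5 pts): INCENP:22-58;Borealin:22-69;Borealin:129-156
107 lattice copies, 502 residue contacts, 16 salt bridges
top-ranked candidate interface salt bridges:
  C:GLU39 - B:ARG22 at 2.8 A (both protected)
  C:GLU42 - B:LYS37 at 2.9 A (both protected)
  ...
```

Reading: the simulated droplet state injects protection factor 50 on
INCENP 30–47 (plus Borealin 30–60 and 140–150); the pipeline recovers
protected intervals containing those windows, reports the construction's
18% median back exchange, and the lattice stage ranks the engineered
E42–K37 inter-copy salt bridge (2.9 Å) among the doubly-protected
candidates. The same stages are available as a CLI
(`hxdiff simulate|uptake|diff|consensus|contacts|report|run`, exit codes
0/2/3) driven by a YAML config.

## Acceptance script

`scripts/acceptance.py` re-runs the entire pipeline from scratch —
simulation, FD normalization, differential statistics, consensus mapping,
lattice expansion and salt-bridge ranking — under a given seed and writes
its results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/hxdiff/` — library: `forward` (EX2 simulator), `envelope`
  (isotopic envelopes), `uptake` (centroiding, FD normalization),
  `differential`, `consensus`, `lattice`, `pipeline`, `cli`, plus the
  synthetic stand-ins (`synthetic_sequences`, `synthetic_structure`).
- `analysis/` — numbered narrative drivers.
- `tests/` — unit, property and acceptance tests (all fixtures generated
  programmatically).
- `docs/methods.md` — model assumptions, parameter choices, limitations.
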