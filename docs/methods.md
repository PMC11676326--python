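# Methods

## Windowing

A specification `N_L_O` cuts a sequence of length `n` into windows
`[0, L), [s, s+L), [2s, 2s+L), …` with step `s = L − O`. The overlap is
bounded by `0 ≤ O ≤ L − 1` so the step is at least one residue. If the last
regular window ends short of the C-terminus, a final window
`[n − L, n)` is appended: the window length takes priority and the last
overlap grows. Consequences worth knowing:

* Windows always tile `[0, n)` and all have length exactly `L` (for
  `n ≥ L`). A sequence shorter than one window yields a single
  full-sequence window and a warning rather than an error, so short
  proteins remain scannable.
* With `O = L/2` every residue further than `L/2` from both termini is
  covered by exactly two windows — *provided* the step divides `n − L`.
  When it does not, the anchored final window adds a third covering model
  over a stretch near the C-terminus; the coverage column of the output
  table makes this visible.

Internally all coordinates are 0-based half-open; `constructs.csv` reports
1-based inclusive ranges, the convention human readers expect for residue
numbering. Flanks are applied symmetrically (the same adaptor on both
termini); queries are written either as one FASTA record with the chain
repeated `N` times joined by `:` (the common prediction-server dialect,
default) or as one record per chain copy.

## Feature definitions

**pLDDT** is read from the B-factor of each residue's Cα atom (the
universal prediction-output convention) and averaged over the `N` chain
copies of each fragment position.

**PAE** for fragment position `i` is the mean of all entries in the rows
*and* columns of every chain copy of residue `i`, diagonal included and
rows/columns counted separately (so asymmetric matrices are handled
symmetrically). Per-residue row∪column averaging, rather than one
whole-matrix scalar per fragment, keeps the feature a per-residue track
like the others. Models without a PAE file carry a missing value, never
zero.

**Orientation.** For each unordered chain pair, `d_fwd` is the mean
`‖Cα_A(i) − Cα_B(i)‖` and `d_rev` the same with `B`'s index reversed; the
pair is antiparallel iff the reversal strictly reduces the mean distance
(a tie, measure-zero on real coordinates, counts as parallel for
determinism). Bundles with more than two chains take the majority over all
pairs, 0.5 on an exact tie; monomers have no orientation. Encoded parallel
= 1 / antiparallel = 0, the integrated value is the fraction of covering
models that were parallel.

**Knobs-into-holes.** The detector follows the SOCKET definition on
side-chain centers: residue `r` of chain `X` is a knob when at least four
side-chain centers of residues on one single other chain `Y` lie within
the contact cutoff (default 7.0 Å, exposed as `--cutoff`) of `r`'s
side-chain center; the four nearest form the hole and are marked as hole
members. Side-chain centers are the centroid of non-backbone heavy atoms,
falling back to Cβ and then Cα (glycine). The per-position feature is
binary: 1 if the residue is a knob or hole member in *any* chain (chain
copies of a homo-oligomer are nearly symmetric, so any-chain vs
chain-averaged participation differ only at the margins; the binary
definition keeps the integrated value interpretable as "fraction of
covering models with KIH here"). Knob typing (SOCKET types 1–4) and
register assignment are out of scope — the feature is participation only.
No helicity prefilter is applied; unpacked residues simply produce no
contacts.

## Integration

The integrator maps each fragment's feature vector (flanks already
stripped) onto full-length coordinates and flattens overlaps with a
reducer — arithmetic mean by default; median, min and max are available
behind the same interface, and all obey the same bounds (output within the
envelope of contributing values; a constant feature integrates to that
constant under every reducer). Missing fragments (absent model files)
are logged and reduce coverage instead of aborting; missing features are
excluded from the reduction. The output is a long table keyed by
(1-based position, specification label) with one column per feature plus
`coverage`, written as CSV that round-trips to 1e-6.

## Synthetic bundles

Fixtures are ideal coils of coils built from the Crick parameterization:
with superhelix radius `R0`, minor-helix radius `R1`, superhelix frequency
`ω0`, minor-helix frequency `ω1`, rise `h` and pitch angle
`α = atan(ω0·R0/h)`,

    θ(t) = φ0 + ω0 t,  ψ(t) = φ1 + ω1 t
    x = R0 cosθ + R1 (cosθ cosψ − cosα sinθ sinψ)
    y = R0 sinθ + R1 (sinθ cosψ + cosα cosθ sinψ)
    z = h t − R1 sinα sinψ

Defaults: `R1 = 2.26 Å`, `ω1 = 720/7 ≈ 102.86°`/residue (heptad, 3.5
residues/turn in the rotating frame), `h = 1.51 Å`/residue,
`ω0 = −3.5°`/residue (left-handed supercoil, pitch ≈ 155 Å), and `R0` by
oligomer state (4.9 Å dimer, 5.8 Å trimer, 6.3 Å tetramer) — standard
idealized values giving consecutive Cα–Cα distances of 3.77–3.78 Å. The
default minor-helix phase `φ1 = 180° + 25.71°` places heptad positions *a*
(index 0 mod 7) and *d* (index 3 mod 7) symmetrically about the
core-facing direction, so knob positions on ideal bundles are exactly the
a/d register — the ground truth the KIH tests verify. Because `ψ` lives in
the frame that rotates with the superhelix, the register is maintained
along arbitrarily long chains.

A pseudo side-chain center is placed 1.5 Å radially outward of each Cα
(continuing the direction from the local minor-helix axis); the KIH
detector consumes only these centers, so rotamers are unnecessary. Chains
sit at azimuthal steps of `360°/N`. Antiparallel chains are produced by a
*proper* 180° rotation about the radial axis through the chain's mean
azimuth — this reverses the chain's direction along the bundle axis while
preserving helix handedness and azimuthal position, and is geometrically
equivalent to the mirror-and-reverse-index construction for the features
that consume these models.

Fake prediction runs stamp region-dependent confidence onto these bundles:
parallel regions get pLDDT 90 / PAE 2 Å, antiparallel 85 / 4 Å,
unstructured 40 / 20 Å (pLDDT values chosen in the confident / confident /
disordered bands practitioners expect from real predictors), with 0.25
pLDDT jitter and 0.1 Å coordinate noise drawn from a single seed that is
recorded in the run's `parameters.json`; identical seeds reproduce
byte-identical run directories. Each fragment's model follows the majority
ground-truth label of its window (ties resolve toward the earlier region).
"Unstructured" fragments are modeled as chains translated 100 Å apart —
non-interacting, hence no knobs-into-holes — rather than as conformational
ensembles; their orientation track is therefore the meaningless-but-defined
value of separated parallel chains, and the low pLDDT/high PAE is what
flags them, as with real predictors.

## What the synthetic tests do and do not show

The generator emulates the *file contracts* and *geometric signal* of real
prediction output: multi-chain PDBs with B-factor pLDDT, PAE JSON in two
dialects, controlled orientation and register. It does not emulate
predictor failure modes — spurious bending, partial helicity, register
drift, chain-length asymmetry, confidence miscalibration — so green tests
certify the division/feature/integration machinery, not the quality of any
predictor's models. One model per fragment is consumed; ranking among a
predictor's five models is the caller's concern.

## Numerical choices and degenerate inputs

* Orientation tie-breaks: `d_rev == d_fwd` → parallel; equal pair counts →
  0.5.
* KIH is monotone in the cutoff by construction (shrinking the cutoff can
  only remove knobs).
* PDB fixed-width precision bounds round-trips: coordinates 1e-3 Å, pLDDT
  1e-2.
* Models written by this package encode each residue as ALA with a Cβ at
  the side-chain center, so write→read preserves side-chain centers
  exactly (to format precision).
* More than 62 chains cannot be written to PDB (chain-identifier
  alphabet); insertion codes and multi-model NMR-style files are
  unsupported; mmCIF is accepted on read where the parsing layer handles
  it transparently.
* Empty sequences, non-amino-acid characters, mismatched PAE dimensions
  and unequal chain lengths raise typed errors naming the offending token
  or file.

## Limitations

* The KIH detector reports participation only — no knob typing, register
  letters or periodicity fitting.
* Orientation is a rigid-geometry heuristic; strongly bent or partially
  folded fragments may be called either way (on real models, low pLDDT is
  the guard).
* The integrator stores the flattened value plus coverage, not the raw
  per-window values; rerun the feature extraction per fragment if the
  unflattened distribution is needed.
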