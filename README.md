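# coilscan

Fragment-based scanning of coiled-coil folding potential.

Long fibrous coiled coils — myosin stalks, endosomal tethers such as EEA1,
viral fusion-protein heptad repeats — are hard targets for structure
predictors: full-length models come out spuriously bent, with broken
confidence along the stalk, and non-canonical repeats are modeled poorly.
Predicting short overlapping fragments instead often yields confident,
well-packed models and, because each window is modeled out of its native
context, reveals *local* structural preferences (oligomeric state, helix
orientation, knobs-into-holes packing) that a single full-length model
hides.

`coilscan` automates both ends of this workflow without running any
predictor itself:

1. **divide** — cut a sequence into windows under one or more
   *specifications* `N_L_O` (oligomer count `N`, window length `L`, overlap
   `O`; e.g. `2_30_15` = 30-residue windows, 15-residue overlap, modeled as
   dimers) and write prediction-ready homo-oligomer FASTA queries, a
   constructs table and a parameters file. Windows advance by `L − O`; if
   the last one would run past the C-terminus it is anchored there (`L`
   takes priority and the final overlap grows). An optional flank sequence
   (a GCN4-style adaptor) can be attached to both termini of every window
   to promote folding; it is stripped again before integration.
2. **integrate** — read the per-fragment models (PDB with pLDDT in the
   B-factor column, plus PAE JSON) and flatten four per-residue features
   back onto full-length coordinates, averaging where windows overlap:
   * `plddt` — mean predicted-confidence (0–100) over chain copies,
   * `pae` — mean predicted aligned error (Å) over the rows/columns of
     every chain copy of the residue,
   * `orientation` — parallel (1) vs antiparallel (0), decided per chain
     pair by comparing the mean inter-chain Cα distance at equal residue
     index against the same mean with one index reversed; an integrated
     value of 0.5 means half of the covering models were parallel — the
     local sequence does not encode a topology,
   * `kih` — knobs-into-holes participation: a residue is a *knob* when ≥4
     side-chain centers on a single other chain lie within 7 Å (the SOCKET
     packing-cutoff convention) of its own side-chain center; the four
     nearest form the *hole*.
3. **make-fixtures** — generate ideal Crick-parameterized coiled-coil
   bundles (controlled oligomer state, orientation, heptad register) and
   complete fake "prediction runs" for designed sequences, so the whole
   pipeline is testable at desk scale.

## Worked example

Fabricate a prediction run for a designed 300-residue protein whose thirds
are a parallel dimer, an antiparallel dimer and an unstructured linker,
then integrate it:

```python
from pathlib import Path
from coilscan import build_fake_run, integrate_run, write_table

run = build_fake_run(
    [("parallel", 100), ("antiparallel", 100), ("unstructured", 100)],
    specs=["2_50_25"], seed=7, outdir=Path("scan"),
)
table = integrate_run(run.rundir, run.models_dir)
write_table(table, "scan/per_residue.csv")
print(table.set_index("position").loc[[40, 160, 260],
      ["spec_label", "plddt", "pae", "orientation", "kih", "coverage"]].round(2))
```

prints

```
         spec_label  plddt   pae  orientation  kih  coverage
position
40          2_50_25  89.87   2.0          1.0  1.0         2
160         2_50_25  85.14   4.0          0.0  0.0         2
260         2_50_25  40.22  20.0          1.0  0.0         2
```

Residue 40 sits in the parallel region: both covering models are confident
(pLDDT ≈ 90, PAE 2 Å), parallel (1.0) and knob/hole-packed. Residue 160 is
confidently antiparallel (0.0). Residue 260 lies in the unstructured third:
low confidence, high PAE and no knobs-into-holes packing. `coverage` is 2
everywhere away from the termini because the overlap is half the window.

The same pipeline is available from the shell:

```sh
coilscan divide --fasta protein.fasta --spec 2_30_15 --spec 2_50_25 \
    --flank RMKQLEDKVEELLSK --outdir run/
# ... run your predictor on run/queries/*.fasta, place models in models/ ...
coilscan integrate --rundir run/ --models models/ --out per_residue.csv \
    --plot summary.png
```

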