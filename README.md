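# psmopt

Workflow-parameter optimization for peptide-spectrum matching, at desk
scale.

Shotgun proteomics pipelines are governed by parameters that practitioners
rarely revisit: the negative and positive precursor mass-measurement-error
tolerances (MME−/MME+), the allowed isotope misassignment, the number of
missed cleavages, and the enzymatic fidelity. The optimum is not where
intuition puts it — wide tolerance windows pick up co-isolated
("freerider") precursors and spectra of unmodified N-terminal Gln/Glu
peptides whose b-ion series lost NH₃/H₂O (mass-identical to pyroglutamate
formation, so they match the pyroglutamate candidate at ~+17/+18 Da
precursor error), while ever-wider windows also admit better-scoring random
matches and erode the discrimination between true and false identifications.
Somewhere in between lies an interior optimum.

`psmopt` makes this optimization reproducible without instrument data:

* **peptide_space** — tryptic digestion (after K/R, not before P; full or
  semi fidelity; 0–4 missed cleavages), reversed-sequence decoys,
  carbamidomethyl-Cys fixed and N-terminal pyroglutamate variable
  modifications, and a mass-sorted candidate index.
* **search_core** — precursor acceptance-window algebra with isotope
  offsets, square-root/binned spectrum preprocessing and a k-score-style
  normalized dot product against singly charged b/y-ion templates.
* **confidence** — target-decoy q-values, 1% FDR filtering, and the fitness
  function: accepted doubly charged target PSMs divided by total spectra.
* **optimizer** — a genetic algorithm over mixed continuous / integer /
  boolean / categorical genes with dependency constraints, elitism and
  tournament selection.
* **rt_suite** — three retention-time predictors with 21 / 43 / 93 free
  parameters, an n > p feasibility rule, 10-fold cross-validated RMSD model
  selection and Z-score outlier filtering.
* **synthetic_data** — a ground-truthed LC-MS/MS simulator that plants
  exactly the phenomena above (co-isolation, isotope satellites, N-terminal
  ammonia/water loss, noise spectra) with a planted linear retention model.
* **interface** — MGF/FASTA/TSV I/O, fitness-surface mapping, and the
  `psmopt` command line.

## The quantities at the core

For a spectrum with precursor m/z *m* and charge *z*, the measured neutral
mass is *M* = (*m* − m<sub>proton</sub>)·*z* and the raw mass error against
a candidate peptide of mass *M*<sub>p</sub> is Δ = *M* − *M*<sub>p</sub>. A
candidate is accepted when Δ − *k*·s ∈ [−MME−, +MME+] for some isotope
offset *k* ∈ {0..isotope_max} (s ≈ 1.00335 Da). For a symmetric tolerance
*t* at 1 Da spacing the per-isotope windows merge into one contiguous
window exactly at *t* = 0.5 Da, after which the acceptance region grows
along two edges rather than four or six.

The optimization target is

fitness = #(target PSMs, charge 2+, q ≤ 0.01) / #(spectra searched),

with q-values from the concatenated target-decoy search: FDR(s) =
#decoys ≥ s / max(1, #targets ≥ s), monotonized over decreasing score.

## Worked example

```
psmopt simulate --out run/sim --seed 7 --n-spectra 1000 --n-proteins 50
psmopt search --fasta run/sim/proteome.fasta --mgf run/sim/spectra.mgf \
    --out run/psms.tsv --mme-minus 0.5 --mme-plus 2.5
psmopt optimize --fasta run/sim/proteome.fasta --mgf run/sim/spectra.mgf \
    --out run/opt --population 12 --generations 15 --seed 1
```

The search step prints, for the windows (0.5, 2.5):

```
994 PSMs; fitness=0.4940 (1000 spectra)
```

i.e. 994 spectra had at least one candidate and 494 doubly charged target
PSMs passed 1% FDR. The optimizer then explores MME−/MME+ in [0, 25] Da
and ends with

```
best fitness 0.5200 at MME- 6.68 Da, MME+ 13.13 Da
```

— an interior optimum far from the narrow windows instrument accuracy
would suggest: MME− is set by the co-isolation window rather than the
precursor error, and wide MME+ additionally collects the
pyroglutamate/ammonia-loss matches (the +17–18 Da ridge visible with
`psmopt surface`). `run/opt/generations.tsv` logs best/mean fitness per
generation (nondecreasing best, by elitism). `psmopt surface` writes the
full (MME−, MME+, fitness) grid for contour plotting, and `psmopt
rt-select` / `psmopt rt-filter` perform retention-time model selection and
|Z| ≤ 2 outlier removal on a PSM table.

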