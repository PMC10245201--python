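# warnsig

Quantification of aposematic (warning-signal) colour-pattern phenotypes in
mimetic frogs, and the population statistics built on top of them:

- **`warnsig.synth`** — synthetic studies with known ground truth: phenotype
  tables drawn from population specs (circular hue, clipped saturation,
  integer band counts, a mimicry-convergence dial between sympatric
  partners), plus a cartoon frog renderer whose dorsal band counts, reference
  patches and global colour cast are exactly controllable.
- **`warnsig.phenotyping`** — measurement of one annotated image: 3×4 affine
  colour correction fitted from reference patches; region mean hue/saturation
  (brightness dropped); landmark-aligned binary head-pattern rasters;
  transect transition counts ("adjacent method" reticulation score).
- **`warnsig.distances`** — seven per-characteristic pairwise distance
  matrices (three region colours, three pattern measures, one qualitative
  Dice class), each min-max normalized and fused entrywise as
  √(Σ NM²) into a global distance with equal characteristic weights.
- **`warnsig.mimicry`** — within-population variability (Var = mean pairwise
  distance), centroid-based mimetic distance Im, mimicry similarity
  ms = 1/ΣIm (ms < 1 ⇒ no detected convergence), and the Var–ms Pearson
  correlation with Shapiro–Wilk prechecks.
- **`warnsig.morphospace`** — classical (Torgerson) MDS embedding with
  eigenvalue diagnostics, per-population density surfaces, and leave-self-out
  nearest-centroid outlier fractions.
- **`warnsig.variation`** — per-characteristic variability anatomy:
  Kruskal–Wallis across characteristics plus pairwise Wilcoxon tests with
  Bonferroni correction, variance totals and variability rankings.
- **`warnsig.pipeline` / `warnsig.cli`** — a resumable, seeded, manifested
  end-to-end pipeline behind a `warnsig` subcommand CLI.

## CLI

```sh
warnsig all --config examples/study.yaml --out out/
warnsig simulate  --config examples/study.yaml --out out/   # single stages
warnsig mimicry   --config examples/study.yaml --out out/
warnsig all --config examples/study.yaml --seed 99 --out out99/
warnsig all --config examples/study.yaml --out out/ --from-stage mimicry
```

Outputs: `phenotypes.csv`, `head_rasters.csv`, per-characteristic matrices
under `matrices/`, `matglob.csv`, `mimicry.csv`, `correlation.json`,
`embedding.csv`, `outliers.csv`, `anatomy_*.csv/json`, plots, and a
`manifest.json` whose hash every CSV carries as a leading comment line.

Input is either an inline synthetic study spec (see `examples/study.yaml`)
or a pre-extracted phenotype CSV (`input: {phenotype_csv: path}`); with
`options.render_images: true` the pipeline renders every record to PNG (with
landmark CSVs and indexed-PNG masks), colour-corrects and re-measures the
images instead of using the table directly.

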