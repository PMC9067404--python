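# tilescan

Analysis toolkit for CRISPR–Cas9 **tiling screens**: pooled outgrowth
screens in which hundreds of sgRNAs tile a gene's coding sequence so that
guide-level dropout maps which parts of the protein are required for
proliferation. tilescan takes a guide library and read-count matrix to
per-guide Z-scores, calls gene-level essentiality, deconvolves each
gene's depletion profile into a piecewise-constant step function with a
convex fused lasso, and reports the depleted amino-acid intervals —
candidate essential protein regions — with annotation and conservation
summaries. A synthetic-screen generator with known ground truth makes the
whole pipeline testable without any external data.

It is intended for functional-genomics groups running (or reanalyzing)
dense tiling libraries, and for method work on segmenting noisy
per-position fitness signals along coding sequences.

## The model

**Why tiling works.** Cas9 cuts are repaired by error-prone end joining;
roughly 80% of repair scars shift the reading frame. In diploid cells a
fraction (1−p)² of edited cells (p ≈ 0.2 in-frame repair rate) carries
biallelic frameshifts — lethal anywhere in an essential gene — while the
remaining 1−(1−p)² ≈ 36% keep at least one in-frame but locally
mutagenized allele. Those cells survive *unless* the edit lands in a
residue stretch the protein cannot do without. Guide dropout therefore
steps up inside essential regions, and the step structure along the CDS
is the signal of interest.

**Scoring.** For each guide and replicate, dropout is quantified as
log2 fold change of library-size-normalized counts, final vs initial
population (pseudocount 0.5). Medians across replicates are standardized
per cell line into Z-scores against the whole library (or the
nontargeting controls), and averaged across cell lines. A gene is called
essential when more than 9% of its guides score Z < −1 in at least one
cell line.

**Deconvolution (TiVex).** Ordering a gene's guide Z-scores y by cut
site, the classical fused lasso

    argmin_x 0.5‖y − x‖² + λ₀‖x‖₁ + λ₁ Σᵢ |xᵢ − xᵢ₋₁|

yields a sparse piecewise-constant fit, but its ℓ1 penalties tax large
essential blocks in proportion to their size. tilescan's main estimator
replaces both penalties with a saturating transform
f(t, a) = (1 − e^(−a|t|))/a:

    argmin_x 0.5‖y − x‖² + λ₀ Σᵢ f(xᵢ, a₀) + λ₁ Σᵢ f(xᵢ − xᵢ₋₁, a₁)

f is concave in |t| with curvature bounded by a, and the squared spectral
norm of the first-difference operator is below 4, so the objective stays
convex whenever **1 − a₀λ₀ − 4a₁λ₁ ≥ 0**; this gate is enforced before
fitting. The solver majorizes each f by its tangent line and solves the
resulting weighted fused lasso *exactly* with an O(n) dynamic program, so
the objective is non-increasing and converges to the global minimum.
Regions are then called where the fitted profile drops below the global
average of all genes by a margin τ (default 1 NTC-noise SD), and can be
annotated against Pfam/literature/disorder intervals and per-nucleotide
phyloP conservation.

## Worked example

```python
import tilescan as ts

sim = ts.simulate_screen(ts.SimConfig(n_genes=10, seed=0))
print(f"library: {len(sim.library)} guides "
      f"({(sim.library.gene == 'NTC').sum()} NTCs), "
      f"{len(sim.truth.regions)} planted regions")

result = ts.analyze_screen(sim.library, sim.counts)
print(f"essential genes called: {int(result.gene_calls.essential.sum())}/10")
print(f"regions called: {len(result.regions)} "
      f"(threshold = {result.global_mean:.2f} - {result.ntc_sd:.2f})")

pr = ts.precision_recall(result.regions, sim.truth.true_regions())
print(f"precision {pr['precision']:.2f}, recall {pr['recall']:.2f}")

r = result.regions[0]
print(f"first region: {r.gene} aa {r.aa_start}-{r.aa_end}, "
      f"mean depletion {r.score:.2f} z")
```

prints

```
library: 1567 guides (133 NTCs), 20 planted regions
essential genes called: 10/10
regions called: 25 (threshold = -0.12 - 0.27)
precision 1.00, recall 1.00
first region: GENE001 aa 255-297, mean depletion -0.68 z
```

The simulated library tiles ten 300–1000-aa genes at ~14-nt cut-site
spacing plus scaled-in nontargeting controls; every gene is
frameshift-lethal with two planted essential regions of 30–80 aa. The
pipeline recovers all planted regions (recall 1.00) and calls nothing
outside them (precision 1.00); each called region reports its amino-acid
span and mean fitted depletion in Z units. The same steps are available
from the shell:

```bash
tilescan simulate --config sim.yaml --seed 7 --out simdir/
tilescan design   --cds genes.fasta --out library.tsv
tilescan score    --library library.tsv --counts counts.tsv --samples samples.tsv --out scores.tsv
tilescan fit      --scores scores.tsv --library library.tsv --out-fits fits.tsv --out-regions regions.tsv
tilescan run      --config conf.yaml --out outdir/        # end to end + manifest
```

## Layout

- `tilescan.library_io` — guide/count/annotation/conservation/region I/O
- `tilescan.library_design` — PAM scanning, spacing stats, sequence flags
- `tilescan.screen_stats` — logFC → Z pipeline, gene calls, comparisons
- `tilescan.tivex` — fused-lasso and transformed solvers, region calling
- `tilescan.region_analysis` — overlap, categorization, conservation
- `tilescan.synthetic` — screen generator, perturbation, precision/recall
- `tilescan.cli` — `tilescan {design,score,fit,annotate,simulate,robustness,run}`

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
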