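# cadchart

Chromatin accessibility dynamics charting for the human primed-to-naïve
pluripotency transition — and for any staged differentiation series with
ATAC-seq, RNA-seq and histone-mark data.

During the conversion of primed human embryonic stem cells to the naïve
state, chromatin remodeling runs ahead of transcription: by day 8 of the
transition the reporter-sorted RFP⁻ and RFP⁺ populations already share a
near-identical open-chromatin landscape, yet express naïve and
trophectoderm/primitive-endoderm programs very differently. `cadchart`
implements the downstream computational analysis that quantifies this:

1. **Open/closed calling by empirical FDR.** Peak RPKM values are compared
   against shuffled, length-matched background regions. At a threshold *t*,

   FDR(*t*) = |{background ≥ *t*}| / |{peaks ≥ *t*}|,

   and the global open/closed cutoff is the smallest *t* with FDR(*t*) ≤
   target (default 1%). A peak with stage-level RPKM ≥ *t* is "open",
   otherwise "closed".
2. **Six-module dynamics charting.** Each peak's binary trajectory across
   the ordered stages (pESC → day-8 RFP⁻ → day-8 RFP⁺ → RFP⁺GFP⁺ → nESC) is
   classified: permanently open (1), open-to-closed (2), opened from day 8
   (3), transiently open (4), permanently closed (5), residual (6); plus
   nearest-gene annotation (promoter / genic / distal intergenic).
3. **Accessibility–expression discordance.** Genes whose peaks are open in
   *both* day-8 populations with similar signal (|ATAC log₂FC| ≤ 0.5) but
   whose expression differs (Welch test on log₂(FPKM+1), BH q ≤ 0.05,
   |log₂FC| ≥ 1) are routed into up (higher in RFP⁺) and down (higher in
   RFP⁻) sets.
4. **Histone-mark integration.** ±3 kb peak-centered (or scaled-gene-body)
   profile matrices from binned coverage, pileups, seeded k-means heatmap
   clustering, and a per-mark summary |log₂ ratio| between populations that
   asks which mark (H3K27ac vs H3K4me3) better separates the discordant
   genes.

A first-class synthetic-data module generates coupled ATAC/RNA/histone
bundles with known ground truth (module labels, discordant gene sets, the
RPKM band separating open from closed), so the whole pipeline runs and is
validated end to end with no external download.

## Worked example

```python
from cadchart import *

cfg = SimulationConfig(seed=7)            # 2,000 peaks, 5 stages x 3 replicates
b = generate_dataset(cfg)

t, curve = calibrate_threshold(b.atac, b.background, target_fdr=0.01)
signal = stage_means(b.atac, cfg.stage_design, cfg.stage_labels)
states = binarize_states(signal, t)
assignment = chart_modules(states)
print(round(t, 2))
print(assignment.summary_frame())
```

prints

```
15.42
        count  proportion
module
1         346      0.1730
2         151      0.0755
3         657      0.3285
4         649      0.3245
5         112      0.0560
6          85      0.0425
```

The calibrated threshold (RPKM 15.42) falls inside the generator's true
open/closed separability band, and the recovered module mix matches the
simulated proportions (dominated by modules 1/3/4, as in the real
transition) to within binomial error. Continuing,

```python
neg, pos = cfg.stage_labels[1], cfg.stage_labels[2]
shared = shared_open_peaks(states, neg, pos)              # 1,651 peaks
ann = annotate_peaks(b.peaks, b.genes)
gp = [s for s, l in cfg.stage_design.items() if l == pos]
gn = [s for s, l in cfg.stage_design.items() if l == neg]
de = differential_expression(b.expression_fpkm, gp, gn)
res = find_discordant(shared, signal, de, ann, stage_pos=pos, stage_neg=neg)
print(len(res.up_genes), len(res.down_genes))             # 81 81

loci = b.peaks.subset(g.replace("gene", "peak")
                      for g in res.up_genes + res.down_genes)
prof = {k: build_profile_matrix(tr, loci) for k, tr in b.tracks.items()}
comp = compare_marks(prof, pop_a=pos, pop_b=neg)
print(comp.summary.round(3))   # H3K27ac 0.642, H3K4me3 0.309
print(comp.strongest_mark)     # H3K27ac
```

Of the 170 injected discordant genes, 162 are recovered (precision 1.0),
and the mark comparison reports the larger H3K27ac differential — the
configured asymmetry between the acetylation and methylation effects.

## Command line

```bash
cadchart simulate --out fixtures/ --seed 7          # synthetic fixture bundle
cadchart run-all --fixtures fixtures/ --out run/    # all 11 pipeline stages
cadchart calibrate --peaks peak_rpkm.tsv --background bg_rpkm.tsv
cadchart chart --stage-signal signal.tsv --threshold 25.16 --out modules.tsv
cadchart profiles --track mark.bedgraph --loci peaks.bed --out prof
```

`run-all` writes every intermediate (union peaks, background BED, RPKM
matrices, FDR curve, states, module tables, annotation, DE results,
discordant genes, profile matrices and clusters) plus a JSON manifest with
per-file checksums; identical config and seed reproduce identical bytes.

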