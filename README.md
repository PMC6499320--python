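# svmosaic

A toolkit for building population-scale structural-variant (SV) maps from
many per-sample call sets, in the style of resequencing panels spanning
thousands of rice genomes: merge calls from several SV callers within each
sample, cluster calls across samples into allelic events, benchmark callers
against simulated truth sets, and run the downstream genome-annotation and
regulatory statistics (transposable-element classification, TSS-relative
profiles, TFBS–deletion independence, linguistic complexity, SV-density
windows, deleted genes, enrichment).

It is written for geneticists and pipeline developers who have per-sample
VCFs from tools like Pindel, DELLY, LUMPY or GROM and want one coherent,
deterministic, testable implementation of the comparison and clustering
rules those pipelines rely on.

## Core definitions

For two calls *a*, *b* with half-open intervals:

- **Reciprocal overlap**: `RO(a,b) = min(overlap/len(a), overlap/len(b))` —
  thresholding at *t* requires each call to cover ≥ *t* of the other.
- **Breakpoint error**: `e(a,b) = |a.start − b.start| + |a.end − b.end|`.
- **Benchmark match** (prediction *p* vs simulated event *S*): `RO ≥ 0.9`
  and `e < min(10 bp, 0.1·(len(p)+len(S)))`; duplications relax to
  `RO ≥ 0.7` with no error constraint; insertions (point events) match by
  site distance ≤ 10 bp. Results are tallied per SV type and size bin
  (A 50–150 bp, B 151–500, C 501–5000, D 5–50 kb, E 50–250 kb, F 0.25–1 Mb).
- **Within-sample merge**: keep every anchor-caller (Pindel) PASS call; keep
  all LUMPY inversions; keep any other call supported by ≥ 2 callers at
  pairwise RO ≥ 0.7 when LUMPY is in the pair, else ≥ 0.9; chain insertion
  sites within 10 bp.
- **Cross-sample clustering**: calls of one type overlapping by ≥ 1 bp are
  grouped; a similarity graph connects calls with RO ≥ 0.9, or RO ≥ 0.7 and
  e ≤ 10 bp; each connected component is clustered by complete linkage on
  `d(a,b) = e(a,b)/(len(a)+len(b))` with the tree cut at height 0.1. Each
  resulting cell is one allelic event with median representative
  breakpoints, carrier count/allele frequency, and a *tightness* statistic
  (mean per-side breakpoint deviation over the representative length).

A seeded synthetic-data module generates coordinate-level genomes, truth SV
sets, emulated caller outputs (breakpoint jitter, false negatives, false
positives), multi-sample panels with a planted-cluster answer key, and
annotation tracks — so every pipeline stage can be validated against known
ground truth without external data.

## Worked example

```python
from svmosaic.simulate import SimConfig, simulate_panel
from svmosaic.cluster import cluster_all

cfg = SimConfig(seed=7, panel_size=12, panel_jitter_rel=0.02,
                genome_lengths={"chr1": 2_000_000})
panel = simulate_panel(cfg, n_clusters=6)        # 6 planted allelic events
catalog = cluster_all(panel.all_calls, panel_size=cfg.panel_size)
print("clusters:", catalog.summary()["n_clusters"])
for cl in catalog.clusters[:3]:
    print(cl.cluster_id, f"{cl.chrom}:{cl.rep_start}-{cl.rep_end}",
          cl.svtype, cl.n_samples, round(cl.allele_frequency, 2),
          round(cl.tightness, 4))
```

prints

```
clusters: 6
cl_000000 chr1:11855-14618 DEL 6 0.5 0.0127
cl_000001 chr1:600288-600733 DEL 12 1.0 0.0132
cl_000002 chr1:605821-608295 DEL 10 0.83 0.015
```

The 47 jittered per-sample calls collapse back into exactly the 6 planted
events; each line shows one event's representative interval, its carrier
count out of the 12-sample panel, the allele frequency, and the tightness
(here ≈ 1.3–1.5 % of the event length, reflecting the 2 %-of-length
breakpoint jitter the panel was simulated with).

The same pipeline is available from the shell:

```bash
svmosaic simulate --seed 7 --out sim/
svmosaic merge --sample S000 --vcf pindel=sim/calls/S000.pindel.vcf -o merged/S000.merged.vcf
svmosaic cluster --merged-dir merged/ -o clusters.vcf --matrix membership.tsv
svmosaic benchmark --truth sim/planted.bed --pred merged/S000.merged.vcf -o bench.tsv
```

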