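# heterosis3d

Integrative 3D-genome × transcriptome analysis of **heterosis** — hybrid
vigour — in a parent/parent/hybrid (P1, P2, F1) trio. Given whole-genome
Hi-C contact matrices and replicate FPKM expression tables for the three
samples, the package asks the question hybrid-breeding studies ask: *which
expression changes in the hybrid coincide with changes in its chromatin
architecture?*

It is written for plant genomicists working with small genomes (the design
point is a crucifer-sized genome binned at 40–100 kb), but every stage is
generic Hi-C/RNA-seq methodology.

## What it computes

**Contact matrices** (`matrix_ops`). Sparse-triplet text matrices over a
BED4 bin table are balanced by ICE-style iterative correction (equalizing
bin marginals; zero-marginal bins masked), summarized into cis/trans totals
and the trans/cis contact ratio, and reduced to a per-distance expected
vector E(d).

**A/B compartments** (`compartments`). Per chromosome at 100 kb: the
observed/expected matrix O(i,j)/E(|i−j|) is correlated bin-by-bin
(Pearson), and the first principal component of the correlation matrix
scores each bin. The sign is oriented so the positive (A) side is the
gene-dense one; bins with PC1 > 0 are A, the rest B. Across the trio every
bin gets one of the 8 states `P1-to-P2-to-F1` (e.g. `B-to-B-to-A`), with
percentage reports and gene-level lists of parent→hybrid A-to-B / B-to-A
shifts.

**TADs** (`tads`). The directionality index of bin *i* over window *w*,
with A/B the upstream/downstream contact sums and E = (A+B)/2,

    DI(i) = sign(B − A) · [ (A − E)²/E + (B − E)²/E ]

changes sign from sustained-negative to sustained-positive at domain
boundaries; domains are called from those sign runs. Domains are compared
across samples (conserved iff both boundaries match within ±1 bin),
conserved domains are ranked by the mean log₂ fold change (parent/F1) of
their genes — top 10% *activated*, bottom 10% *repressed* — and boundary
sharing is scored by correlating the two samples' DI tracks around each
boundary.

**Expression & heterosis** (`expression`). Actively expressed genes
(mean FPKM ≥ 1), sample-specific genes (SEGs), replicate/sample R²,
DEG tables (Welch + Benjamini–Hochberg on synthetic data; real DE tables
can be supplied), the trio Up / Down / B2P split (B2P = hybrid strictly
between the parents), and mid-/high-parent heterosis

    MPH = (F̄1 − MP)/MP × 100 %,   HPH = (F̄1 − BP)/BP × 100 %

with MP the mid-parent and BP the better-parent mean.

**Integration** (`integration`). Candidate genes are DEGs sitting in
compartment-shift bins or in activated/repressed TADs, flagged *concordant*
when the expression direction matches the structural change (B-to-A ↔ up in
F1, repressed-in-parent TAD ↔ up in F1, …).

**Synthetic trios** (`simulate`). A generator plants all of the above —
distance decay, compartment checkerboard, TAD blocks, trans background,
A-enriched gene density, DEG/SEG/divergence effects, hybrid-vigour
phenotypes — with full truth tables, so recovery is testable end to end.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from heterosis3d import make_heterosis_trio, analyze_trio

bundle = make_heterosis_trio(seed=1)   # synthetic trio with planted truth
res = analyze_trio(bundle)

print({s: round(r.trans_cis_ratio, 3) for s, r in res.summaries.items()})
print({s: (st["count"], round(st["mean_length_bp"]/1e3)) for s, st in res.tad_stats.items()})
print(res.shift_report.aggregates["unchanged"])
print(res.trio_report.table.to_string(index=False))
print(res.candidate_summary)
```

prints

```
{'P1': 0.129, 'P2': 0.128, 'F1': 0.303}
{'P1': (35, 1143), 'P2': (33, 1212), 'F1': (39, 1026)}
93.5
contrast  up  down  b2p  total  up_pct  down_pct  b2p_pct
  P1vsP2 139   133    0    272   51.10     48.90     0.00
  F1vsP1 190   157    0    347   54.76     45.24     0.00
  F1vsP2 188   152    0    340   55.29     44.71     0.00
F1vsBoth 130    17  117    264   49.24      6.44    44.32
{'n_candidates': 121, 'n_compartment_only': 47, 'n_tad_only': 21, 'n_both': 53, 'n_concordant': 113}
```

Reading it: the hybrid's trans/cis contact ratio (0.303) exceeds both
parents', it has more and smaller TADs (39 domains averaging ~1.0 Mb),
93.5 % of compartment bins keep an unchanged `A-A-A`/`B-B-B` trio state,
264 genes differ from both parents (49 % above both, 44 % between them),
and 121 DEGs coincide with a structural change, 113 of them with matching
direction — all of which reflects the structure the simulation planted.

The same analyses run from the shell:

```bash
heterosis3d simulate --preset heterosis --seed 1 --out trio/   # write a bundle
heterosis3d analyze  --preset heterosis --seed 1 --out results/
```

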