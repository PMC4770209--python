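# foxcobind

Multi-factor ChIP-seq co-binding and DNA-binding-specificity analysis for
Forkhead (FOX) transcription factors — or any set of factors that compete for
closely related motifs.

Members of a transcription-factor family share near-identical DNA-binding
domains, so ChIP-seq experiments for different family members (here FOXK2,
FOXO3 and FOXJ3) return heavily overlapping peak sets. The scientific
questions this package addresses are: which genomic regions are bound by
which exact subset of factors; whether co-bound regions contain one shared
motif or several; whether subtle sequence preferences — in particular the
bases flanking the core `GTAAACA` Forkhead motif — distinguish the factors;
and how binding category relates to the direction of target-gene regulation.

It is written for computational biologists who have per-factor peak calls
(from two peak callers), mapped-tag positions, a genome FASTA, gene models
and a differential-expression table — and for method development, since every
analysis stage can be exercised end-to-end on synthetic data with planted,
recorded ground truth.

## Methods at a glance

- **Consensus peaks.** A peak from the primary caller is retained iff it
  shares ≥ 1 bp with any peak from a second caller; primary coordinates and
  summits are kept.
- **Co-binding categories.** All factors' peaks form an overlap graph
  (edge ⇔ ≥ 1 shared bp); each connected component is one merged region
  labelled by the exact factor subset present, giving factor-specific,
  pairwise-shared and triple-shared classes, plus per-factor raw-peak and
  merged-event counts.
- **Motif statistics.** Exact IUPAC scanning on both strands (genome `N`
  never matches; palindromic double-hits collapsed). Per-category motif
  fractions in ±200 bp summit windows; an exact binomial test for
  enrichment of k/n peak occurrences against a background rate p₀; a survey
  of all 22 single-substitution permutations of the core motif with a
  derived primary/secondary consensus; and genome-saturation counts of motif
  instances inside bound regions.
- **Flanking-base preference.** For core-motif instances found within
  200 bp of peak summits, base counts at offsets −5…−1, +1…+5 (in motif
  orientation) are compared with 1000 resamples of equally many instances
  drawn from the whole genome; a cell is significant when
  z = (observed − mean_null)/sd_null > 13.
- **Tag-density profiles.** Tags are 5′ anchors extended to 200 bp
  fragments; coverage is counted as bases of overlap in 10-bp bins around
  summits or TSSs, giving heatmap matrices and average metaprofiles.
- **Gene association.** A summit is assigned to a gene iff it lies within
  −5 kb…+2 kb of the TSS (strand-aware, boundaries inclusive; nearest TSS
  wins). Genes are labelled up/down-regulated by strict |fold change| > 1.5
  and FDR < 0.05 filters, and tabulated per binding category.

## Worked example

Simulate a complete study (a 2 × 1.2 Mb genome; 135 binding regions across
seven co-binding classes; planted core motifs with an A/T-preferring 5′
flank; tag tracks with occupancy proportional to the number of co-binding
factors; genes whose regulation direction depends on binding class) and run
every analysis stage:

```python
from foxcobind import simulate_study, run_all

simulate_study("demo_bundle", seed=42)
report = run_all("demo_bundle", "demo_out", seed=42)

print("co-binding categories (merged regions):")
for cat, n in sorted(report["venn"].items()):
    print(f"  {cat:10s} {n}")
pair = report["summit_distance"]["K2+O3"]
print(f"K2/O3 summit pairs within 160 bp: "
      f"{100 * pair['fraction_within_cutoff']:.0f}% of {pair['n']}")
```

prints

```
co-binding categories (merged regions):
  J3         15
  J3+K2      15
  J3+K2+O3   25
  J3+O3      10
  K2         30
  K2+O3      25
  O3         15
K2/O3 summit pairs within 160 bp: 100% of 50
```

— exactly the planted architecture (15/15/25/10/30/25/15 regions per class),
recovered through two-caller consensus and overlap partitioning, with every
shared-region summit pair inside the 160-bp co-localization window (the
generator jitters per-factor summits by at most ±40 bp). The report also
shows the mean central tag density rising with the number of co-binding
factors (J3 track: 1405 for J3-specific, ~2700 for pairwise, 4081 for
triple-shared regions) and the planted regulation pattern (72% of
triple-shared genes up-regulated, 8% down, in this run). `demo_out/`
contains the Venn counts, motif fractions and survey, flanking-base
statistics, density profiles and the category × regulation table as TSVs
plus `report.json`.

The same stages are available from the shell:

```
foxcobind simulate --out-dir demo_bundle --seed 42
foxcobind run-all --bundle-dir demo_bundle --out-dir demo_out --seed 42
foxcobind partition --peaks K2=demo_bundle/K2_callerA.narrowPeak \
                    --peaks O3=demo_bundle/O3_callerA.narrowPeak --out-dir part_out
```

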