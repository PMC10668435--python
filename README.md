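# splicemyco

Tools for three analyses that recur in plant symbiosis genetics:

1. **Genome-wide splice-motif surveys.** Most spliceosomal introns begin with
   GT and end with AG; alternatives (GC-AG, AT-AC, and the extremely rare
   GA-AG) make up under 2% of plant introns. `splicemyco` derives introns from
   GFF3 gene models, extracts the boundary dinucleotides in transcript
   orientation, classifies each intron by its joint (donor, acceptor) pair,
   and builds frequency tables with canonical / non-canonical rollups — plus
   locators for the genes carrying a rare motif such as GA-AG.
2. **Intron-retention quantification from RNA-seq alignments.** Per exon and
   per intron, mean per-base coverage per replicate (pileup over M/D CIGAR
   operations; N junction gaps contribute nothing), summarised across
   biological replicates as mean ± s.d. The splicing efficiency of a target
   intron is estimated two independent ways:
   - *coverage ratio*: `1 − intron coverage / mean(flanking exon coverages)`;
   - *junction counting*: reads whose N gap matches the intron exactly versus
     reads aligned continuously across the donor boundary (≥ 3 bp anchors).
3. **Arbuscular-mycorrhization scoring (Trouvelot system).** From per-fragment
   colonization classes (0–5) and arbuscule classes (A0–A3), the indices
   F% (frequency of mycorrhiza), M% (colonization intensity of the root
   system), m% (intensity within colonized fragments), a% (arbuscule abundance
   in colonized parts) and A% (arbuscule abundance in the whole root system),
   with Kruskal–Wallis + rank-based Fisher LSD group statistics and a
   two-sample Student t-test.

A synthetic-data module generates genomes with planted splice motifs, spliced
/ intron-retaining reads with known per-intron retention, and fragment score
tables with known class probabilities — each with a ground-truth manifest —
so the whole pipeline is testable without any downloads.

## Worked example

```python
from splicemyco.survey import SurveyTable
from splicemyco.retention import efficiency_from_coverage
from splicemyco.amf import FragmentScore, compute_indices

# splice-motif table from per-class intron counts of a plant annotation set
table = SurveyTable.from_counts(
    {"GT-AG": 102107, "GC-AG": 537, "AT-AC": 13, "GA-AG": 11, "Others": 1426}
)
for label, count, pct in table.rows():
    print(f"{label:<14}{count:>8}  {pct:6.2f}%")

# splicing efficiency of an intron with mean coverage 4.6 between exons
# covered at 91.8 and 109.4 reads/base
est = efficiency_from_coverage(4.6, [91.8, 109.4])
print(f"splicing efficiency (coverage ratio): {est.efficiency:.4f}")

# Trouvelot indices for 10 scored root fragments
idx = compute_indices(
    [FragmentScore("p1", 0, "A0")] * 5 + [FragmentScore("p1", 1, "A0")] * 2
    + [FragmentScore("p1", 3, "A1")] * 2 + [FragmentScore("p1", 5, "A3")]
)
print(f"F={idx.F:.1f}  M={idx.M:.1f}  m={idx.m:.1f}  a={idx.a:.2f}  A={idx.A:.2f}")
```

prints

```
GT-AG           102107   98.09%
GC-AG              537    0.52%
AT-AC               13    0.01%
GA-AG               11    0.01%
Others            1426    1.37%
Canonical       102107   98.09%
Non-canonical     1987    1.91%
Grand Total     104094  100.00%

splicing efficiency (coverage ratio): 0.9543
F=50.0  M=15.7  m=31.4  a=64.33  A=10.10
```

GT-AG introns are 98.09% of the 104,094 surveyed, GA-AG only 11 (0.01%); an
intron covered at 4.6 reads/base between exons near 100 reads/base is spliced
at ~95%; and a root sample with half its fragments colonized scores F=50 with
arbuscules contributing A=10.1% over the whole root system.

## Command line

```sh
splicemyco simulate-genome --n-genes 50 --seed 1 --out-dir sim
splicemyco survey  --genome sim/genome.fasta --gff sim/genome.gff3 --out-dir out
splicemyco locate  --genome sim/genome.fasta --gff sim/genome.gff3 --motif GA-AG --out-dir out
splicemyco simulate-reads --genome sim/genome.fasta --gff sim/genome.gff3 \
    --retention 0.05 --depth 50 --seed 1 --out-dir reads
splicemyco efficiency --sam reads/reads.sam --features reads/features.tsv \
    --intron intron1 --out-dir out
splicemyco simulate-amf --n-plants 10 --n-fragments 50 --seed 1 --out-dir amf
splicemyco amf --scores amf/fragment_scores.tsv --out-dir out
```

Every subcommand writes TSV artifacts and is byte-reproducible for fixed
inputs and seeds.

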