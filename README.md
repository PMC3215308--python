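# genedesign

A Python toolkit for synthetic-gene design and analysis: codon-usage
metrics, unwanted-sequence discovery and removal, mRNA folding-energy
profiles, Monte-Carlo codon optimization, and a configurable,
constraint-screened optimization pipeline over structured gene constructs.

It is aimed at molecular biologists and bioinformaticians who design
coding sequences for heterologous expression — recoding a gene for a new
host, stripping restriction sites and polyadenylation signals without
touching the protein, controlling local mRNA secondary-structure
stability, and screening large numbers of candidate designs against
explicit constraints.

## What it computes

**Codon adaptation index (CAI).** From a reference codon-usage table the
relative synonymous codon usage is RSCU<sub>ij</sub> = X<sub>ij</sub>·k<sub>i</sub> / Σ<sub>j</sub>X<sub>ij</sub>,
the relative adaptiveness is w<sub>ij</sub> = RSCU<sub>ij</sub>/RSCU<sub>i,max</sub>
(floored at 0.01), and

&nbsp;&nbsp;&nbsp;&nbsp;CAI = exp( (1/L) · Σ<sub>ij</sub> X<sub>ij</sub> ln w<sub>ij</sub> ),

the geometric mean of w over the gene's codons, with L excluding Met
(ATG), Trp (TGG) and stops.

**Effective number of codons (Nc).** Per-amino-acid codon homozygosity
F̂ = (n·Σp<sub>j</sub>² − 1)/(n − 1) is averaged within each degeneracy class
m ∈ {2, 3, 4, 6}, and

&nbsp;&nbsp;&nbsp;&nbsp;Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,

ranging from 20 (one codon per amino acid) to 61 (uniform synonymous
usage). When isoleucine — the only 3-fold family of the standard code — is
absent or rare, F̄₃ is reconstructed from the other classes with
Fuglsang's estimator.

**Sequence search.** Repeated-sequence discovery (direct,
reverse-complement, palindromic and tandem repeats, with a containment
"smart filter"), and multi-query search over motifs or restriction-enzyme
names, with packaged sets of common enzyme sites, polyadenylation signals
and cryptic splice-site motifs.

**mRNA folding.** Minimum-free-energy secondary structure behind a
pluggable engine contract: a self-contained Nussinov-style
weighted-pairing dynamic program by default (pseudo-energies GC −1.0,
AU −0.8, GU −0.5; hairpin loop ≥ 3), or ViennaRNA's `RNAfold` through an
optional adapter. Moving-window energy/GC/CAI profiles (default window
60 nt, step 10 nt).

**Optimization.** Monte-Carlo codon optimization through a 1000-slot
look-up table per amino acid; silent (synonymous) removal of unwanted
motifs; energy-range mRNA optimization with gradual mutation escalation —
all guaranteed to preserve the encoded protein, and all deterministic
under a fixed seed.

**Pipeline.** Gene constructs are ordered, typed components (coding
regions, fixed sites, spacers) carrying `Original AA` / `Original DNA` /
`Modified DNA` properties. A strategy file lists optimization modules and
`Constraint` screens (exclude queries, mRNA stability threshold, repeat
count, CAI/GC bounds) executed in order; every cycle yields a candidate
with metric values, per-constraint verdicts and parent lineage.

A small feedforward neural network (logistic activations, standard
backpropagation, plain-text model files) is included as a pluggable
predictor for strategy experiments.

## Worked example

```python
from genedesign import (
    back_translate, build_lut, cai, codon_optimize, compute_rscu,
    energy_profile, gc_content, nc, search_queries, translate,
)
from genedesign.synthetic import biased_reference_table, random_coding_sequence

table = biased_reference_table()          # deterministic biased reference set
adapt = compute_rscu(table)               # RSCU, RSCU_max, floored w
gene = random_coding_sequence(200, table, seed=42)

print("GC  = %.2f %%" % gc_content(gene))
print("CAI = %.4f" % cai(gene, adapt))
print("Nc  = %.2f" % nc(gene))

opt = codon_optimize(gene, build_lut(adapt), seed=7)
print("optimized CAI = %.4f (%d codons changed)"
      % (cai(opt.sequence, adapt), len(opt.changes)))

track = energy_profile(gene, window=60, step=10)
print("profile rows =", len(track.rows), "min =", track.min())

for h in search_queries(gene, "EcoRI,BamHI"):
    print(h.query, "->", h.motif, "count", h.count)

best = back_translate(translate(gene), policy="max-w", w=adapt.w)
print("max-w CAI = %.4f" % cai(best, adapt))
```

prints

```
GC  = 44.00 %
CAI = 0.6825
Nc  = 45.58
optimized CAI = 0.6771 (93 codons changed)
profile rows = 55 min = -19.8
EcoRI -> GAATTC count 0
BamHI -> GGATCC count 1
max-w CAI = 1.0000
```

The 200-codon gene drawn from the biased table scores CAI 0.68 (well
adapted but not optimal) and Nc 45.6 (moderately biased). Monte-Carlo
resampling from the same table keeps CAI near the table's expectation
while changing 93 codons; the energy profile's most stable 60-nt window
folds at pseudo-energy −19.8; the gene happens to carry one BamHI site
and no EcoRI site; and back-translating with the maximal-w codon at every
position reaches the CAI ceiling of exactly 1.

The same operations are available from the shell:

```sh
genedesign analyze --fasta genes.fa --usage ecoli.cutg --out metrics.tsv
genedesign sites --fasta gene.fa --predefined polyA-signals
genedesign pipeline --construct c.yml --strategy s.yml --usage ecoli.cutg --seed 7
```

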