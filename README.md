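# gaprepair

Analysis toolkit for plasmid gap-repair recombination assays with
diverged templates: calls heteroduplex-DNA (hDNA) tracts from per-SNP
genotype codes of both alleles of individual noncrossover (NCO)
recombinants, classifies each event's repair mechanism from tract
topology, and decomposes normalized gap-repair efficiency into
crossover (CO) / NCO and unidirectional / bidirectional class
efficiencies. A mechanistic event simulator generates synthetic cohorts
with the same statistical structure, so every pipeline stage can be
tested — including parameter recovery — without external data.

## The assay in one paragraph

A plasmid carrying an 800-bp gene with a central 8-bp gap is repaired
off a diverged chromosomal template carrying 19 SNPs (the nearest 18 bp
from each gap edge). In a mismatch-repair-deficient background,
heteroduplex formed during repair is preserved and appears as double
peaks ("H" codes) at SNPs when both alleles of a recombinant are
sequenced. The topology of hDNA identifies the mechanism: plasmid hDNA
on one side of the gap only (unidirectional) indicates
synthesis-dependent strand annealing; on both sides (bidirectional)
indicates Holliday-junction dissolution or two independent invasions;
plasmid hDNA on one side with donor hDNA on the opposite side indicates
junction cleavage. Repair efficiency is the His+:Leu+ co-transformation
ratio normalized to the wild-type mean for the same plasmid mix, and is
decomposed multiplicatively by CO/NCO proportion and then by hDNA class
proportion.

## Package layout

| module | contents |
|---|---|
| `gaprepair.substrate` | `SnpMap` geometry, side conventions, default 800-bp / 19-SNP map, JSON round-trip |
| `gaprepair.hdna` | genotype-code parsing, maximal H-run tract calling, side-level transfer summary |
| `gaprepair.classify` | mechanism-pattern classification and per-strain class tabulation |
| `gaprepair.simulate` | mechanism-conditional event generator, tract-length model, overdispersed transformation counts |
| `gaprepair.efficiency` | mix-wise normalization, CO/NCO partition, efficiency decomposition, table assembly |
| `gaprepair.stats` | pooled-variance Student's t (Welch optional), two-sided Fisher exact, scaled-ratio distributions |
| `gaprepair.datasets` | bundled published strain-level counts and the reference efficiency table |
| `gaprepair.io`, `gaprepair.render`, `gaprepair.cli` | TSV formats with provenance headers, text tract maps, CLI |

## CLI

```sh
gaprepair simulate  --seed 1 --out-dir out/            # events.tsv + transformations.tsv
gaprepair call-hdna --events out/events.tsv --out out/tracts.tsv
gaprepair classify  --events out/events.tsv --out-dir out/
gaprepair summarize --events out/events.tsv \
                    --transformations out/transformations.tsv --out-dir out/
gaprepair compare   --ratios-a a.tsv --ratios-b b.tsv --proportion-a 0.91 --proportion-b 0.75
gaprepair render    --events out/events.tsv
```

`simulate` takes a JSON config describing one or more strains
(mechanism weights, tract-length model, transformation-count
parameters); see `tests/test_io_cli.py` for a worked example. Exit
codes: 0 ok, 1 analysis warning, 2 usage/input error. All TSVs carry
`#`-prefixed provenance headers (tool version, seed, config hash).

Genotype-code strings use `R` (recipient base), `D` (donor base, full
conversion), `H` (heteroduplex double peak), with a literal `|` at the
gap, e.g. `RRHHRRRRR|RRRRRRRRRR`.

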