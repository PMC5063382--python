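# scartag

Primer design and in-silico integration simulation for **scarless gene
tagging in yeast**.

Fusing a fluorescent protein to a gene at its endogenous locus usually
leaves something behind: a selection marker parked in the 3' UTR, or a
loxP/FRT "scar" after marker excision, either of which can perturb the
fusion's expression or regulation. A scarless alternative integrates a
cassette in which the selection marker is flanked by two identical tag
fragments (direct repeats): after integration, spontaneous recombination
between the repeats excises the marker and reconstitutes a seamless
linker + full-length tag, leaving both UTRs untouched. The cassette is
built by two-step PCR with **>= 300 bp homology arms**, which makes
transformation efficient enough that colony screening becomes unnecessary —
but it requires five primers per gene, which is what this package
automates, genome-wide.

## What it computes

For each ORF and tagging mode (scarless C-terminal `C`, scarless
N-terminal `N`, marker-retaining C-terminal `CM`) the designer produces the
quintet **F1, R1, F2, R2, Fc**:

* `R1`/`F2` bind immediately at the insertion junction and carry 5'
  appendices matching the cassette template's ends, so the first-round arm
  products H1/H2 act as megaprimers in the second-round PCR;
* `F1`/`R2` are placed so each homology arm (primer 5' end to junction) is
  at least 300 bp, scanning outward and taking the shortest qualifying arm;
* `Fc` is an optional verification primer 50–300 bp upstream of F1.

Candidate primers must end in a G/C (GC clamp), be free of exact-stem
hairpins, and reach a minimum melting temperature computed on the
genome-binding region only, with a nearest-neighbor model:

```
Tm = 1000·ΔH / (ΔS − 10.8 + R·ln([primer]/4)) − 273.15
     + 16.6·log10([Na+]) + c
```

with ΔH (kcal/mol) and ΔS (cal/(K·mol)) summed over a published 16-stack
nearest-neighbor table, R = 1.987 cal/(K·mol), [primer] = 1 µM,
[Na+] = 50 mM and the empirical offset c = 0.1518 °C. Primers longer than
60 nt are truncated from the 5' end. ORFs whose search window is clipped by
a chromosome end below arm + primer size are reported `not_designable`
(telomere proximity) — failures are table content, not errors.

The companion simulator then proves each design on a locus model:
in-silico PCR (with primer-site uniqueness checks), two-step cassette
assembly (or isothermal overlap joining), exact double-crossover
integration, direct-repeat marker pop-out, and a byte-exact audit that the
final locus is the intended scarless fusion: expected payload, identical
UTRs, in-frame fusion ORF, no residual marker or promoter.

## Worked example

```sh
python examples/design_primers.py
```

```
47 ORFs designable, 3 not designable
    orf mode                 reason
ORF0048    C R2: telomere proximity
ORF0049    C R2: telomere proximity
ORF0050    C R2: telomere proximity

primer set for ORF0001 (H1 arm 300 bp, H2 arm 300 bp):
  ORF0001_C_F1     19 nt  Tm 59.19 C  ggcagaattagagggctac
  ORF0001_C_R1     48 nt  Tm 60.20 C  CGGCACCTGCTCCAGCGCCTGCACCcacgatgttcttaaatgaaaatc
  ORF0001_C_F2     45 nt  Tm 70.27 C  GCTACCGTCCGAGCGGGCAAGATAAaaagggggtcaacgccattc
  ORF0001_C_R2     18 nt  Tm 66.26 C  tgtgcgcacgacaaaaag
  ORF0001_C_Fc     20 nt  Tm 57.29 C  agaatagatacaatacgcgc
```

On a seeded 50-ORF synthetic genome all 47 mid-chromosome ORFs get a
design; the 3 deliberately telomere-proximal ORFs fail with the telomere
reason. Uppercase = cassette-matching appendix (never counted in the Tm),
lowercase = genome-binding region; both homology arms are exactly the
300 bp minimum here because the nearest qualifying GC-clamp site wins.
`examples/simulate_tagging.py` runs the same ORF through all three modes
and prints the audit (`PASS`, marker absent, UTRs identical, frame intact),
and `examples/melting_temperature.py` shows the Tm model in isolation.

The same workflows are available as a CLI for real annotated genomes
(GenBank flat files):

```sh
scartag fixtures --seed 1 --n-orfs 12 --out-dir fix/
scartag design --genome fix/genome.gb --mode C \
    --template fix/template_C.yaml --out out/primers.tsv
scartag simulate --genome fix/genome.gb --table out/primers.tsv \
    --template fix/template_C.yaml --out out/audit.jsonl
```

`design` writes a TSV primer table, a FASTA of full primer sequences, a
failure report and a manifest for byte-identical reruns; `simulate` exits
non-zero iff any scarlessness audit fails.

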