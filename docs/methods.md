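# Methods

## The design problem

Scarless tagging inserts `linker + tag` at a precise junction of an ORF —
immediately 5' of the stop codon for C-terminal fusions, immediately 5' of
the start codon for N-terminal fusions — using an integration cassette with
two long homology arms and a counterselectable marker flanked by identical
tag-fragment direct repeats. scartag designs the five PCR primers that
build such a cassette for any ORF of an annotated genome, and simulates the
construction and integration to certify, byte for byte, that the end state
is scarless.

## Coordinates and junctions

Coordinates are 1-based inclusive on the forward strand (GenBank
convention); junctions are inter-base positions, so "between bases k and
k+1" is the 0-based cut index k and no off-by-one ambiguity survives strand
flips. All design work happens in gene orientation: for minus-strand ORFs
windows are reverse complemented, so "downstream" always means 3' of the
sense strand, and a design is invariant under reverse-complementing the
chromosome and flipping the annotation (tested).

Mode-specific junction conventions:

* **C** (scarless C-terminal): junction between the last sense codon and
  the stop codon. The cassette carries its own stop codon, so the
  downstream homology arm begins 3' of the native stop: integration deletes
  those 3 bp and the audit records a stop-codon substitution.
* **CM** (C-terminal with marker): same junction; nothing is deleted — the
  downstream arm begins at the native stop, which is retained behind the
  cassette's own stop/terminator.
* **N** (scarless N-terminal): junction immediately 5' of the native ATG.
  The cassette's first tag fragment supplies its own start codon and the
  native ATG stays in frame downstream of the linker. The junction base is
  a convention of this package; placing it after the native ATG would be
  equally consistent, but supplying the start with the cassette keeps the
  cassette anatomy identical for every target gene.

Multi-interval (spliced) CDS features are joined into one min..max record:
homologous recombination targets chromosomal DNA, so arms must be genomic,
introns included. Every CDS feature is a design target; annotation status
is not filtered. Records failing coordinate or codon validation are
skipped and reported, and validation can be disabled to match external
inventories.

## The melting-temperature model

Tm of the genome-binding region (5' appendices never contribute):

    Tm = 1000*dH / (dS - ds_init + R*ln([primer]/4)) - 273.15
         + 16.6*log10([Na+]) + c

dH and dS are sums over the len−1 dinucleotide stacks of a published
16-stack nearest-neighbor table shipped as package data
(`data/nn_breslauer.tsv`) and overridable per run. Defaults: ds_init =
10.8 cal/(K·mol), R = 1.987 cal/(K·mol), [primer] = 1 µM, [Na+] = 0.05 M
(the salt term takes mol/L, so log10(0.05) ≈ −1.301), c = 0.1518 °C. The c
offset was originally calibrated against a commercial primer-design
program; agreement with that program is not promised here, only with the
formula itself (tested against an independent re-evaluation to 1e-9 °C).
This parameter set runs hot relative to modern unified parameters — a
20-mer at 40 % GC lands near 60 °C — which is why the default acceptance
threshold `tm_min` is 57 °C (PCR annealing in the underlying protocol runs
at 53 °C, leaving margin); it is configurable, as are all constants.

## Candidate selection rules

* **GC clamp**: 3'-terminal base in {G, C}. This is the common convention;
  the definition is centralized in `thermo.has_gc_clamp` should a stricter
  variant (k G/C among the last 5) ever be needed.
* **Junction primers (R1/F2)**: binding 5' boundary pinned at the junction;
  length grows from 18 nt until Tm ≥ tm_min and the clamp holds, up to
  35 nt; candidates flagged as hairpins are passed over. If no length
  qualifies the ORF fails with a Tm/clamp (or hairpin) reason.
* **Distal primers (F1/R2)**: candidates ordered by (arm length ascending
  from 300 bp, binding length ascending); the first clamp + Tm +
  hairpin-free candidate wins. Shortest-arm-first is a deterministic
  tie-break that keeps first-round amplicons small; the equivalence of the
  scan with exhaustive search over all (position, length) pairs under the
  same order is pinned by test.
* **Fc**: nearest qualifying site whose 3' end sits 50–300 bp upstream of
  F1's 5' end; omitted with a warning when no site exists (the set stays
  ok — Fc is a verification convenience, not part of the cassette).
* **Truncation**: full sequences longer than 60 nt lose bases from the 5'
  end (appendix first); the binding 3' end never moves. With default
  appendix (25 nt) and binding (≤ 35 nt) sizes the limit is never hit, but
  the rule is enforced and tested for configured appendices of any length.
* **Hairpin screen**: an exact-match scan for two reverse-complementary
  stems separated by a minimal loop. The raw predicate defaults to
  stem ≥ 4 / loop ≥ 3, matching classical oligo-property reports; as a
  *rejection* criterion that setting is useless — over 40–60 nt the
  expected number of complementary 4-mer pairs exceeds one, so nearly every
  oligo is "a hairpin". The designer therefore rejects on the binding
  region only, with stem ≥ 8, loop ≥ 3 (configurable): long exact stems
  are the ones that measurably compete with template annealing, and the
  appendix is a fixed property of the cassette template — its secondary
  structure is a template-design question settled once, not a per-ORF
  selection criterion.
* **Telomere rule**: an ORF is not designable on a side whose clipped
  window cannot host min_arm + len_min (= 318) bases. This reproduces the
  known failure class of genome-wide runs, where a handful of
  telomere-proximal ORFs get "N/A" table entries.

## Cassette templates and the simulation

A `SegmentedTemplate` is an ordered list of labeled, role-annotated
segments (linker, tag fragments, marker, promoter, terminator, stop) with
an annotated direct-repeat pair: the last `repeat_len` bases of the first
named segment equal the first `repeat_len` bases of the second. R1's
appendix is the reverse complement of the template's first 25 bases and
F2's appendix its last 25, so the homology-arm products anneal at the
template ends in round two. Template ends must be unique within the
template — a full-length-tag template whose second tag copy repeats the
end verbatim (no recoded codons) is rejected at assembly time, reproducing
the unique-primer-binding-site constraint.

The simulation chain is deliberately exact-match and mismatch-intolerant:

* `in_silico_pcr` requires each primer's 3'-terminal 15 nt (configurable)
  to match the template at exactly one site, convergently; 5' tails are
  incorporated. Multiple sites raise an ambiguous-priming error.
* `assemble_two_step` merges H1 + template interior + H2 with each
  25-bp appendix overlap counted once. `overlap_join` is the
  isothermal-assembly equivalent for arbitrary fragments with unique
  terminal overlaps (the two routes produce identical cassettes, tested).
* `integrate` is an exact double crossover at the genomic arm boundaries;
  arms must match the locus exactly once.
* `popout_marker` collapses the first two occurrences of the repeat,
  deleting everything between (marker; plus the promoter in mode N). A
  locus already carrying a single repeat copy is returned unchanged
  (idempotence); a single copy with the marker still present is a pop-out
  failure (the second repeat was damaged).
* `verify_scarless` reconstructs the expected final locus from the
  original plus the template's popped payload and checks: byte equality;
  5'/3' UTR spans unchanged (scarless modes); fusion ORF in frame, ATG to
  stop, with no internal stop; no marker/promoter substring remaining.

## The synthetic-data generator

`fixtures.make_genome` emulates what the designer actually consumes:
multiple chromosomes, stranded non-overlapping CDS features with valid
start/stop codons and stop-free bodies (codon-wise generation), intergenic
spacers, and deliberately telomere-proximal ORFs. Defaults: 38 % GC
(yeast-like), ORF lengths 300–900 bp, intergenic gaps 900–1500 bp, 30 %
minus-strand. Each telomere-proximal ORF sits on its own short
subtelomeric fragment with 100 bp flanks so that it is undesignable in
every mode, and the emitted truth table records expected per-mode
designability from placement geometry. That truth is an upper bound: an
unusually AT-rich junction window can additionally fail the Tm screen,
which is a real property of the algorithm, not a generator artifact.

`fixtures.make_template` builds mode-appropriate cassette anatomies with a
350 bp direct repeat by default (the shared homology of the published
partial/full-length tag cassettes is ~350 bp), a 708 bp tag (a typical
fluorescent-protein CDS length), an 800 bp marker and, for mode N, a
400 bp promoter between marker and second tag fragment. Tag bodies and the
varied-codon 5xGly-Ala linker are stop-free and codon-aligned so audited
fusions stay in frame. One integer seed drives a single numpy Generator;
the same seed reproduces GenBank output byte-identically.

What the fixtures do *not* model: realistic codon usage, repeated gene
families, introns in the generated CDSs, sequence polymorphism, and
chromatin/efficiency effects on recombination. Passing tests therefore
demonstrate the correctness of the design arithmetic and the
integration/pop-out bookkeeping on realistic-scale sequence, not wet-lab
success rates.

## Problem sizes and determinism

The shipped tests and the acceptance script run on 20–50-ORF genomes
(~90 kb) — large enough that every code path (strands, clipping, telomere
failures, all three modes, ≥ 100 end-to-end audits) is exercised while the
whole suite completes in seconds. Genome-scale runs (thousands of ORFs)
use the same code path through the CLI and scale linearly, a few
milliseconds per ORF. Every operation is a pure function of its inputs;
the only randomness lives in the fixture generator's seed, and repeated
runs are byte-identical.

## Known limitations

* Tm parameters are the classical nearest-neighbor set the underlying
  design procedure used, not the modern unified set; absolute Tm values
  differ from contemporary calculators by several degrees (the empirical
  offset c absorbs part of this).
* No dimer energetics, dangling-end or mismatch corrections; the hairpin
  screen is exact-match, not thermodynamic.
* No genome-wide uniqueness screening of primer sites (only
  cassette-template uniqueness is enforced); no off-target integration
  modeling; recombination is all-or-nothing with zero mismatch tolerance.
* Partial CDS annotations are designable only at their intact end;
  alternative nuclear genetic codes are out of scope.
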