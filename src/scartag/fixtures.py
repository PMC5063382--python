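"""Deterministic synthetic genomes and cassette templates for offline testing.

The generator emulates the structure a tagging-primer designer cares about:
multi-chromosome genomes carrying stranded, non-overlapping CDS features with
proper start/stop codons and stop-free bodies, plus deliberately
telomere-proximal ORFs whose search windows are too clipped to host a
>=300-bp homology arm.  Each telomere-proximal ORF sits on its own short
subtelomeric fragment with only ``telomere_gap`` bp of flank on either side,
so it is undesignable in every tagging mode; regular ORFs are packed
mid-chromosome with generous intergenic spacing.  A truth table of expected
per-mode designability is emitted alongside, derived purely from placement
geometry.

Cassette templates follow the published plasmid anatomy: a linker, a partial
tag fragment, the selection marker (plus a constitutive promoter in mode N),
a second tag fragment sharing an exact direct repeat with the first, and a
stop codon for C-terminal cassettes.  Tag bodies are generated codon-wise
without stop codons so the reconstructed fusion stays in frame.

A single integer seed drives one numpy Generator stream; identical seeds
yield byte-identical GenBank output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .cassette import Segment, SegmentedTemplate
from .genome_io import GenomeAssembly, OrfRecord, STOP_CODONS, junction_position, junction_skip
from .thermo import revcomp

__all__ = [
    "FixtureSpec",
    "make_genome",
    "write_genome_genbank",
    "write_truth_table",
    "make_template",
    "DEFAULT_LINKER",
]

#: 5x Gly-Ala linker with varied codons (non-periodic, stop-free, 30 nt).
DEFAULT_LINKER = "GGTGCAGGCGCTGGAGCAGGTGCCGGCGCA"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic genome."""

    seed: int = 1
    n_chromosomes: int = 2
    n_orfs: int = 20
    orf_len_range: tuple[int, int] = (300, 900)  # bp, rounded to codons
    intergenic_range: tuple[int, int] = (900, 1500)
    gc_fraction: float = 0.38
    minus_strand_fraction: float = 0.3
    n_telomere_proximal: int = 0
    telomere_gap: int = 100
    min_arm: int = 300
    len_min: int = 18

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.n_telomere_proximal > self.n_orfs:
            raise ValueError("more telomere-proximal ORFs than ORFs")
        if self.orf_len_range[0] < 30 or self.orf_len_range[0] > self.orf_len_range[1]:
            raise ValueError("invalid orf_len_range")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")


def _base_probs(gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(_BASES, size=n, p=_base_probs(gc)))


def _stopfree_codons(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Concatenation of n_codons random codons, none of them a stop codon."""
    out: list[str] = []
    while len(out) < n_codons:
        codon = _random_dna(rng, 3, gc)
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def _orf_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG + stop-free body + stop codon; *length* is rounded to codons."""
    n_codons = max(3, length // 3)
    body = _stopfree_codons(rng, n_codons - 2, gc)
    stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    return "ATG" + body + stop


def make_genome(
    spec: FixtureSpec,
) -> tuple[GenomeAssembly, list[OrfRecord], pd.DataFrame]:
    """Generate (assembly, ORF inventory, per-mode designability truth table)."""
    rng = np.random.default_rng(spec.seed)
    n_regular = spec.n_orfs - spec.n_telomere_proximal
    chromosomes: dict[str, str] = {}
    orfs: list[OrfRecord] = []

    per_chrom = [[] for _ in range(spec.n_chromosomes)]
    for i in range(n_regular):
        per_chrom[i % spec.n_chromosomes].append(i)

    orf_index = 0
    for c in range(spec.n_chromosomes):
        cid = f"chr{c + 1:02d}"
        parts: list[str] = []
        pos = 0
        for _ in per_chrom[c]:
            gap = int(rng.integers(*spec.intergenic_range))
            parts.append(_random_dna(rng, gap, spec.gc_fraction))
            pos += gap
            length = int(rng.integers(*spec.orf_len_range))
            oseq = _orf_sequence(rng, length, spec.gc_fraction)
            strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
            parts.append(oseq if strand == "+" else revcomp(oseq))
            orf_index += 1
            orfs.append(
                OrfRecord(
                    name=f"ORF{orf_index:04d}",
                    chromosome=cid,
                    strand=strand,
                    cds_start=pos + 1,
                    cds_end=pos + len(oseq),
                )
            )
            pos += len(oseq)
        tail = int(rng.integers(*spec.intergenic_range))
        parts.append(_random_dna(rng, tail, spec.gc_fraction))
        chromosomes[cid] = "".join(parts)

    # each telomere-proximal ORF gets its own short subtelomeric fragment
    for t in range(spec.n_telomere_proximal):
        cid = f"tel{t + 1:02d}"
        length = int(rng.integers(*spec.orf_len_range))
        oseq = _orf_sequence(rng, length, spec.gc_fraction)
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        flank5 = _random_dna(rng, spec.telomere_gap, spec.gc_fraction)
        flank3 = _random_dna(rng, spec.telomere_gap, spec.gc_fraction)
        chromosomes[cid] = flank5 + (oseq if strand == "+" else revcomp(oseq)) + flank3
        orf_index += 1
        orfs.append(
            OrfRecord(
                name=f"ORF{orf_index:04d}",
                chromosome=cid,
                strand=strand,
                cds_start=spec.telomere_gap + 1,
                cds_end=spec.telomere_gap + len(oseq),
            )
        )

    assembly = GenomeAssembly(
        chromosomes=chromosomes, release_label=f"synthetic-seed{spec.seed}"
    )
    truth = _truth_table(assembly, orfs, spec)
    return assembly, orfs, truth


def _truth_table(
    assembly: GenomeAssembly, orfs: list[OrfRecord], spec: FixtureSpec
) -> pd.DataFrame:
    """Expected designability per mode, from placement geometry alone.

    A mode is expected designable when both gene-oriented clearances from
    the junction to the chromosome ends can host min_arm + len_min bases.
    This is an upper bound: an unusually AT-rich window can still fail the
    designer's Tm/GC-clamp screens.
    """
    need = spec.min_arm + spec.len_min
    rows = []
    for orf in orfs:
        row = {
            "name": orf.name,
            "chromosome": orf.chromosome,
            "strand": orf.strand,
            "start": orf.cds_start,
            "end": orf.cds_end,
        }
        chrom_len = assembly.length(orf.chromosome)
        for mode in ("CM", "C", "N"):
            k = junction_position(orf, mode)
            s = junction_skip(mode)
            if orf.strand == "+":
                up, down = k, chrom_len - (k + s)
            else:
                up, down = chrom_len - k, k - s
            row[f"designable_{mode}"] = bool(up >= need and down >= need)
        rows.append(row)
    return pd.DataFrame(rows)


def write_genome_genbank(
    assembly: GenomeAssembly, orfs: list[OrfRecord], path: str
) -> None:
    """Write a multi-record GenBank flat file; byte-identical per seed."""
    by_chrom: dict[str, list[OrfRecord]] = {c: [] for c in assembly.chromosomes}
    for orf in orfs:
        by_chrom[orf.chromosome].append(orf)
    records = []
    for cid, seq in assembly.chromosomes.items():
        rec = SeqRecord(Seq(seq), id=cid, name=cid, description="synthetic fixture")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["date"] = "01-JAN-2000"
        rec.annotations["data_file_division"] = "PLN"
        for orf in sorted(by_chrom[cid], key=lambda o: o.cds_start):
            loc = FeatureLocation(
                orf.cds_start - 1, orf.cds_end, strand=1 if orf.strand == "+" else -1
            )
            rec.features.append(
                SeqFeature(loc, type="CDS", qualifiers={"locus_tag": [orf.name]})
            )
        records.append(rec)
    SeqIO.write(records, path, "genbank")


def write_truth_table(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


def make_template(
    mode: str,
    seed: int = 1,
    tag_len: int = 708,
    marker_len: int = 800,
    repeat_len: int = 350,
    promoter_len: int = 400,
    head_len: int = 177,
    terminator_len: int = 200,
    linker: str = DEFAULT_LINKER,
    recoded: bool = True,
) -> SegmentedTemplate:
    """Build a mode-appropriate cassette template with exact direct repeats.

    ``tag_len`` is the full tag coding length (must be a codon multiple so
    the fusion stays in frame); ``repeat_len`` the shared homology between
    the two tag fragments (~350 bp in the published cassettes).  With
    ``recoded=False`` (mode C only) both tag copies are full length and
    byte-identical, reproducing the non-recoded template whose primer
    binding sites are ambiguous.  ``repeat_len=0`` yields a template without
    annotated repeats: ``popout_ready`` is False and marker excision cannot
    be simulated.
    """
    if mode not in ("CM", "C", "N"):
        raise ValueError("mode must be CM, C or N")
    if tag_len % 3 or len(linker) % 3 or head_len % 3:
        raise ValueError("tag_len, head_len and linker length must be codon multiples")
    if repeat_len > tag_len:
        raise ValueError("repeat_len cannot exceed tag_len")
    if mode == "N" and head_len + repeat_len > tag_len:
        raise ValueError("head_len + repeat_len cannot exceed tag_len")
    rng = np.random.default_rng(seed)
    gc = 0.45
    marker = _random_dna(rng, marker_len, gc)

    if mode == "CM":
        tag = _stopfree_codons(rng, tag_len // 3, gc)
        segments = (
            Segment("linker", linker, "linker"),
            Segment("tag", tag, "tag_full"),
            Segment("stop", "TAA", "stop"),
            Segment("terminator", _random_dna(rng, terminator_len, gc), "terminator"),
            Segment("marker", marker, "marker"),
        )
        return SegmentedTemplate(segments=segments, mode=mode)

    if mode == "C":
        body = _stopfree_codons(rng, tag_len // 3, gc)
        if not recoded:
            segments = (
                Segment("linker", linker, "linker"),
                Segment("tag5", body, "tag_full"),
                Segment("marker", marker, "marker"),
                Segment("tag3", body, "tag_full"),
            )
            return SegmentedTemplate(
                segments=segments, mode=mode,
                repeat_pair=("tag5", "tag3"), repeat_len=len(body),
            )
        repeat = body[:repeat_len]
        tail = body[repeat_len:]
        segments = (
            Segment("linker", linker, "linker"),
            Segment("tag5", repeat, "tag_partial"),
            Segment("marker", marker, "marker"),
            Segment("tag3", repeat + tail, "tag_full"),
            Segment("stop", "TAA", "stop"),
        )
        if repeat_len == 0:
            # degenerate: no shared homology, pop-out cannot occur
            return SegmentedTemplate(segments=segments, mode=mode)
        return SegmentedTemplate(
            segments=segments, mode=mode,
            repeat_pair=("tag5", "tag3"), repeat_len=repeat_len,
        )

    # mode N: first fragment carries the cassette's own start codon; the
    # promoter between marker and second fragment drives an intermediate
    # fusion while the marker is still in place.
    body = "ATG" + _stopfree_codons(rng, tag_len // 3 - 1, gc)
    head = body[:head_len]
    repeat = body[head_len : head_len + repeat_len]
    tail = body[head_len + repeat_len :]
    segments = (
        Segment("tag5", head + repeat, "tag_partial"),
        Segment("marker", marker, "marker"),
        Segment("promoter", _random_dna(rng, promoter_len, gc), "promoter"),
        Segment("tag3", repeat + tail, "tag_partial"),
        Segment("linker", linker, "linker"),
    )
    if repeat_len == 0:
        return SegmentedTemplate(segments=segments, mode=mode)
    return SegmentedTemplate(
        segments=segments, mode=mode,
        repeat_pair=("tag5", "tag3"), repeat_len=repeat_len,
    )
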