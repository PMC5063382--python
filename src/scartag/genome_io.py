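"""Annotated-genome input, ORF inventory, and junction-window extraction.

Genomes enter either as GenBank flat files (one or more records per file;
CDS features define the ORF inventory) or as a plain FASTA plus a TSV table
of CDS coordinates.  Coordinates are 1-based inclusive on the forward strand,
matching GenBank convention.  Insertion junctions are inter-base positions:
junction ``k`` sits between forward-strand bases ``k`` and ``k+1``, which in
0-based string terms is the cut index ``k``.

Tagging modes:

``C``
    scarless C-terminal: the payload is inserted between the last sense codon
    and the stop codon; the cassette carries its own stop, so the downstream
    homology window begins 3' of the native stop (a 3-bp skip).
``CM``
    C-terminal with a retained marker: junction as for C, but the downstream
    window begins at the native stop codon (nothing deleted).
``N``
    scarless N-terminal: junction immediately 5' of the native ATG; the
    cassette supplies its own start codon and the native ATG stays in frame
    downstream of the linker.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import AfterPosition, BeforePosition
from Bio.SeqRecord import SeqRecord

from .thermo import revcomp

__all__ = [
    "MODES",
    "STOP_CODONS",
    "GenomeAssembly",
    "OrfRecord",
    "JunctionWindows",
    "ParseIssue",
    "ParseResult",
    "NotDesignableError",
    "parse_genome",
    "junction_position",
    "junction_skip",
    "extract_windows",
    "upstream_sequence",
    "assembly_to_fasta",
    "assembly_from_fasta",
    "write_orf_table",
    "read_orf_table",
]

MODES = ("CM", "C", "N")
STOP_CODONS = ("TAA", "TAG", "TGA")
_IUPAC_DNA = set("ACGTNRYSWKMBDHV")


class NotDesignableError(ValueError):
    """A design step cannot proceed for this ORF; carries a short reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class GenomeAssembly:
    """Chromosome sequences keyed by id, in file order."""

    chromosomes: dict[str, str]
    release_label: str = ""
    organelle_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        ids = list(self.chromosomes)
        if len(ids) != len(set(ids)):
            raise ValueError("chromosome ids must be unique")
        for cid, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {cid} has an empty sequence")
            bad = set(seq) - _IUPAC_DNA
            if bad:
                raise ValueError(
                    f"chromosome {cid} contains non-IUPAC letters {sorted(bad)}"
                )

    @property
    def nuclear_ids(self) -> list[str]:
        return [c for c in self.chromosomes if c not in self.organelle_ids]

    def length(self, chromosome: str) -> int:
        return len(self.chromosomes[chromosome])


@dataclass(frozen=True)
class OrfRecord:
    """One CDS feature: stranded 1-based inclusive forward coordinates.

    Multi-interval (spliced) CDS features are joined into a single record
    spanning min..max with the interval list retained in ``parts``.
    """

    name: str
    chromosome: str
    strand: str  # '+' or '-'
    cds_start: int
    cds_end: int
    parts: tuple[tuple[int, int], ...] = ()
    partial_5: bool = False
    partial_3: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.cds_start <= self.cds_end):
            raise ValueError("require 1 <= cds_start <= cds_end")

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start + 1

    def oriented_cds(self, assembly: GenomeAssembly) -> str:
        """CDS sequence 5'->3' on the sense strand (introns included)."""
        seq = assembly.chromosomes[self.chromosome][
            self.cds_start - 1 : self.cds_end
        ]
        return seq if self.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class JunctionWindows:
    """Gene-oriented sequence windows flanking a tagging junction.

    ``upstream`` ends exactly at the junction; ``downstream`` begins ``skip``
    bases 3' of it (skip = 3 for mode C where the native stop codon is
    replaced, else 0).  For minus-strand ORFs both windows are reverse
    complemented so that "downstream" always means 3' of the sense strand.
    """

    orf: OrfRecord
    mode: str
    upstream: str
    downstream: str
    junction: int  # forward-strand inter-base position (0-based cut index)
    skip: int
    window_size: int

    @property
    def upstream_len(self) -> int:
        return len(self.upstream)

    @property
    def downstream_len(self) -> int:
        return len(self.downstream)


@dataclass(frozen=True)
class ParseIssue:
    file: str
    record: str
    feature: str
    message: str


@dataclass
class ParseResult:
    assembly: GenomeAssembly
    orfs: list[OrfRecord]
    report: list[ParseIssue] = field(default_factory=list)

    def __iter__(self):  # allow (assembly, orfs) unpacking
        return iter((self.assembly, self.orfs))


def _feature_name(feature, index: int) -> str:
    for key in ("locus_tag", "gene", "protein_id"):
        if key in feature.qualifiers:
            return feature.qualifiers[key][0]
    return f"CDS_{index:05d}"


def _is_partial(pos) -> bool:
    return isinstance(pos, (BeforePosition, AfterPosition))


def parse_genome(
    files: Sequence[str],
    organelle_ids: Iterable[str] = (),
    release_label: str = "",
    validate_codons: bool = True,
) -> ParseResult:
    """Read GenBank flat files into an assembly plus an ORF inventory.

    One OrfRecord is produced per CDS feature on non-organellar chromosomes.
    Records whose coordinates fall outside the chromosome, or (when
    *validate_codons* is set) whose non-partial sense-strand sequence lacks a
    start/stop codon or a length divisible by 3, are skipped and reported.
    Output ordering is deterministic: chromosome file order, then cds_start.
    """
    organelles = frozenset(organelle_ids)
    chromosomes: dict[str, str] = {}
    orfs: list[OrfRecord] = []
    report: list[ParseIssue] = []

    for path in files:
        try:
            records = list(SeqIO.parse(path, "genbank"))
        except Exception as exc:  # noqa: BLE001 - report file and cause
            raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc
        if not records:
            raise ValueError(f"cannot parse GenBank file {path}: no records found")
        for rec in records:
            if rec.id in chromosomes:
                raise ValueError(f"duplicate chromosome id {rec.id} in {path}")
            chromosomes[rec.id] = str(rec.seq).upper()
            if rec.id in organelles:
                continue
            idx = 0
            for feature in rec.features:
                if feature.type != "CDS":
                    continue
                idx += 1
                name = _feature_name(feature, idx)
                loc = feature.location
                strand = "-" if loc.strand == -1 else "+"
                parts = tuple(
                    sorted((int(p.start) + 1, int(p.end)) for p in loc.parts)
                )
                start, end = parts[0][0], parts[-1][1]
                partial_low = _is_partial(loc.start)
                partial_high = _is_partial(loc.end)
                partial_5 = partial_low if strand == "+" else partial_high
                partial_3 = partial_high if strand == "+" else partial_low
                if start < 1 or end > len(rec.seq):
                    report.append(
                        ParseIssue(path, rec.id, name, "coordinates outside sequence")
                    )
                    continue
                orf = OrfRecord(
                    name=name,
                    chromosome=rec.id,
                    strand=strand,
                    cds_start=start,
                    cds_end=end,
                    parts=parts,
                    partial_5=partial_5,
                    partial_3=partial_3,
                )
                issue = _codon_issue(orf, str(rec.seq).upper()) if validate_codons else None
                if issue:
                    report.append(ParseIssue(path, rec.id, name, issue))
                    continue
                orfs.append(orf)

    assembly = GenomeAssembly(
        chromosomes=chromosomes,
        release_label=release_label,
        organelle_ids=organelles,
    )
    order = {cid: i for i, cid in enumerate(chromosomes)}
    orfs.sort(key=lambda o: (order[o.chromosome], o.cds_start, o.name))
    return ParseResult(assembly=assembly, orfs=orfs, report=report)


def _codon_issue(orf: OrfRecord, chrom_seq: str) -> str | None:
    seq = chrom_seq[orf.cds_start - 1 : orf.cds_end]
    if orf.strand == "-":
        seq = revcomp(seq)
    if len(seq) < 3:
        return "CDS shorter than one codon"
    partial = orf.partial_5 or orf.partial_3
    if partial:
        return None
    if len(seq) % 3:
        return "CDS length not divisible by 3"
    if not seq.startswith("ATG"):
        return "CDS does not begin with a start codon"
    if seq[-3:] not in STOP_CODONS:
        return "CDS does not end with a stop codon"
    return None


def junction_position(orf: OrfRecord, mode: str) -> int:
    """Forward-strand inter-base insertion position for *orf* under *mode*.

    The returned integer k labels the cut between forward bases k and k+1
    (1-based), equivalently the 0-based string index at which to split.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "N":
        if orf.partial_5:
            raise NotDesignableError("ORF annotated partial at its 5' end")
        return orf.cds_start - 1 if orf.strand == "+" else orf.cds_end
    # C / CM: between the last sense codon and the stop codon
    if orf.partial_3:
        raise NotDesignableError("ORF annotated partial at its 3' end")
    return orf.cds_end - 3 if orf.strand == "+" else orf.cds_start + 2


def junction_skip(mode: str) -> int:
    """Genomic bases deleted at the junction (the native stop in mode C)."""
    return 3 if mode == "C" else 0


def extract_windows(
    assembly: GenomeAssembly,
    orf: OrfRecord,
    mode: str,
    window_size: int,
) -> JunctionWindows:
    """Up to *window_size* gene-oriented bases on each side of the junction.

    Windows are clipped at chromosome ends; the achieved lengths are simply
    the lengths of the returned strings (clipping is reported, not fatal).
    """
    k = junction_position(orf, mode)
    s = junction_skip(mode)
    chrom = assembly.chromosomes[orf.chromosome]
    n = len(chrom)
    if orf.strand == "+":
        upstream = chrom[max(0, k - window_size) : k]
        downstream = chrom[k + s : min(n, k + s + window_size)]
    else:
        upstream = revcomp(chrom[k : min(n, k + window_size)])
        downstream = revcomp(chrom[max(0, k - s - window_size) : k - s])
    return JunctionWindows(
        orf=orf,
        mode=mode,
        upstream=upstream,
        downstream=downstream,
        junction=k,
        skip=s,
        window_size=window_size,
    )


def upstream_sequence(
    assembly: GenomeAssembly, orf: OrfRecord, mode: str, length: int
) -> str:
    """Gene-oriented sequence ending exactly at the junction (clipped)."""
    k = junction_position(orf, mode)
    chrom = assembly.chromosomes[orf.chromosome]
    if orf.strand == "+":
        return chrom[max(0, k - length) : k]
    return revcomp(chrom[k : min(len(chrom), k + length)])


def assembly_to_fasta(assembly: GenomeAssembly, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="")
        for cid, seq in assembly.chromosomes.items()
    ]
    SeqIO.write(records, path, "fasta")


def assembly_from_fasta(
    path: str, release_label: str = "", organelle_ids: Iterable[str] = ()
) -> GenomeAssembly:
    chromosomes = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")
    }
    return GenomeAssembly(
        chromosomes=chromosomes,
        release_label=release_label,
        organelle_ids=frozenset(organelle_ids),
    )


def write_orf_table(orfs: Sequence[OrfRecord], path: str) -> None:
    df = pd.DataFrame(
        [
            {
                "name": o.name,
                "chromosome": o.chromosome,
                "strand": o.strand,
                "start": o.cds_start,
                "end": o.cds_end,
            }
            for o in orfs
        ],
        columns=["name", "chromosome", "strand", "start", "end"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_orf_table(path: str) -> list[OrfRecord]:
    """TSV ORF inventory (name, chromosome, strand, start, end) as input."""
    df = pd.read_csv(path, sep="\t")
    return [
        OrfRecord(
            name=str(r["name"]),
            chromosome=str(r["chromosome"]),
            strand=str(r["strand"]),
            cds_start=int(r["start"]),
            cds_end=int(r["end"]),
        )
        for _, r in df.iterrows()
    ]
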