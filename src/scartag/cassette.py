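"""In-silico cassette assembly, chromosomal integration and marker pop-out.

The simulation mirrors the wet-lab workflow exactly, at base-pair precision:

1. First-round PCRs amplify the two homology arms H1 and H2 from the locus
   (``in_silico_pcr``); the R1/F2 appendix tails become part of the products.
2. Second-round PCR uses H1 and H2 as megaprimers on the cassette template
   (``assemble_two_step``), merging each appendix overlap exactly once.  An
   isothermal-assembly alternative (``overlap_join``) fuses fragments via
   unique terminal overlaps.
3. ``integrate`` models homologous recombination as an exact double crossover
   at the arm boundaries, replacing the genomic span between the arms.
4. ``popout_marker`` collapses the template's two direct repeats to a single
   copy, deleting the selection marker (and, for N-terminal tagging, the
   heterologous promoter) that sits between them.
5. ``verify_scarless`` audits the final locus byte-for-byte: expected payload
   at the junction, untouched UTRs, an in-frame fusion ORF with no internal
   stop, and no residual marker or promoter sequence.

Recombination is deliberately modeled without mismatch tolerance: the audit
must be exact for "scarless" to mean anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import yaml

from .design import PrimerSet, PrimerSpec
from .genome_io import (
    GenomeAssembly,
    OrfRecord,
    STOP_CODONS,
    junction_position,
    junction_skip,
)
from .thermo import revcomp

__all__ = [
    "Segment",
    "SegmentedTemplate",
    "Amplicon",
    "LocusModel",
    "AuditReport",
    "IntegrationOutcome",
    "PcrError",
    "NoProductError",
    "AmbiguousPrimingError",
    "AssemblyError",
    "AmbiguousAssemblyError",
    "IntegrationError",
    "PopoutError",
    "in_silico_pcr",
    "assemble_two_step",
    "overlap_join",
    "integrate",
    "popout_marker",
    "verify_scarless",
    "simulate_tagging",
    "locus_from_assembly",
    "template_to_yaml",
    "template_from_yaml",
]

SEGMENT_ROLES = (
    "linker",
    "tag_full",
    "tag_partial",
    "marker",
    "promoter",
    "terminator",
    "stop",
    "other",
)


class PcrError(ValueError):
    pass


class NoProductError(PcrError):
    pass


class AmbiguousPrimingError(PcrError):
    pass


class AssemblyError(ValueError):
    pass


class AmbiguousAssemblyError(AssemblyError):
    pass


class IntegrationError(ValueError):
    pass


class PopoutError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    label: str
    sequence: str
    role: str = "other"

    def __post_init__(self) -> None:
        if self.role not in SEGMENT_ROLES:
            raise ValueError(f"unknown segment role {self.role!r}")


@dataclass(frozen=True)
class SegmentedTemplate:
    """Ordered, role-annotated anatomy of a tagging-cassette template.

    ``repeat_pair`` names the two segments carrying the direct repeat and
    ``repeat_len`` its length: the last ``repeat_len`` bases of the first
    named segment must equal the first ``repeat_len`` bases of the second.
    For scarless modes the repeats flank the marker (plus the promoter in
    mode N); marker excision by recombination collapses them to one copy.
    """

    segments: tuple[Segment, ...]
    mode: str
    repeat_pair: tuple[str, str] | None = None
    repeat_len: int = 0

    def __post_init__(self) -> None:
        labels = [s.label for s in self.segments]
        if len(labels) != len(set(labels)):
            raise ValueError("segment labels must be unique")
        if self.repeat_pair is not None:
            if self.repeat_len < 1:
                raise ValueError("repeat_len must be >= 1 when repeats are set")
            a, b = (self.segment(x) for x in self.repeat_pair)
            if (
                len(a.sequence) < self.repeat_len
                or len(b.sequence) < self.repeat_len
                or a.sequence[-self.repeat_len :] != b.sequence[: self.repeat_len]
            ):
                raise ValueError("repeat_pair sequences are not identical")

    def segment(self, label: str) -> Segment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(label)

    @property
    def sequence(self) -> str:
        """Concatenation of segments: the template's amplifiable region."""
        return "".join(s.sequence for s in self.segments)

    @property
    def popout_ready(self) -> bool:
        """True when a direct-repeat pair is annotated for marker excision."""
        return self.repeat_pair is not None

    @property
    def repeat_seq(self) -> str:
        if self.repeat_pair is None:
            raise ValueError("template has no annotated direct repeats")
        return self.segment(self.repeat_pair[0]).sequence[-self.repeat_len :]

    def popped_payload(self) -> str:
        """Template sequence after collapsing the direct repeats once.

        Everything between the first repeat copy and the end of the second
        (the marker, and the promoter in mode N) is removed; one repeat copy
        remains.  Without repeats the full template is returned (mode CM).
        """
        if self.repeat_pair is None:
            return self.sequence
        a_label, b_label = self.repeat_pair
        out: list[str] = []
        skipping = False
        for s in self.segments:
            if s.label == a_label:
                out.append(s.sequence)
                skipping = True
            elif s.label == b_label:
                out.append(s.sequence[self.repeat_len :])
                skipping = False
            elif not skipping:
                out.append(s.sequence)
        return "".join(out)

    def marker_seq(self) -> str | None:
        for s in self.segments:
            if s.role == "marker":
                return s.sequence
        return None

    def promoter_seq(self) -> str | None:
        for s in self.segments:
            if s.role == "promoter":
                return s.sequence
        return None


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    fwd_site: int  # template index of the forward primer's 3'-anneal start
    rev_site: int  # template index of the reverse primer's 3'-anneal start
    fwd_primer: PrimerSpec | None = None
    rev_primer: PrimerSpec | None = None


@dataclass(frozen=True)
class LocusModel:
    """A genomic locus in gene orientation with optional annotated spans.

    Spans are 0-based half-open indices into ``sequence``.
    """

    sequence: str
    orf_span: tuple[int, int] | None = None
    utr5_span: tuple[int, int] | None = None
    utr3_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for span in (self.orf_span, self.utr5_span, self.utr3_span):
            if span is not None:
                s, e = span
                if not (0 <= s <= e <= len(self.sequence)):
                    raise ValueError(f"span {span} outside sequence")


@dataclass(frozen=True)
class AuditReport:
    passed: bool
    checks: dict[str, bool]
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class IntegrationOutcome:
    intermediate: LocusModel
    final: LocusModel
    audit: AuditReport | None = None


def _count_occurrences(haystack: str, needle: str) -> int:
    """Overlapping occurrence count."""
    count = start = 0
    while True:
        i = haystack.find(needle, start)
        if i == -1:
            return count
        count += 1
        start = i + 1


def in_silico_pcr(
    template: str,
    fwd: PrimerSpec,
    rev: PrimerSpec,
    min_anneal: int = 15,
) -> Amplicon:
    """Predict the product of a PCR with exact 3'-end annealing.

    The 3'-terminal ``min_anneal`` bases of each primer must match the
    template at exactly one site, in convergent orientation.  5' tails that
    do not match (appendices) are incorporated into the product:

        product = fwd.full_seq + inter-site template + revcomp(rev.full_seq)
    """
    fwd_anchor = fwd.full_seq[-min_anneal:]
    rev_anchor = revcomp(rev.full_seq[-min_anneal:])
    n_f = _count_occurrences(template, fwd_anchor)
    n_r = _count_occurrences(template, rev_anchor)
    if n_f == 0 or n_r == 0:
        raise NoProductError(
            f"primer 3' end not found on template (fwd x{n_f}, rev x{n_r})"
        )
    if n_f > 1 or n_r > 1:
        raise AmbiguousPrimingError(
            f"primer 3' end matches template more than once "
            f"(fwd x{n_f}, rev x{n_r})"
        )
    p = template.find(fwd_anchor)
    q = template.find(rev_anchor)
    if q < p + min_anneal:
        raise NoProductError("primer sites are not in convergent orientation")
    product = fwd.full_seq + template[p + min_anneal : q] + revcomp(rev.full_seq)
    return Amplicon(
        sequence=product, fwd_site=p, rev_site=q, fwd_primer=fwd, rev_primer=rev
    )


def assemble_two_step(
    locus: LocusModel,
    primer_set: PrimerSet,
    template: SegmentedTemplate,
    min_anneal: int = 15,
) -> str:
    """Two-step PCR synthesis of the integration cassette.

    Round 1 amplifies H1 (F1 x R1) and H2 (F2 x R2) from the locus; round 2
    uses H1 and H2 as megaprimers on the cassette template, their appendix
    tails annealing at the template's 5' and 3' ends.  Each appendix overlap
    is counted once, so the cassette is H1 + template interior + H2.
    """
    if not primer_set.ok:
        raise ValueError("cannot assemble from a not-designable primer set")
    tseq = template.sequence
    h1 = in_silico_pcr(locus.sequence, primer_set.f1, primer_set.r1, min_anneal)
    h2 = in_silico_pcr(locus.sequence, primer_set.f2, primer_set.r2, min_anneal)
    head = revcomp(primer_set.r1.appendix_seq)  # template 5' end expected
    tail = primer_set.f2.appendix_seq  # template 3' end expected
    for name, anchor in (("H1 appendix", head), ("H2 appendix", tail)):
        n = _count_occurrences(tseq, anchor)
        if n == 0:
            raise AssemblyError(f"{name} not found on the template")
        if n > 1:
            raise AssemblyError(
                f"{name} occurs {n} times on the template; primer-binding "
                f"sites must be unique (recode one tag copy)"
            )
    if not tseq.startswith(head):
        raise AssemblyError("H1 appendix does not anneal at the template 5' end")
    if not tseq.endswith(tail):
        raise AssemblyError("H2 appendix does not anneal at the template 3' end")
    return h1.sequence + tseq[len(head) : len(tseq) - len(tail)] + h2.sequence


def _terminal_overlap(a: str, b: str, min_overlap: int) -> int:
    """Length of the longest suffix of *a* equal to a prefix of *b* (>= min)."""
    top = min(len(a), len(b))
    for k in range(top, min_overlap - 1, -1):
        if a[-k:] == b[:k]:
            return k
    return 0


def overlap_join(fragments: Sequence[str], min_overlap: int) -> str:
    """Isothermal-style assembly of fragments via unique terminal overlaps.

    Adjacent fragments must share an exact terminal overlap of at least
    ``min_overlap`` bases; the overlap graph must form a single simple path.
    Each shared overlap is counted once in the product.
    """
    n = len(fragments)
    if n < 2:
        raise AssemblyError("need at least two fragments")
    edges: dict[int, tuple[int, int]] = {}  # i -> (j, overlap)
    indeg: dict[int, int] = {i: 0 for i in range(n)}
    for i in range(n):
        hits = []
        for j in range(n):
            if i == j:
                continue
            k = _terminal_overlap(fragments[i], fragments[j], min_overlap)
            if k:
                hits.append((j, k))
        if len(hits) > 1:
            raise AmbiguousAssemblyError(
                f"fragment {i} overlaps {len(hits)} other fragments"
            )
        if hits:
            j, k = hits[0]
            edges[i] = (j, k)
            indeg[j] += 1
    if any(d > 1 for d in indeg.values()):
        raise AmbiguousAssemblyError("a fragment is targeted by multiple overlaps")
    starts = [i for i in range(n) if indeg[i] == 0]
    if len(starts) != 1:
        raise AmbiguousAssemblyError(
            "overlap graph is not a single simple path (cycle or disjoint parts)"
        )
    order = [starts[0]]
    while order[-1] in edges:
        j, _ = edges[order[-1]]
        if j in order:
            raise AmbiguousAssemblyError("overlap graph contains a cycle")
        order.append(j)
    if len(order) != n:
        raise AssemblyError("missing overlap: fragments do not chain into one path")
    out = fragments[order[0]]
    for prev, cur in zip(order, order[1:]):
        _, k = edges[prev]
        out += fragments[cur][k:]
    return out


def integrate(
    locus: LocusModel, cassette: str, primer_set: PrimerSet
) -> LocusModel:
    """Exact double-crossover integration of the cassette into the locus.

    The cassette's terminal genomic arms (H1/H2 without the appendix-derived
    template bases) must each match the locus exactly once; the genomic span
    between them is replaced by the cassette.
    """
    a1 = primer_set.h1_arm
    a2 = primer_set.h2_arm
    if a1 is None or a2 is None:
        raise IntegrationError("primer set lacks arm lengths")
    arm1 = cassette[:a1]
    arm2 = cassette[-a2:]
    seq = locus.sequence
    for name, arm in (("H1", arm1), ("H2", arm2)):
        n = _count_occurrences(seq, arm)
        if n == 0:
            raise IntegrationError(f"{name} arm not found in the locus")
        if n > 1:
            raise IntegrationError(f"{name} arm found {n} times in the locus")
    i1 = seq.find(arm1)
    j2 = seq.find(arm2) + a2
    if j2 - a2 < i1 + a1:
        raise IntegrationError("arms map in the wrong order on the locus")
    return LocusModel(sequence=seq[:i1] + cassette + seq[j2:])


def popout_marker(locus: LocusModel, template: SegmentedTemplate) -> LocusModel:
    """Collapse the template's two direct repeats, excising the marker.

    A.R.M.R.B becomes A.R.B.  A locus that already carries a single repeat
    copy is returned unchanged (the operation is idempotent); a locus with
    no repeat copy at all raises PopoutError.
    """
    repeat = template.repeat_seq
    r = len(repeat)
    seq = locus.sequence
    i = seq.find(repeat)
    if i == -1:
        raise PopoutError("direct repeat not found in the locus")
    j = seq.find(repeat, i + r)
    if j == -1:
        marker = template.marker_seq()
        if marker and marker in seq:
            raise PopoutError(
                "second repeat copy absent or mismatched while the marker "
                "is still present; recombination cannot excise it"
            )
        return locus  # already popped out
    return LocusModel(sequence=seq[: i + r] + seq[j + r :])


def _junction_in_locus(locus: LocusModel, mode: str) -> int:
    if locus.orf_span is None:
        raise ValueError("original locus must carry an orf_span")
    s, e = locus.orf_span
    return s if mode == "N" else e - 3


def verify_scarless(
    original: LocusModel,
    outcome: IntegrationOutcome,
    template: SegmentedTemplate,
    mode: str,
) -> AuditReport:
    """Byte-exact audit that the final locus is the intended scarless fusion.

    Checks: (a) the final locus equals the original with exactly the expected
    payload at the junction; (b) 5'/3' UTR spans are untouched in scarless
    modes; (c) the fusion ORF is in frame with no internal stop codon;
    (d) no marker or heterologous-promoter bases remain in scarless modes.
    Mode C replaces the native stop with the cassette's own stop codon; the
    audit records this substitution as a note rather than a failure.
    """
    seq0 = original.sequence
    j = _junction_in_locus(original, mode)
    skip = junction_skip(mode)
    scarless = mode in ("C", "N")
    payload = template.popped_payload() if scarless else template.sequence
    expected = seq0[:j] + payload + seq0[j + skip :]
    final = outcome.final.sequence
    checks: dict[str, bool] = {}
    notes: list[str] = []

    checks["payload_match"] = final == expected
    delta = len(payload) - skip

    def shifted(span: tuple[int, int] | None) -> str | None:
        if span is None:
            return None
        s, e = span
        if e <= j:
            return final[s:e] if e <= len(final) else None
        s2, e2 = s + delta, e + delta
        return final[s2:e2] if 0 <= s2 <= e2 <= len(final) else None

    if scarless:
        for name, span in (("utr5", original.utr5_span), ("utr3", original.utr3_span)):
            if span is None:
                continue
            s, e = span
            checks[f"{name}_identical"] = shifted(span) == seq0[s:e]

    # fusion reading frame
    s0, e0 = original.orf_span
    if mode == "N":
        fusion = final[s0 : e0 + delta]
    else:  # C or CM: fusion runs from the native start to the payload's stop
        stop_off = _payload_stop_offset(template, payload, mode)
        fusion = final[s0 : j + stop_off]
    checks["frame_ok"] = (
        len(fusion) % 3 == 0
        and fusion.startswith("ATG")
        and fusion[-3:] in STOP_CODONS
        and all(
            fusion[i : i + 3] not in STOP_CODONS
            for i in range(0, len(fusion) - 3, 3)
        )
    )

    if scarless:
        marker = template.marker_seq()
        checks["marker_absent"] = marker is None or marker not in final
        promoter = template.promoter_seq()
        if mode == "N" and promoter is not None:
            checks["promoter_absent"] = promoter not in final
    if mode == "C":
        notes.append("native stop codon replaced by the cassette's stop codon")

    return AuditReport(passed=all(checks.values()), checks=checks, notes=tuple(notes))


def _payload_stop_offset(
    template: SegmentedTemplate, payload: str, mode: str
) -> int:
    """Offset within the payload of the end of its stop codon segment."""
    # walk the popped (or full, for CM) segment list to locate the stop role
    segs: list[Segment] = []
    if mode == "CM" or template.repeat_pair is None:
        segs = list(template.segments)
        lengths = [len(s.sequence) for s in segs]
    else:
        a_label, b_label = template.repeat_pair
        skipping = False
        lengths = []
        for s in template.segments:
            if s.label == a_label:
                segs.append(s)
                lengths.append(len(s.sequence))
                skipping = True
            elif s.label == b_label:
                segs.append(s)
                lengths.append(len(s.sequence) - template.repeat_len)
                skipping = False
            elif not skipping:
                segs.append(s)
                lengths.append(len(s.sequence))
    off = 0
    for s, ln in zip(segs, lengths):
        off += ln
        if s.role == "stop":
            return off
    # no explicit stop segment: assume the payload ends with the stop
    return len(payload)


def simulate_tagging(
    locus: LocusModel,
    primer_set: PrimerSet,
    template: SegmentedTemplate,
    min_anneal: int = 15,
) -> IntegrationOutcome:
    """assemble -> integrate -> (pop out) -> audit, in one call."""
    cassette = assemble_two_step(locus, primer_set, template, min_anneal)
    intermediate = integrate(locus, cassette, primer_set)
    if template.repeat_pair is not None and primer_set.mode in ("C", "N"):
        final = popout_marker(intermediate, template)
    else:
        final = intermediate
    outcome = IntegrationOutcome(intermediate=intermediate, final=final)
    audit = verify_scarless(locus, outcome, template, primer_set.mode)
    return replace(outcome, audit=audit)


def locus_from_assembly(
    assembly: GenomeAssembly,
    orf: OrfRecord,
    flank: int = 700,
    utr_len: int = 200,
) -> LocusModel:
    """Gene-oriented locus (flank + ORF + flank) with annotated spans."""
    chrom = assembly.chromosomes[orf.chromosome]
    lo = max(0, orf.cds_start - 1 - flank)
    hi = min(len(chrom), orf.cds_end + flank)
    seq = chrom[lo:hi]
    if orf.strand == "+":
        s = orf.cds_start - 1 - lo
    else:
        seq = revcomp(seq)
        s = hi - orf.cds_end
    e = s + orf.length
    u5 = (max(0, s - utr_len), s)
    u3 = (e, min(len(seq), e + utr_len))
    return LocusModel(sequence=seq, orf_span=(s, e), utr5_span=u5, utr3_span=u3)


# ---------------------------------------------------------------------------
# template config I/O

def template_to_yaml(template: SegmentedTemplate, path: str) -> None:
    doc = {
        "mode": template.mode,
        "repeat_pair": list(template.repeat_pair) if template.repeat_pair else None,
        "repeat_len": template.repeat_len,
        "segments": [
            {"label": s.label, "role": s.role, "sequence": s.sequence}
            for s in template.segments
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def template_from_yaml(path: str) -> SegmentedTemplate:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SegmentedTemplate(
        segments=tuple(
            Segment(label=s["label"], sequence=s["sequence"].upper(), role=s["role"])
            for s in doc["segments"]
        ),
        mode=doc["mode"],
        repeat_pair=tuple(doc["repeat_pair"]) if doc.get("repeat_pair") else None,
        repeat_len=int(doc.get("repeat_len", 0)),
    )
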