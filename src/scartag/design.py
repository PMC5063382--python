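"""Automated design of the F1/R1/F2/R2/Fc primer quintet for gene tagging.

For one ORF and one tagging mode the designer produces:

* ``R1`` and ``F2`` — junction primers whose binding 5' boundary is pinned at
  the insertion junction.  The binding length grows from ``len_min`` until the
  binding Tm reaches ``tm_min`` and the 3'-terminal base is a GC clamp.  Each
  carries a mode-specific 5' appendix matching one end of the cassette
  template, which turns the first-round homology-arm products H1/H2 into
  megaprimers for the second-round PCR.
* ``F1`` and ``R2`` — distal primers placed so the implied homology arm
  (primer outer 5' end to junction) is at least ``min_arm`` bp.  Candidate
  positions are scanned outward starting at arm = ``min_arm``; the first
  position/length with a GC clamp, sufficient Tm and no hairpin wins, so the
  shortest qualifying arm is chosen and amplicons stay small.
* ``Fc`` — an optional verification primer wholly 5' of F1 (nearest
  qualifying site 50-300 bp upstream); its absence degrades gracefully.

Primers longer than ``max_total_len`` (60 nt) are truncated from the 5' end.
An ORF whose clipped search window cannot host ``min_arm + len_min`` bases is
reported as not designable for telomere proximity, mirroring the "N/A"
entries of a genome-wide design table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from . import thermo
from .genome_io import (
    MODES,
    GenomeAssembly,
    JunctionWindows,
    NotDesignableError,
    OrfRecord,
    extract_windows,
    junction_position,
    junction_skip,
    upstream_sequence,
)
from .thermo import ThermoParams, revcomp

__all__ = [
    "ROLES",
    "DesignConfig",
    "PrimerSpec",
    "PrimerSet",
    "design_junction_primer",
    "design_distal_primer",
    "design_fc_primer",
    "truncate_primer",
    "design_primer_set",
    "genome_wide_design",
    "DesignRun",
    "appendices_for_template",
    "primer_table",
    "write_primer_table",
    "write_primer_fasta",
    "read_primer_table",
]

ROLES = ("F1", "R1", "F2", "R2", "Fc")


@dataclass(frozen=True)
class DesignConfig:
    """Tunable parameters of the design algorithm (defaults: budding yeast)."""

    mode: str = "C"
    window_size: int = 500  # 700 for fission yeast
    min_arm: int = 300
    tm_min: float = 57.0
    len_min: int = 18
    len_max_binding: int = 35
    max_total_len: int = 60
    appendix_r1: str = ""
    appendix_f2: str = ""
    fc_min_offset: int = 50
    fc_max_offset: int = 300
    hairpin_stem: int = 8
    hairpin_loop: int = 3
    thermo: ThermoParams = field(default_factory=ThermoParams)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not self.min_arm < self.window_size:
            raise ValueError("min_arm must be smaller than window_size")
        if self.len_min < 15:
            raise ValueError("len_min must be at least 15")
        if self.max_total_len < self.len_max_binding:
            raise ValueError("max_total_len must be >= len_max_binding")

    def with_(self, **kwargs) -> "DesignConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PrimerSpec:
    """One primer: genome-binding part plus an optional 5' appendix.

    ``tm_binding`` is computed on the binding part only; the appendix never
    enters the Tm.  ``genomic_anchor`` is the 1-based forward-strand
    coordinate of the binding 3' end; ``arm_length`` is set for F1/R2.
    """

    name: str
    role: str
    binding_seq: str
    appendix_seq: str = ""
    tm_binding: float = float("nan")
    genomic_anchor: int | None = None
    arm_length: int | None = None

    @property
    def full_seq(self) -> str:
        return self.appendix_seq + self.binding_seq

    @property
    def display_seq(self) -> str:
        """Appendix uppercase + binding lowercase, the table convention."""
        return self.appendix_seq.upper() + self.binding_seq.lower()


@dataclass(frozen=True)
class PrimerSet:
    orf_name: str
    mode: str
    f1: PrimerSpec | None = None
    r1: PrimerSpec | None = None
    f2: PrimerSpec | None = None
    r2: PrimerSpec | None = None
    fc: PrimerSpec | None = None
    status: str = "ok"  # ok | not_designable
    failure_reason: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    @property
    def primers(self) -> list[PrimerSpec]:
        return [p for p in (self.f1, self.r1, self.f2, self.r2, self.fc) if p]

    @property
    def h1_arm(self) -> int | None:
        return self.f1.arm_length if self.f1 else None

    @property
    def h2_arm(self) -> int | None:
        return self.r2.arm_length if self.r2 else None


def _binding_ok(seq: str, cfg: DesignConfig) -> tuple[bool, bool, bool]:
    """(tm_ok, clamp_ok, hairpin_free) for one candidate binding sequence."""
    tm_ok = thermo.melting_temperature(seq, cfg.thermo) >= cfg.tm_min
    clamp_ok = thermo.has_gc_clamp(seq)
    hp_free = not thermo.hairpin_flag(seq, cfg.hairpin_stem, cfg.hairpin_loop)
    return tm_ok, clamp_ok, hp_free


def design_junction_primer(
    window: JunctionWindows,
    side: str,
    appendix: str,
    cfg: DesignConfig,
) -> PrimerSpec:
    """Design R1 (side='upstream') or F2 (side='downstream').

    The binding 5' boundary is fixed at the junction; length is grown from
    ``len_min`` until Tm and GC-clamp requirements are met, rejecting
    hairpin-prone candidates along the way.
    """
    if side == "upstream":
        source, role = window.upstream, "R1"
    elif side == "downstream":
        source, role = window.downstream, "F2"
    else:
        raise ValueError("side must be 'upstream' or 'downstream'")
    if len(source) < cfg.len_min:
        raise NotDesignableError(
            f"{role}: fewer than {cfg.len_min} bases adjacent to the junction"
        )
    saw_qualifying = False
    top = min(cfg.len_max_binding, len(source))
    for k in range(cfg.len_min, top + 1):
        binding = revcomp(source[-k:]) if role == "R1" else source[:k]
        tm_ok, clamp_ok, hp_free = _binding_ok(binding, cfg)
        if tm_ok and clamp_ok:
            saw_qualifying = True
            if hp_free:
                tm = thermo.melting_temperature(binding, cfg.thermo)
                return PrimerSpec(
                    name="", role=role, binding_seq=binding,
                    appendix_seq=appendix, tm_binding=tm,
                )
    if saw_qualifying:
        raise NotDesignableError(f"{role}: hairpin at all candidate lengths")
    raise NotDesignableError(
        f"{role}: no binding length in [{cfg.len_min}, {top}] reaches "
        f"Tm {cfg.tm_min} C with a GC clamp"
    )


def design_distal_primer(
    window: JunctionWindows, side: str, cfg: DesignConfig
) -> PrimerSpec:
    """Design F1 (side='upstream') or R2 (side='downstream').

    Candidates are ordered by (arm length ascending, binding length
    ascending); the first with clamp, Tm and no hairpin is selected.
    """
    if side == "upstream":
        source, role = window.upstream, "F1"
    elif side == "downstream":
        source, role = window.downstream, "R2"
    else:
        raise ValueError("side must be 'upstream' or 'downstream'")
    w = len(source)
    if w < cfg.min_arm + cfg.len_min:
        raise NotDesignableError(f"{role}: telomere proximity")
    for arm in range(cfg.min_arm, w + 1):
        for k in range(cfg.len_min, min(cfg.len_max_binding, arm) + 1):
            if role == "F1":
                binding = source[w - arm : w - arm + k]
            else:
                binding = revcomp(source[arm - k : arm])
            tm_ok, clamp_ok, hp_free = _binding_ok(binding, cfg)
            if tm_ok and clamp_ok and hp_free:
                tm = thermo.melting_temperature(binding, cfg.thermo)
                return PrimerSpec(
                    name="", role=role, binding_seq=binding,
                    tm_binding=tm, arm_length=arm,
                )
    raise NotDesignableError(
        f"{role}: no GC-clamp site with Tm >= {cfg.tm_min} C in the window"
    )


def design_fc_primer(
    window_extension: str, f1: PrimerSpec, cfg: DesignConfig
) -> PrimerSpec | None:
    """Design the colony-PCR verification primer Fc, wholly 5' of F1.

    *window_extension* is the gene-oriented sequence ending at the junction
    (it must span at least F1's arm).  The nearest qualifying site with a
    3'-end 50-300 bp (configurable) upstream of F1's 5' end is taken.
    Returns None when no site qualifies; the primer set stays valid.
    """
    if f1.arm_length is None:
        raise ValueError("F1 must carry an arm_length")
    n = len(window_extension)
    f1_start = n - f1.arm_length  # index of F1's 5' base
    for offset in range(cfg.fc_min_offset, cfg.fc_max_offset + 1):
        p = f1_start - offset  # exclusive end of the Fc binding site
        if p < cfg.len_min:
            break
        for k in range(cfg.len_min, min(cfg.len_max_binding, p) + 1):
            binding = window_extension[p - k : p]
            tm_ok, clamp_ok, hp_free = _binding_ok(binding, cfg)
            if tm_ok and clamp_ok and hp_free:
                tm = thermo.melting_temperature(binding, cfg.thermo)
                return PrimerSpec(
                    name="", role="Fc", binding_seq=binding, tm_binding=tm
                )
    return None


def truncate_primer(p: PrimerSpec, max_total_len: int, cfg: DesignConfig) -> PrimerSpec:
    """Trim bases from the 5' end until the full sequence fits max_total_len.

    The appendix shrinks first; the binding 3' end never moves.  Tm is
    recomputed when binding bases are removed.
    """
    excess = len(p.full_seq) - max_total_len
    if excess <= 0:
        return p
    if excess <= len(p.appendix_seq):
        return replace(p, appendix_seq=p.appendix_seq[excess:])
    cut = excess - len(p.appendix_seq)
    binding = p.binding_seq[cut:]
    if len(binding) < cfg.len_min:
        raise NotDesignableError(
            f"{p.role}: truncation to {max_total_len} nt leaves fewer than "
            f"{cfg.len_min} binding bases"
        )
    tm = thermo.melting_temperature(binding, cfg.thermo)
    return replace(p, appendix_seq="", binding_seq=binding, tm_binding=tm)


def _anchor_maps(orf: OrfRecord, windows: JunctionWindows):
    """Functions mapping window indices to 1-based forward coordinates."""
    k, s = windows.junction, windows.skip
    wu, wd = len(windows.upstream), len(windows.downstream)
    if orf.strand == "+":
        up = lambda i: k - wu + i + 1
        down = lambda i: k + s + i + 1
    else:
        up = lambda i: k + wu - i
        down = lambda i: k - s - i
    return up, down


def design_primer_set(
    assembly: GenomeAssembly,
    orf: OrfRecord,
    mode: str,
    cfg: DesignConfig,
) -> PrimerSet:
    """Run the full per-ORF design; failures become data, not exceptions."""
    cfg = cfg if cfg.mode == mode else cfg.with_(mode=mode)
    try:
        windows = extract_windows(assembly, orf, mode, cfg.window_size)
        f1 = design_distal_primer(windows, "upstream", cfg)
        r2 = design_distal_primer(windows, "downstream", cfg)
        r1 = design_junction_primer(windows, "upstream", cfg.appendix_r1, cfg)
        f2 = design_junction_primer(windows, "downstream", cfg.appendix_f2, cfg)
        ext_len = f1.arm_length + cfg.fc_max_offset + cfg.len_max_binding
        extension = upstream_sequence(assembly, orf, mode, ext_len)
        fc = design_fc_primer(extension, f1, cfg)

        up_map, down_map = _anchor_maps(orf, windows)
        wu, wd = len(windows.upstream), len(windows.downstream)
        f1 = replace(f1, genomic_anchor=up_map(wu - f1.arm_length + len(f1.binding_seq) - 1))
        r1 = replace(r1, genomic_anchor=up_map(wu - len(r1.binding_seq)))
        f2 = replace(f2, genomic_anchor=down_map(len(f2.binding_seq) - 1))
        r2 = replace(r2, genomic_anchor=down_map(r2.arm_length - len(r2.binding_seq)))
        if fc is not None:
            # the extension ends at the junction just like the upstream window
            site_end = _fc_site_end(extension, fc, f1, cfg)
            fc = replace(fc, genomic_anchor=up_map(wu - (len(extension) - site_end) - 1))

        primers = {}
        for p in (f1, r1, f2, r2) + ((fc,) if fc else ()):
            p = truncate_primer(p, cfg.max_total_len, cfg)
            p = replace(p, name=f"{orf.name}_{mode}_{p.role}")
            primers[p.role] = p
        return PrimerSet(
            orf_name=orf.name,
            mode=mode,
            f1=primers["F1"],
            r1=primers["R1"],
            f2=primers["F2"],
            r2=primers["R2"],
            fc=primers.get("Fc"),
        )
    except NotDesignableError as exc:
        return PrimerSet(
            orf_name=orf.name,
            mode=mode,
            status="not_designable",
            failure_reason=exc.reason,
        )


def _fc_site_end(extension: str, fc: PrimerSpec, f1: PrimerSpec, cfg: DesignConfig) -> int:
    """Exclusive end index of Fc's binding site within the extension."""
    f1_start = len(extension) - f1.arm_length
    # Re-locate by scanning offsets the same way design_fc_primer does.
    k = len(fc.binding_seq)
    for offset in range(cfg.fc_min_offset, cfg.fc_max_offset + 1):
        p = f1_start - offset
        if p < k:
            break
        if extension[p - k : p] == fc.binding_seq:
            return p
    raise RuntimeError("Fc binding site not found in its own search region")


@dataclass
class DesignRun:
    sets: list[PrimerSet]
    n_ok: int
    n_failed: int
    failures: pd.DataFrame  # columns: orf, mode, reason


def genome_wide_design(
    assembly: GenomeAssembly,
    orfs: Sequence[OrfRecord],
    mode: str,
    cfg: DesignConfig,
) -> DesignRun:
    """Design primers for every ORF in input order; deterministic output."""
    sets = [design_primer_set(assembly, orf, mode, cfg) for orf in orfs]
    fails = [
        {"orf": s.orf_name, "mode": s.mode, "reason": s.failure_reason}
        for s in sets
        if not s.ok
    ]
    return DesignRun(
        sets=sets,
        n_ok=sum(s.ok for s in sets),
        n_failed=len(fails),
        failures=pd.DataFrame(fails, columns=["orf", "mode", "reason"]),
    )


def appendices_for_template(template_seq: str, length: int = 25) -> tuple[str, str]:
    """(R1 appendix, F2 appendix) matching a cassette template's ends.

    R1's appendix is the reverse complement of the template's first *length*
    bases (so H1's sense strand ends with the template start); F2's appendix
    is the template's last *length* bases.
    """
    if len(template_seq) < 2 * length:
        raise ValueError("template shorter than twice the appendix length")
    return revcomp(template_seq[:length]), template_seq[-length:]


# ---------------------------------------------------------------------------
# table / FASTA output

_TABLE_COLUMNS = ["orf", "mode", "role", "sequence", "tm", "arm_length", "status"]


def primer_table(sets: Iterable[PrimerSet]) -> pd.DataFrame:
    rows = []
    for s in sets:
        if s.ok:
            for p in s.primers:
                rows.append(
                    {
                        "orf": s.orf_name,
                        "mode": s.mode,
                        "role": p.role,
                        "sequence": p.display_seq,
                        "tm": round(p.tm_binding, 4),
                        "arm_length": p.arm_length if p.arm_length else "n/a",
                        "status": "ok",
                    }
                )
        else:
            rows.append(
                {
                    "orf": s.orf_name,
                    "mode": s.mode,
                    "role": "N/A",
                    "sequence": "N/A",
                    "tm": "N/A",
                    "arm_length": "N/A",
                    "status": f"not_designable:{s.failure_reason}",
                }
            )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_primer_table(sets: Iterable[PrimerSet], path: str) -> None:
    primer_table(sets).to_csv(path, sep="\t", index=False)


def write_primer_fasta(sets: Iterable[PrimerSet], path: str) -> None:
    with open(path, "w") as fh:
        for s in sets:
            if not s.ok:
                continue
            for p in s.primers:
                fh.write(f">{p.name}\n{p.full_seq}\n")


def read_primer_table(path: str) -> list[PrimerSet]:
    """Re-parse a primer TSV back into PrimerSet objects (round-trip)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    sets: list[PrimerSet] = []
    for (orf, mode), group in df.groupby(["orf", "mode"], sort=False):
        first = group.iloc[0]
        if first["status"].startswith("not_designable"):
            reason = first["status"].split(":", 1)[1] if ":" in first["status"] else ""
            sets.append(
                PrimerSet(orf_name=orf, mode=mode, status="not_designable",
                          failure_reason=reason)
            )
            continue
        primers = {}
        for _, row in group.iterrows():
            seq = row["sequence"]
            appendix = "".join(c for c in seq if c.isupper())
            binding = "".join(c for c in seq if c.islower()).upper()
            arm = row["arm_length"]
            primers[row["role"]] = PrimerSpec(
                name=f"{orf}_{mode}_{row['role']}",
                role=row["role"],
                binding_seq=binding,
                appendix_seq=appendix,
                tm_binding=float(row["tm"]),
                arm_length=None if arm == "n/a" else int(arm),
            )
        sets.append(
            PrimerSet(
                orf_name=orf, mode=mode,
                f1=primers.get("F1"), r1=primers.get("R1"),
                f2=primers.get("F2"), r2=primers.get("R2"),
                fc=primers.get("Fc"),
            )
        )
    return sets
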