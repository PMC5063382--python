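"""Nearest-neighbor oligonucleotide thermodynamics and primer quality screens.

Melting temperatures are computed from a 16-stack nearest-neighbor table of
helix-formation enthalpies and entropies (Breslauer-style parameters), combined
with an entropy initiation correction, a primer-concentration term, a
16.6*log10([Na+]) salt correction and a small empirical offset calibrated
against a commercial primer-design program:

    Tm = 1000*dH / (dS - ds_init + R*ln([primer]/4)) - 273.15
         + 16.6*log10([Na+]) + c

with dH in kcal/mol, dS in cal/(K*mol), R = 1.987 cal/(K*mol), and Tm in
degrees Celsius.  Only the genome-binding portion of a primer is ever passed
to these functions; 5' appendix tails do not contribute to Tm.

The module also provides the two sequence-quality screens used during primer
selection: a GC clamp test (3'-terminal base is G or C) and an exact-match
hairpin scan (two reverse-complementary stems separated by a minimal loop).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

__all__ = [
    "DNA_BASES",
    "InvalidSequenceError",
    "ThermoDomainError",
    "ThermoParams",
    "ThermoResult",
    "revcomp",
    "load_nn_table",
    "duplex_thermo",
    "melting_temperature",
    "has_gc_clamp",
    "hairpin_flag",
]

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Gas constant in cal/(K*mol).
GAS_CONSTANT = 1.987


class InvalidSequenceError(ValueError):
    """Raised when a sequence is empty, too short, or has non-ACGT letters."""


class ThermoDomainError(ValueError):
    """Raised when the Tm denominator is numerically degenerate."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, min_len: int = 1) -> None:
    if len(seq) < min_len:
        raise InvalidSequenceError(
            f"sequence of length {len(seq)} shorter than required {min_len}"
        )
    if any(b not in DNA_BASES for b in seq):
        raise InvalidSequenceError(f"sequence contains non-ACGT letters: {seq!r}")


def load_nn_table(path: str | None = None) -> dict[str, tuple[float, float]]:
    """Load a nearest-neighbor table (stack -> (dH, dS)) from a TSV file.

    Without an explicit *path* the packaged Breslauer-style table is used.
    The file has a header line and three columns: stack, dH (kcal/mol) and
    dS (cal/(K*mol)).
    """
    if path is None:
        text = (
            resources.files("scartag").joinpath("data/nn_breslauer.tsv").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, tuple[float, float]] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for line in lines[1:]:
        stack, dh, ds = line.split("\t")
        table[stack.strip().upper()] = (float(dh), float(ds))
    _validate_nn_table(table)
    return table


def _validate_nn_table(table: Mapping[str, tuple[float, float]]) -> None:
    expected = {a + b for a in DNA_BASES for b in DNA_BASES}
    if set(table) != expected:
        missing = expected - set(table)
        extra = set(table) - expected
        raise ValueError(
            f"nearest-neighbor table must cover all 16 stacks; "
            f"missing={sorted(missing)}, unexpected={sorted(extra)}"
        )


@dataclass(frozen=True)
class ThermoParams:
    """Constants of the melting-temperature model.

    Defaults reproduce the published calculation: 1 uM primer, 50 mM Na+,
    entropy initiation 10.8 cal/(K*mol) and empirical offset c = 0.1518 C.
    """

    nn_table: Mapping[str, tuple[float, float]] = field(
        default_factory=load_nn_table
    )
    ds_init: float = 10.8
    gas_constant: float = GAS_CONSTANT
    primer_conc: float = 1e-6
    na_conc: float = 0.05
    c: float = 0.1518

    def __post_init__(self) -> None:
        if self.primer_conc <= 0 or self.na_conc <= 0:
            raise ValueError("primer_conc and na_conc must be strictly positive")
        _validate_nn_table(self.nn_table)

    def with_(self, **kwargs) -> "ThermoParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ThermoResult:
    dH: float  # kcal/mol
    dS: float  # cal/(K*mol)
    tm: float  # degrees C


def duplex_thermo(
    seq: str, params: ThermoParams | None = None
) -> tuple[float, float]:
    """Sum nearest-neighbor (dH, dS) over the len-1 dinucleotide stacks of seq."""
    params = params or ThermoParams()
    _check_dna(seq, min_len=2)
    dh = 0.0
    ds = 0.0
    for i in range(len(seq) - 1):
        h, s = params.nn_table[seq[i : i + 2]]
        dh += h
        ds += s
    return dh, ds


def melting_temperature(seq: str, params: ThermoParams | None = None) -> float:
    """Tm in degrees C of the duplex formed by *seq* and its exact complement.

    Callers must strip any 5' appendix before calling: the appendix tail is
    not part of the genome-annealing duplex and never contributes to Tm.
    """
    params = params or ThermoParams()
    dh, ds = duplex_thermo(seq, params)
    denom = ds - params.ds_init + params.gas_constant * math.log(
        params.primer_conc / 4.0
    )
    if abs(denom) < 1e-9:
        raise ThermoDomainError("Tm denominator is zero or near zero")
    return (
        1000.0 * dh / denom
        - 273.15
        + 16.6 * math.log10(params.na_conc)
        + params.c
    )


def thermo_result(seq: str, params: ThermoParams | None = None) -> ThermoResult:
    """Convenience bundle of (dH, dS, Tm) for one sequence."""
    params = params or ThermoParams()
    dh, ds = duplex_thermo(seq, params)
    return ThermoResult(dH=dh, dS=ds, tm=melting_temperature(seq, params))


def has_gc_clamp(seq: str) -> bool:
    """True iff the 3'-terminal base is G or C."""
    _check_dna(seq, min_len=1)
    return seq[-1] in "GC"


def hairpin_flag(seq: str, stem_min: int = 4, loop_min: int = 3) -> bool:
    """True iff *seq* can fold into a hairpin with an exact-complement stem.

    A hairpin exists when two non-overlapping subsequences of length
    >= stem_min are reverse complements of each other and are separated by
    >= loop_min intervening bases.  Sequences shorter than
    2*stem_min + loop_min cannot fold and return False.

    Scanning stems of exactly stem_min bases is complete: any longer stem
    contains a stem_min-long sub-stem whose loop is at least as long.
    """
    _check_dna(seq, min_len=1)
    n = len(seq)
    if n < 2 * stem_min + loop_min:
        return False
    s = stem_min
    for i in range(n - 2 * s - loop_min + 1):
        target = revcomp(seq[i : i + s])
        if seq.find(target, i + s + loop_min) != -1:
            return True
    return False
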