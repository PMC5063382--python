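"""The five-primer design algorithm: selection rules, invariants, outputs."""

import dataclasses

import numpy as np
import pytest

from scartag import design as dz
from scartag import thermo
from scartag.design import (
    DesignConfig,
    PrimerSpec,
    appendices_for_template,
    design_distal_primer,
    design_fc_primer,
    design_junction_primer,
    design_primer_set,
    genome_wide_design,
    truncate_primer,
)
from scartag.genome_io import (
    GenomeAssembly,
    JunctionWindows,
    NotDesignableError,
    OrfRecord,
)

from conftest import rc


def _window(upstream: str, downstream: str, mode: str = "CM") -> JunctionWindows:
    orf = OrfRecord("TST", "c1", "+", 1, 3)
    return JunctionWindows(
        orf=orf, mode=mode, upstream=upstream, downstream=downstream,
        junction=len(upstream), skip=0, window_size=max(len(upstream), len(downstream)),
    )


def _qualifies(seq: str, cfg: DesignConfig) -> bool:
    return (
        thermo.melting_temperature(seq, cfg.thermo) >= cfg.tm_min
        and thermo.has_gc_clamp(seq)
        and not thermo.hairpin_flag(seq, cfg.hairpin_stem, cfg.hairpin_loop)
    )


# ---------------------------------------------------------------------------
# junction primers (R1 / F2)

def test_junction_primer_accepts_first_qualifying_length():
    # GC-rich window: the len_min-mer next to the junction already qualifies
    down = ("GC" * 40) + "ATAT"
    cfg = DesignConfig(mode="CM", appendix_r1="AAAA", appendix_f2="TTTT")
    p = design_junction_primer(_window("A" * 80, down), "downstream", "TTTT", cfg)
    assert p.role == "F2"
    assert len(p.binding_seq) == cfg.len_min
    assert p.binding_seq == down[: cfg.len_min]


def test_junction_primer_extension_matches_exhaustive_scan():
    rng = np.random.default_rng(5)
    cfg = DesignConfig(mode="CM")
    for _ in range(25):
        # AT-biased windows force extension beyond len_min
        down = "".join(rng.choice(list("ACGT"), size=60, p=[0.35, 0.15, 0.15, 0.35]))
        expected = next(
            (k for k in range(cfg.len_min, cfg.len_max_binding + 1)
             if _qualifies(down[:k], cfg)),
            None,
        )
        if expected is None:
            with pytest.raises(NotDesignableError):
                design_junction_primer(_window("A" * 60, down), "downstream", "", cfg)
        else:
            p = design_junction_primer(_window("A" * 60, down), "downstream", "", cfg)
            assert len(p.binding_seq) == expected


def test_r1_binding_is_revcomp_of_window_tail():
    rng = np.random.default_rng(6)
    up = "".join(rng.choice(list("ACGT"), size=80))
    cfg = DesignConfig(mode="CM", appendix_r1="GGGG")
    p = design_junction_primer(_window(up, "A" * 30), "upstream", "GGGG", cfg)
    k = len(p.binding_seq)
    assert p.binding_seq == rc(up[-k:])
    assert p.appendix_seq == "GGGG"
    assert p.full_seq == "GGGG" + p.binding_seq


def test_junction_primer_needs_len_min_bases():
    cfg = DesignConfig(mode="CM")
    with pytest.raises(NotDesignableError):
        design_junction_primer(_window("A" * 80, "GCGCGC"), "downstream", "", cfg)


# ---------------------------------------------------------------------------
# distal primers (F1 / R2)

def _bruteforce_distal(source: str, role: str, cfg: DesignConfig):
    """Enumerate every (arm, length) candidate; first in scan order wins."""
    w = len(source)
    for arm in range(cfg.min_arm, w + 1):
        for k in range(cfg.len_min, min(cfg.len_max_binding, arm) + 1):
            if role == "F1":
                seq = source[w - arm : w - arm + k]
            else:
                seq = rc(source[arm - k : arm])
            if _qualifies(seq, cfg):
                return arm, seq
    return None


@pytest.mark.parametrize("role,side", [("F1", "upstream"), ("R2", "downstream")])
def test_distal_primer_matches_bruteforce_on_random_windows(role, side):
    rng = np.random.default_rng(9)
    cfg = DesignConfig(mode="CM")
    n_checked = 0
    for _ in range(20):
        source = "".join(rng.choice(list("ACGT"), size=500,
                                    p=[0.31, 0.19, 0.19, 0.31]))
        win = _window(source, source)
        expected = _bruteforce_distal(source, role, cfg)
        if expected is None:
            with pytest.raises(NotDesignableError):
                design_distal_primer(win, side, cfg)
        else:
            p = design_distal_primer(win, side, cfg)
            assert (p.arm_length, p.binding_seq) == expected
            n_checked += 1
    assert n_checked >= 15  # nearly all random windows host a site


def test_distal_primer_shortest_qualifying_arm_wins():
    # clamps only far out: pad the arm region with A/T so arm=min_arm fails
    rng = np.random.default_rng(10)
    inner = "AT" * 180  # junction-proximal 360 bases without any G/C
    outer = "".join(rng.choice(list("ACGT"), size=140))
    source = (outer + inner)  # F1 scans from position len-300 outward
    cfg = DesignConfig(mode="CM")
    expected = _bruteforce_distal(source, "F1", cfg)
    if expected is not None:
        p = design_distal_primer(_window(source, "A" * 400), "upstream", cfg)
        assert p.arm_length == expected[0] > cfg.min_arm


def test_telomere_proximity_is_not_designable():
    cfg = DesignConfig(mode="CM")
    short = "GC" * 150  # 300 < min_arm + len_min
    with pytest.raises(NotDesignableError, match="telomere"):
        design_distal_primer(_window(short, short), "downstream", cfg)


# ---------------------------------------------------------------------------
# Fc

def test_fc_omitted_when_no_upstream_sequence():
    f1 = PrimerSpec(name="x", role="F1", binding_seq="ATGC" * 5, arm_length=300)
    cfg = DesignConfig(mode="CM")
    assert design_fc_primer("G" * 300, f1, cfg) is None  # extension == arm only


def test_fc_sits_wholly_upstream_of_f1_on_random_fixtures():
    rng = np.random.default_rng(12)
    cfg = DesignConfig(mode="CM")
    found = 0
    for _ in range(100):
        ext = "".join(rng.choice(list("ACGT"), size=700,
                                 p=[0.31, 0.19, 0.19, 0.31]))
        f1 = PrimerSpec(name="x", role="F1", binding_seq=ext[400:425],
                        arm_length=300)
        fc = design_fc_primer(ext, f1, cfg)
        if fc is None:
            continue
        found += 1
        site = ext.rfind(fc.binding_seq, 0, 400)
        assert site != -1  # binds before F1's 5' end
        gap = 400 - (site + len(fc.binding_seq))
        assert cfg.fc_min_offset <= gap <= cfg.fc_max_offset
        assert fc.appendix_seq == ""
    assert found >= 80


# ---------------------------------------------------------------------------
# truncation

def test_truncation_arithmetic():
    cfg = DesignConfig(mode="CM")
    rng = np.random.default_rng(2)
    b40 = "".join(rng.choice(list("ACGT"), size=40))
    p58 = PrimerSpec(name="a", role="R1", binding_seq=b40[:33],
                     appendix_seq="G" * 25)
    assert truncate_primer(p58, 60, cfg) == p58  # 58 nt: untouched

    p65 = PrimerSpec(name="b", role="R1", binding_seq=b40, appendix_seq="G" * 25)
    t = truncate_primer(p65, 60, cfg)
    assert len(t.full_seq) == 60 and len(t.appendix_seq) == 20
    assert t.binding_seq == b40  # binding untouched, 3' end fixed

    p75 = PrimerSpec(name="c", role="R1", binding_seq=b40[:30],
                     appendix_seq="G" * 45)
    t = truncate_primer(p75, 60, cfg)
    assert len(t.full_seq) == 60 and len(t.appendix_seq) == 30
    assert t.binding_seq == b40[:30]

    deep = PrimerSpec(name="d", role="R1", binding_seq=b40[:30], appendix_seq="G" * 5)
    with pytest.raises(NotDesignableError):
        truncate_primer(deep, 15, cfg)  # would leave < len_min binding bases
    cut = truncate_primer(deep, 25, cfg)  # appendix gone, binding trimmed to 25
    assert cut.appendix_seq == "" and cut.binding_seq == b40[5:30]


# ---------------------------------------------------------------------------
# per-ORF and genome-wide design

def test_primer_set_names_follow_orf_mode_role(genome20, configs):
    assembly, orfs, truth = genome20
    orf = next(o for o in orfs
               if truth.set_index("name").loc[o.name, "designable_CM"])
    s = design_primer_set(assembly, orf, "CM", configs["CM"])
    assert s.ok
    assert [p.name for p in s.primers] == [
        f"{orf.name}_CM_{r}" for r in ("F1", "R1", "F2", "R2", "Fc")
    ]


def test_design_is_deterministic(genome20, configs):
    assembly, orfs, _ = genome20
    a = design_primer_set(assembly, orfs[0], "C", configs["C"])
    b = design_primer_set(assembly, orfs[0], "C", configs["C"])
    assert a == b


@pytest.mark.parametrize("mode", ["CM", "C", "N"])
def test_genome_wide_counts_against_placement_truth(genome20, configs, mode):
    """Placement truth is an exact predictor of telomere failures and an
    upper bound on designability: the only failures beyond it are
    thermodynamic (Tm/clamp/hairpin), never telomeric."""
    assembly, orfs, truth = genome20
    run = genome_wide_design(assembly, orfs, mode, configs[mode])
    assert run.n_ok + run.n_failed == len(orfs)
    sets_by_name = {s.orf_name: s for s in run.sets}
    for _, row in truth.iterrows():
        s = sets_by_name[row["name"]]
        if not row[f"designable_{mode}"]:
            assert not s.ok and "telomere" in s.failure_reason
        elif not s.ok:
            assert "telomere" not in s.failure_reason


def test_empty_orf_list_gives_empty_table(genome20, configs):
    assembly, _, _ = genome20
    run = genome_wide_design(assembly, [], "C", configs["C"])
    assert run.sets == [] and run.n_ok == 0


@pytest.mark.parametrize("mode", ["CM", "C", "N"])
def test_design_invariants_hold_for_every_ok_set(genome20, configs, mode):
    assembly, orfs, _ = genome20
    cfg = configs[mode]
    run = genome_wide_design(assembly, orfs, mode, cfg)
    assert run.n_ok > 0
    for s in run.sets:
        if not s.ok:
            continue
        assert s.h1_arm >= cfg.min_arm and s.h2_arm >= cfg.min_arm
        for p in s.primers:
            assert len(p.full_seq) <= cfg.max_total_len
            assert p.tm_binding >= cfg.tm_min
        assert s.r1.appendix_seq == cfg.appendix_r1
        assert s.f2.appendix_seq == cfg.appendix_f2
        assert s.f1.appendix_seq == s.r2.appendix_seq == ""
        if s.fc:
            assert s.fc.appendix_seq == ""


def _single_orf_assembly(pad5: str, orf_seq: str, pad3: str):
    chrom = pad5 + orf_seq + pad3
    orf = OrfRecord("SOLO", "c1", "+", len(pad5) + 1, len(pad5) + len(orf_seq))
    return GenomeAssembly(chromosomes={"c1": chrom}), orf


def test_translation_invariance(configs):
    rng = np.random.default_rng(21)
    # build a valid 402-bp ORF: ATG + 132 stop-free codons + TAA
    codons = []
    while len(codons) < 132:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in ("TAA", "TAG", "TGA"):
            codons.append(c)
    orf_seq = "ATG" + "".join(codons) + "TAA"
    pad5 = "".join(rng.choice(list("ACGT"), size=900))
    pad3 = "".join(rng.choice(list("ACGT"), size=900))
    shift = "".join(rng.choice(list("ACGT"), size=1000))
    a1, o1 = _single_orf_assembly(pad5, orf_seq, pad3)
    a2, o2 = _single_orf_assembly(shift + pad5, orf_seq, pad3)
    for mode in ("CM", "C", "N"):
        s1 = design_primer_set(a1, o1, mode, configs[mode])
        s2 = design_primer_set(a2, o2, mode, configs[mode])
        assert s1.ok and s2.ok
        for p1, p2 in zip(s1.primers, s2.primers):
            assert p1.full_seq == p2.full_seq


def test_strand_invariance(genome20, configs):
    assembly, orfs, truth = genome20
    designable = truth.set_index("name")
    orf = next(o for o in orfs if o.strand == "+"
               and designable.loc[o.name, "designable_C"])
    chrom = assembly.chromosomes[orf.chromosome]
    n = len(chrom)
    flipped = GenomeAssembly(chromosomes={orf.chromosome: rc(chrom)})
    mirrored = OrfRecord(orf.name, orf.chromosome, "-",
                         n - orf.cds_end + 1, n - orf.cds_start + 1)
    for mode in ("CM", "C", "N"):
        s1 = design_primer_set(assembly, orf, mode, configs[mode])
        s2 = design_primer_set(flipped, mirrored, mode, configs[mode])
        assert s1.ok and s2.ok
        for p1, p2 in zip(s1.primers, s2.primers):
            assert p1.full_seq == p2.full_seq


# ---------------------------------------------------------------------------
# table / FASTA output

def test_primer_table_rows_and_case_convention(genome20, configs, tmp_path):
    assembly, orfs, truth = genome20
    orf = next(o for o in orfs
               if truth.set_index("name").loc[o.name, "designable_C"])
    s = design_primer_set(assembly, orf, "C", configs["C"])
    df = dz.primer_table([s])
    assert len(df) == 5
    r1_row = df[df.role == "R1"].iloc[0]
    upper_prefix = "".join(c for c in r1_row.sequence if c.isupper())
    assert upper_prefix == configs["C"].appendix_r1
    assert r1_row.sequence == r1_row.sequence[: len(upper_prefix)] + \
        r1_row.sequence[len(upper_prefix):].lower()


def test_primer_table_round_trip(genome20, configs, tmp_path):
    assembly, orfs, _ = genome20
    run = genome_wide_design(assembly, orfs, "N", configs["N"])
    path = tmp_path / "primers.tsv"
    dz.write_primer_table(run.sets, str(path))
    back = dz.read_primer_table(str(path))
    assert len(back) == len(run.sets)
    for s0, s1 in zip(run.sets, back):
        assert (s0.orf_name, s0.mode, s0.status) == (s1.orf_name, s1.mode, s1.status)
        if s0.ok:
            for p0, p1 in zip(s0.primers, s1.primers):
                assert (p0.role, p0.full_seq, p0.arm_length) == (
                    p1.role, p1.full_seq, p1.arm_length
                )
                assert p1.tm_binding == pytest.approx(p0.tm_binding, abs=1e-4)


def test_fasta_export_contains_every_ok_primer(genome20, configs, tmp_path):
    assembly, orfs, _ = genome20
    run = genome_wide_design(assembly, orfs[:5], "C", configs["C"])
    path = tmp_path / "primers.fasta"
    dz.write_primer_fasta(run.sets, str(path))
    text = path.read_text()
    for s in run.sets:
        if s.ok:
            for p in s.primers:
                assert f">{p.name}\n{p.full_seq}\n" in text


def test_appendices_for_template(templates):
    tmpl = templates["C"].sequence
    r1, f2 = appendices_for_template(tmpl, length=25)
    assert r1 == rc(tmpl[:25])
    assert f2 == tmpl[-25:]
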