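"""Shared fixtures: a seeded synthetic genome, cassette templates, configs."""

import pytest

from scartag import design as dz
from scartag import fixtures as fx

# independent reverse complement used by test oracles (kept separate from the
# package helper on purpose)
_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


@pytest.fixture(scope="session")
def genome20():
    """Seeded 20-ORF genome with 2 undesignable telomere-proximal ORFs."""
    spec = fx.FixtureSpec(seed=7, n_chromosomes=2, n_orfs=20, n_telomere_proximal=2)
    assembly, orfs, truth = fx.make_genome(spec)
    return assembly, orfs, truth


@pytest.fixture(scope="session")
def templates():
    return {mode: fx.make_template(mode, seed=11) for mode in ("CM", "C", "N")}


@pytest.fixture(scope="session")
def configs(templates):
    cfgs = {}
    for mode, tmpl in templates.items():
        r1, f2 = dz.appendices_for_template(tmpl.sequence)
        cfgs[mode] = dz.DesignConfig(mode=mode, appendix_r1=r1, appendix_f2=f2)
    return cfgs


@pytest.fixture(scope="session")
def genome_gb(genome20, tmp_path_factory):
    """The 20-ORF genome written to a GenBank file."""
    assembly, orfs, _ = genome20
    path = tmp_path_factory.mktemp("gb") / "genome.gb"
    fx.write_genome_genbank(assembly, orfs, str(path))
    return str(path)
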