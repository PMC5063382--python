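"""Design the five tagging primers for every ORF of a synthetic genome.

Builds a seeded toy genome (50 ORFs, 3 deliberately telomere-proximal),
derives the R1/F2 appendices from a scarless C-terminal cassette template,
and runs the genome-wide design.  Telomere-proximal ORFs come back
not-designable: no >=300-bp homology arm fits in their clipped windows.
"""

from scartag import DesignConfig, appendices_for_template, genome_wide_design
from scartag.fixtures import FixtureSpec, make_genome, make_template

assembly, orfs, truth = make_genome(
    FixtureSpec(seed=1, n_chromosomes=3, n_orfs=50, n_telomere_proximal=3)
)
template = make_template("C", seed=1)
appendix_r1, appendix_f2 = appendices_for_template(template.sequence)
cfg = DesignConfig(mode="C", appendix_r1=appendix_r1, appendix_f2=appendix_f2)

run = genome_wide_design(assembly, orfs, "C", cfg)
print(f"{run.n_ok} ORFs designable, {run.n_failed} not designable")
print(run.failures.to_string(index=False))

s = next(x for x in run.sets if x.ok)
print(f"\nprimer set for {s.orf_name} (H1 arm {s.h1_arm} bp, H2 arm {s.h2_arm} bp):")
for p in s.primers:
    # appendix in uppercase, genome-binding part in lowercase
    print(f"  {p.name:<16} {len(p.full_seq):>2} nt  Tm {p.tm_binding:5.2f} C  "
          f"{p.display_seq}")
# R1 and F2 carry the cassette-matching appendices that let the first-round
# homology arms prime the second-round PCR; F1/R2 set the >=300-bp arms.
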