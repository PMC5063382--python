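"""Simulate the full tagging workflow for one ORF in all three modes.

For each mode: design primers, assemble the integration cassette by two-step
PCR, integrate it at the locus, pop out the marker by direct-repeat
recombination (scarless modes), and audit the final locus byte-for-byte.
"""

from scartag import (
    DesignConfig,
    appendices_for_template,
    design_primer_set,
    locus_from_assembly,
    simulate_tagging,
)
from scartag.fixtures import FixtureSpec, make_genome, make_template

assembly, orfs, truth = make_genome(FixtureSpec(seed=1, n_orfs=10))
orf = orfs[0]
locus = locus_from_assembly(assembly, orf)
print(f"ORF {orf.name}: {orf.length} bp on {orf.chromosome}{orf.strand}, "
      f"locus model {len(locus.sequence)} bp")

for mode in ("CM", "C", "N"):
    template = make_template(mode, seed=1)
    r1, f2 = appendices_for_template(template.sequence)
    cfg = DesignConfig(mode=mode, appendix_r1=r1, appendix_f2=f2)
    s = design_primer_set(assembly, orf, mode, cfg)
    out = simulate_tagging(locus, s, template)
    grew = len(out.intermediate.sequence) - len(locus.sequence)
    final_delta = len(out.final.sequence) - len(locus.sequence)
    print(f"\nmode {mode}: integration adds {grew} bp; after pop-out the locus "
          f"is {final_delta:+d} bp vs the original")
    print(f"  audit: {'PASS' if out.audit.passed else 'FAIL'}  {out.audit.checks}")
    for note in out.audit.notes:
        print(f"  note : {note}")
# In scarless modes the marker (and the promoter, for N) is gone and both
# UTRs are untouched; mode CM keeps the marker downstream of the new stop.
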