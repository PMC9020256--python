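"""Design and validate a three-primer genotyping assay in silico.

Given the wild-type chromosome, the transgenic allele, and the called
breakpoints, designs one shared forward primer plus two allele-specific
reverse primers, predicts the two band sizes by in-silico PCR, and
genotypes all three diploid combinations.
"""

from tlamap import integration
from tlamap.genome import GenomeSpec, IntegrationEvent, build_transgenic_allele, \
    generate_genome, make_transgene
from tlamap.genotyping import PUBLISHED_ASSAY, design_three_primer_assay, \
    genotype_allele_pair

host = generate_genome(GenomeSpec(("chr5",), (200_000,), 0.42, seed=17))
construct = make_transgene(seed=18)
window = next(host.features(kind="region"))
event = IntegrationEvent(window.chromosome, window.start, window.end)
allele, _ = build_transgenic_allele(host, construct, event)
wt, tg = host.sequences["chr5"], allele.sequences["chr5_tg"]
call = integration.IntegrationCall(
    "chr5", event.deletion_start + 1, event.deletion_end + 1, 5, 5
)

assay = design_three_primer_assay(wt, tg, call)
print("designed primers:")
print(f"  forward     {assay.forward.sequence}  (shared host flank)")
print(f"  reverse_wt  {assay.reverse_wt.sequence}  (inside the deleted interval)")
print(f"  reverse_tg  {assay.reverse_tg.sequence}  (inside the cassette 5' region)")
print(f"predicted bands: WT allele {assay.predicted_wt_amplicon_bp} bp, "
      f"transgenic allele {assay.predicted_tg_amplicon_bp} bp")
for pair, name in (((wt, wt), "WT/WT"), ((wt, tg), "WT/TG"), ((tg, tg), "TG/TG")):
    print(f"  {name} animal -> {genotype_allele_pair(pair, assay)}")
print("one band at the WT size = wild type; both bands = heterozygote;")
print("one band at the transgene size = homozygote.")
print(f"(the published assay for the real line used bands of "
      f"{PUBLISHED_ASSAY['wt_amplicon_bp']} bp and "
      f"{PUBLISHED_ASSAY['tg_amplicon_bp']} bp)")
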