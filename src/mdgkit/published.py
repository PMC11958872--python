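"""Published layout of the groundnut 5K mid-density genotyping assay.

These constants describe the released 5,081-SNP AgriSeq panel for
cultivated groundnut (*Arachis hypogaea*, allotetraploid, 20
chromosomes: Arahy.01-10 form the A sub-genome, Arahy.11-20 the B
sub-genome). They serve as defaults for the simulator's genome layout
and as reference ledgers for consistency checks; they are inputs, not
computed results.
"""

from __future__ import annotations

#: Markers per chromosome on the released 5K assay.
ASSAY_CHROMOSOME_COUNTS: dict[str, int] = {
    "Arahy.01": 264, "Arahy.02": 278, "Arahy.03": 393, "Arahy.04": 227,
    "Arahy.05": 225, "Arahy.06": 216, "Arahy.07": 196, "Arahy.08": 196,
    "Arahy.09": 252, "Arahy.10": 181, "Arahy.11": 211, "Arahy.12": 347,
    "Arahy.13": 338, "Arahy.14": 272, "Arahy.15": 237, "Arahy.16": 281,
    "Arahy.17": 261, "Arahy.18": 187, "Arahy.19": 285, "Arahy.20": 234,
}

#: Total size of the released panel.
ASSAY_TOTAL_MARKERS = 5081

#: Diploid-pattern (single sub-genome amplicon) markers on the panel.
ASSAY_CATEGORY1_MARKERS = 963

#: Candidate pool the panel was drawn from (high-density array source).
CANDIDATE_POOL_SIZE = 8027
PRIORITIZED_CANDIDATES = 5000
RESERVE_CANDIDATES = 3027

#: Trait-associated SNP counts by source assembly, as
#: (category-1, category-2, category-3) splits.
TRAIT_SNP_SOURCES: dict[str, tuple[int, int, int]] = {
    "A_duranensis": (58, 25, 14),
    "Shitouqi": (47, 18, 39),
    "Tifrunner": (6, 1, 5),
}

#: Trait-associated SNPs retained on the final assay.
TRAIT_SNPS_ON_ASSAY = 82

#: Variance explained (%) by the first three principal coordinates of the
#: 2,573-genotype diversity analysis run on this assay.
DIVERSITY_PC_PERCENT = (42.16, 24.56, 15.36)

#: Parent-polymorphism screen of four BC3F4 backcross lines:
#: polymorphic marker counts and panel sizes for the 5K assay and the
#: 58K high-density source array.
POLYMORPHIC_SNPS_5K = 726
POLYMORPHIC_SNPS_58K = 2900
HD_ARRAY_SIZE = 58233


def subgenome_of_chromosome(chromosome: str) -> str:
    """Map an Arahy.NN chromosome name to its sub-genome (A or B)."""
    try:
        idx = int(chromosome.split(".")[-1])
    except ValueError as exc:
        raise ValueError(f"unrecognized chromosome name {chromosome!r}") from exc
    if 1 <= idx <= 10:
        return "A"
    if 11 <= idx <= 20:
        return "B"
    raise ValueError(f"chromosome index out of range in {chromosome!r}")
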