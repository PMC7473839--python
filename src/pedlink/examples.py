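"""Synthetic example fixtures.

``segregation_example`` builds a fully synthetic 29-member multiplex
family with two candidate variants whose carrier margins follow the
strongly-but-imperfectly co-segregating pattern typical of validated
dominant-model candidates: among 15 genotyped affected members, 9 carry
both variants and 14 carry at least one, while none of the 6 genotyped
unaffected members carries either.  It is generated data, not a
transcription of any real pedigree.
"""

from __future__ import annotations

from .types import (AFFECTED, FEMALE, MALE, UNAFFECTED, UNKNOWN, Individual,
                    Pedigree)


def segregation_example() -> tuple[Pedigree, dict[str, set[str]], list[str]]:
    """(pedigree, carriers per variant, genotyped ids) for a synthetic family.

    Margins: 15 affected / 6 unaffected / 8 unknown (4 of them genotyped);
    affected carriers: 9 with both variants, 3 with only the first,
    2 with only the second, 1 with neither; no unaffected carriers.
    """
    inds = [Individual("f0", None, None, MALE, AFFECTED),
            Individual("m0", None, None, FEMALE, UNAFFECTED)]
    affection = [AFFECTED] * 14 + [UNAFFECTED] * 5 + [UNKNOWN] * 8
    for k, aff in enumerate(affection, start=1):
        inds.append(Individual(f"i{k}", "f0", "m0",
                               MALE if k % 2 else FEMALE, aff))
    pedigree = Pedigree(inds, family_id="SYN")
    affected = [i for i in pedigree.members
                if pedigree[i].affection == AFFECTED]
    both = set(affected[:9])
    only_a = set(affected[9:12])
    only_b = set(affected[12:14])
    carriers = {"var_a": both | only_a, "var_b": both | only_b}
    unknowns = [i for i in pedigree.members
                if pedigree[i].affection == UNKNOWN]
    genotyped = [i for i in pedigree.members
                 if pedigree[i].affection != UNKNOWN] + unknowns[:4]
    return pedigree, carriers, genotyped
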