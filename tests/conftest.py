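import pytest

from pedagg.pedigree import Individual, Pedigree, Phenotype, Sex


def ind(iid, fam, father=None, mother=None, sex=Sex.MALE, pheno=Phenotype.UNAFFECTED):
    return Individual(iid, fam, father, mother, sex, pheno)


@pytest.fixture
def trio():
    """Father (affected), mother, child (affected)."""
    return Pedigree(
        [
            ind("1", "FAM", sex=Sex.MALE, pheno=Phenotype.AFFECTED),
            ind("2", "FAM", sex=Sex.FEMALE),
            ind("3", "FAM", "1", "2", Sex.MALE, Phenotype.AFFECTED),
        ]
    )


@pytest.fixture
def three_gen():
    """Two sibships with a first-cousin pair in generation 3.

    gp1 x gp2 -> a, b ; a x asp -> c1, c2 ; b x bsp -> d.
    c1 and d are first cousins (phi = 1/16).
    """
    return Pedigree(
        [
            ind("gp1", "F1", sex=Sex.MALE),
            ind("gp2", "F1", sex=Sex.FEMALE),
            ind("a", "F1", "gp1", "gp2", Sex.MALE),
            ind("asp", "F1", sex=Sex.FEMALE),
            ind("b", "F1", "gp1", "gp2", Sex.FEMALE),
            ind("bsp", "F1", sex=Sex.MALE),
            ind("c1", "F1", "a", "asp", Sex.MALE),
            ind("c2", "F1", "a", "asp", Sex.FEMALE),
            ind("d", "F1", "bsp", "b", Sex.FEMALE),
        ]
    )


@pytest.fixture
def nuclear():
    """Parents plus three children; one parent unphenotyped."""
    return Pedigree(
        [
            ind("p1", "N", sex=Sex.MALE, pheno=Phenotype.UNPHENOTYPED),
            ind("p2", "N", sex=Sex.FEMALE),
            ind("i", "N", "p1", "p2", Sex.MALE, Phenotype.AFFECTED),
            ind("s1", "N", "p1", "p2", Sex.FEMALE, Phenotype.AFFECTED),
            ind("s2", "N", "p1", "p2", Sex.MALE),
        ]
    )
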