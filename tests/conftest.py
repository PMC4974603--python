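import numpy as np
import pytest

from ancestrybench.genotype_io import GenotypeMatrix, MarkerInfo, SampleMeta
from ancestrybench.pedigree_sim import Individual, Pedigree


@pytest.fixture
def toy_plink(tmp_path):
    """Hand-written 2-sample, 3-marker .ped/.map pair.

    Sample s1: "A A, A G, G G"; sample s2: "A A, G G, A G".
    The counted allele is the first one observed per marker in file order
    (A, A, G), so dosages are [[2,1,2],[2,0,1]].
    """
    ped = tmp_path / "toy.ped"
    mapf = tmp_path / "toy.map"
    ped.write_text(
        "fam1 s1 0 0 1 -9 A A A G G G\n"
        "fam1 s2 0 0 2 -9 A A G G A G\n"
    )
    mapf.write_text("1 rs1 0 100\n1 rs2 0 200\n1 rs3 0 300\n")
    return ped, mapf


def make_markers(L, chromosome="1"):
    return [
        MarkerInfo(chromosome=chromosome, marker_id=f"snp{l + 1}", position=l + 1)
        for l in range(L)
    ]


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(0)
    dosages = rng.integers(0, 3, size=(4, 6))
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(4)],
        markers=make_markers(6),
        dosages=dosages,
    )


def _founder(pid, sex, label, L=0):
    hap = np.zeros((2, L), dtype=np.int16) if L else np.zeros((2, 0), dtype=np.int16)
    return Individual(
        id=pid, sex=sex, generation=0, haplotypes=hap, founder_label=label
    )


def build_worked_pedigree():
    """The published worked example.

    Unlabeled African male x labeled Yemenite female -> son; son x unlabeled
    Polish female (whose parents are unlabeled founders) -> terminal
    offspring.  Expected: grandparent rule true, matrilineal rule false.
    """
    ped = Pedigree(markers=[])
    ped.add(_founder("african_m", "male", "unlabeled"))
    ped.add(_founder("yemenite_f", "female", "labeled"))
    ped.add(_founder("polish_gf", "male", "unlabeled"))
    ped.add(_founder("polish_gm", "female", "unlabeled"))
    ped.add(
        Individual(
            id="son", sex="male", generation=1,
            mother_id="yemenite_f", father_id="african_m",
            haplotypes=np.zeros((2, 0), dtype=np.int16),
        )
    )
    ped.add(
        Individual(
            id="polish_f", sex="female", generation=1,
            mother_id="polish_gm", father_id="polish_gf",
            haplotypes=np.zeros((2, 0), dtype=np.int16),
        )
    )
    ped.add(
        Individual(
            id="offspring", sex="male", generation=2,
            mother_id="polish_f", father_id="son",
            haplotypes=np.zeros((2, 0), dtype=np.int16),
        )
    )
    return ped


@pytest.fixture
def worked_pedigree():
    return build_worked_pedigree()


def build_two_generation_pedigree(labels):
    """Child with four founder grandparents labeled per ``labels``.

    ``labels`` maps {"mgm", "mgf", "pgm", "pgf"} -> bool (maternal/paternal
    grandmother/grandfather).
    """
    lab = lambda b: "labeled" if b else "unlabeled"
    ped = Pedigree(markers=[])
    ped.add(_founder("mgm", "female", lab(labels["mgm"])))
    ped.add(_founder("mgf", "male", lab(labels["mgf"])))
    ped.add(_founder("pgm", "female", lab(labels["pgm"])))
    ped.add(_founder("pgf", "male", lab(labels["pgf"])))
    ped.add(
        Individual(
            id="mother", sex="female", generation=1,
            mother_id="mgm", father_id="mgf",
            haplotypes=np.zeros((2, 0), dtype=np.int16),
        )
    )
    ped.add(
        Individual(
            id="father", sex="male", generation=1,
            mother_id="pgm", father_id="pgf",
            haplotypes=np.zeros((2, 0), dtype=np.int16),
        )
    )
    ped.add(
        Individual(
            id="child", sex="female", generation=2,
            mother_id="mother", father_id="father",
            haplotypes=np.zeros((2, 0), dtype=np.int16),
        )
    )
    return ped


def make_founder_meta(n, labels=None):
    sexes = ["male" if i % 2 == 0 else "female" for i in range(n)]
    if labels is None:
        labels = ["labeled" if i < n // 2 else "unlabeled" for i in range(n)]
    return [
        SampleMeta(sample_id=f"F{i + 1:03d}", sex=sexes[i], label=labels[i])
        for i in range(n)
    ]
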