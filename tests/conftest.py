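import numpy as np
import pytest

from rootshape.genotypes import GenotypeMatrix
from rootshape.simulate import ShapeParams, generate_population, render_root_mask


@pytest.fixture(scope="session")
def small_population():
    """60 accessions x 200 markers, 3 structured populations."""
    geno, truth = generate_population(60, 200, 3, 0.25, 0.1,
                                      n_chromosomes=3, seed=11)
    return geno, truth


@pytest.fixture(scope="session")
def cylinder_mask():
    return render_root_mask(
        ShapeParams(100, 20, "cylindrical", tip_cap_fraction=0.0), 0.5)


@pytest.fixture(scope="session")
def cone_mask():
    return render_root_mask(ShapeParams(100, 40, "conical"), 0.25)


@pytest.fixture()
def disc_mask():
    """A rasterised circle of diameter 60 mm at 0.5 mm/px."""
    from rootshape.shapes import RootMask

    scale, diameter = 0.5, 60.0
    n = int(diameter / scale)
    yy, xx = np.mgrid[0:n, 0:n]
    disc = ((yy + 0.5 - n / 2) ** 2 + (xx + 0.5 - n / 2) ** 2) \
        <= (n / 2) ** 2
    return RootMask(np.pad(disc, 3), scale)


def make_genotypes(dosage, chrom=None, pos=None, groups=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    chrom = chrom if chrom is not None else ["chr1"] * m
    pos = pos if pos is not None else list(range(100, 100 + m * 10, 10))
    acc = [f"a{i:03d}" for i in range(n)]
    if isinstance(groups, (list, np.ndarray)):
        groups = {a: g for a, g in zip(acc, groups)}
    return GenotypeMatrix(dosage, chrom, pos, ["A"] * m, ["T"] * m, acc,
                          groups)
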