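import numpy as np
import pandas as pd
import pytest

from kinmotif.alphabet import POSITIONS, ROW_ORDER, randomized_residues
from kinmotif.pssm import DensitometryMatrix, normalize_densitometry
from kinmotif.scoring import build_background
from kinmotif.synthetic import ProteomeModel, gen_atlas, gen_background_sites


def make_raw(values=None, kinase_id="K1", fill=1.0, **kwargs):
    """Raw densitometry grid, constant-filled unless cells are overridden.

    ``values``: optional {(residue, position): value} overrides.
    """
    df = pd.DataFrame(fill, index=list(ROW_ORDER), columns=list(POSITIONS),
                      dtype=float)
    for (res, pos), v in (values or {}).items():
        df.loc[res, pos] = v
    return DensitometryMatrix(kinase_id=kinase_id, values=df, **kwargs)


@pytest.fixture
def uniform_raw():
    return make_raw()


@pytest.fixture
def uniform_pssm(uniform_raw):
    return normalize_densitometry(uniform_raw)


@pytest.fixture
def toy_raw():
    """One column where the 17 randomized residues are 1 except Arg = 18."""
    return make_raw(values={("R", -3): 18.0})


@pytest.fixture
def toy_pssm(toy_raw):
    return normalize_densitometry(toy_raw)


@pytest.fixture(scope="session")
def small_reference():
    return gen_background_sites(ProteomeModel(), 500, seed=7)


@pytest.fixture(scope="session")
def small_atlas(small_reference):
    """10 well-separated synthetic kinases with 500-site backgrounds."""
    return gen_atlas(10, small_reference, seed=11)


def random_raw(rng, kinase_id="K", exclusions=frozenset("STC")):
    """Strictly positive random densitometry matrix."""
    vals = pd.DataFrame(
        rng.lognormal(0.0, 0.8, size=(len(ROW_ORDER), len(POSITIONS))),
        index=list(ROW_ORDER), columns=list(POSITIONS),
    )
    return DensitometryMatrix(
        kinase_id=kinase_id, values=vals, randomized_exclusions=exclusions
    )


def random_window(rng, allow_gaps=False):
    """Random canonical 10-symbol window."""
    rand = randomized_residues()
    flank = [str(rng.choice(rand)) for _ in range(9)]
    if allow_gaps:
        for i in range(9):
            if rng.random() < 0.15:
                flank[i] = "_"
    center = "S" if rng.random() < 0.5 else "T"
    return "".join(flank[:5]) + center + "".join(flank[5:])
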