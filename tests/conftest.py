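"""Shared fixtures: every dataset is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from mousecred import CnrNormalizer, ReadCountMatrix, mouse_layout
from mousecred.genome import GenomeLayout, Arm
from mousecred.simulate import (default_gc_bias, simulate_cn_profile,
                                simulate_panel, simulate_read_counts,
                                simulate_strain_panel)

NORMAL_IDS = [f"n{i}" for i in range(8)]


@pytest.fixture(scope="session")
def small_layout() -> GenomeLayout:
    """Five 50-Mb telocentric chromosomes (one arm each, mouse convention)."""
    return mouse_layout({str(c): 50_000_000 for c in range(1, 6)})


@pytest.fixture(scope="session")
def toy_panel(small_layout):
    return simulate_panel(small_layout, genes_per_chrom=3, amplicons_per_gene=8,
                          flox_targets={"Trp53_flox": "g1_0",
                                        "Apc_flox": "g2_0"},
                          n_snps=10, seed=0)


@pytest.fixture(scope="session")
def normal_counts(small_layout, toy_panel):
    truth = simulate_cn_profile(small_layout)
    return simulate_read_counts(truth, toy_panel, NORMAL_IDS, mean_depth=500,
                                dispersion=0.02, gc_bias=default_gc_bias,
                                seed=11)


@pytest.fixture(scope="session")
def fitted_normalizer(normal_counts, toy_panel):
    return CnrNormalizer().fit(normal_counts, toy_panel, NORMAL_IDS)


@pytest.fixture(scope="session")
def normals_cnr(fitted_normalizer, normal_counts):
    return fitted_normalizer.transform(normal_counts)


@pytest.fixture(scope="session")
def strain_panel_df():
    return simulate_strain_panel(n_strains=5, n_snps=500, seed=3)


def combine_counts(*matrices) -> ReadCountMatrix:
    allow = any(m.allow_float for m in matrices)
    return ReadCountMatrix(pd.concat([m.counts for m in matrices], axis=1),
                           allow_float=allow)


@pytest.fixture(scope="session")
def synthetic_smad4_pair():
    """Synthetic stand-in for the SMAD4/Smad4 ortholog pair.

    Constructed (not downloaded) peptides reproducing the structural facts of
    the real pair: human position 361 is R and aligns to mouse position 360
    (also R) across a single-residue deletion far upstream of the window.
    """
    rng = np.random.default_rng(42)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    human = rng.choice(aas, size=420)
    human[360] = "R"  # 1-based position 361
    mouse = np.delete(human, 99)  # drop residue 100 -> downstream shifts by 1
    assert mouse[359] == "R"
    return "".join(human), "".join(mouse)


@pytest.fixture(scope="session")
def synthetic_pik3ca_pair():
    """Synthetic stand-in for the PIK3CA/Pik3ca ortholog pair: position 545 is
    E in both species at identical coordinates; a few substitutions are
    planted far from the focal window."""
    rng = np.random.default_rng(43)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    human = rng.choice(aas, size=1068)
    human[544] = "E"  # 1-based position 545
    mouse = human.copy()
    for i in (10, 200, 900):
        choices = aas[aas != mouse[i]]
        mouse[i] = rng.choice(choices)
    return "".join(human), "".join(mouse)
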