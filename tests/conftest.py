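"""Shared fixtures: small synthetic corpora and derived potentials."""

from __future__ import annotations

import numpy as np
import pytest

import hotmusic as hm
from hotmusic.structures import ProteinStructure, Residue


@pytest.fixture(scope="session")
def synth_config():
    return hm.synthetic_descriptor_config()


@pytest.fixture(scope="session")
def small_corpus(synth_config):
    """Six coupled synthetic structures as StructureData views."""
    spec = hm.SyntheticSpec(
        n_structures=6, chain_length_range=(40, 60), coupling=0.5, seed=7
    )
    structures = hm.generate_structures(spec)
    return [hm.structure_arrays(s, synth_config) for s in structures]


@pytest.fixture(scope="session")
def small_structures(small_corpus):
    return [sd.structure for sd in small_corpus]


@pytest.fixture(scope="session")
def standard_potentials(small_corpus, synth_config):
    return hm.derive_standard_potentials(small_corpus, synth_config)


@pytest.fixture(scope="session")
def tdep_potentials(small_corpus, synth_config):
    return hm.derive_t_dependent_potentials(small_corpus, config=synth_config)


def toy_structure(sequence: str, centroid_spacing: float = 5.0,
                  spacing_list=None) -> ProteinStructure:
    """A hand-buildable structure whose side-chain centroids sit on the x
    axis at controlled spacings (every residue carries a lone CB)."""
    residues = []
    x = 0.0
    spacings = spacing_list or [centroid_spacing] * (len(sequence) - 1)
    for i, aa in enumerate(sequence):
        cb = np.array([x, 0.0, 0.0])
        ca = cb + np.array([0.0, 1.5, 0.0])
        n = ca + np.array([-1.46, 0.0, 0.0])
        c = ca + np.array([0.53, 1.43, 0.0])
        residues.append(
            Residue(
                aa=aa,
                author_number=str(i + 1),
                atoms={"N": n, "CA": ca, "C": c, "CB": cb},
            )
        )
        if i < len(spacings):
            x += spacings[i]
    return ProteinStructure(id="TOY", chain="A", residues=residues, resolution=1.5)
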