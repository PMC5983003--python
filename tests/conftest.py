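"""Shared fixtures: small synthetic structures, tessellations, potentials.

Everything is generated programmatically from fixed seeds; nothing is
downloaded or stored on disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from tessmut.structure_io import CoarseStructure, ResidueSite
from tessmut.synthetic import (SyntheticSpec, synthetic_structure,
                               synthetic_training_potential,
                               synthetic_variant_study)
from tessmut.tessellation import tessellate


def make_structure(coords, sequence, chain="A", start_resnum=1):
    """Build a CoarseStructure directly from coordinates and a sequence."""
    sites = [
        ResidueSite(chain, start_resnum + i, i, sequence[i],
                    tuple(float(x) for x in coords[i]))
        for i in range(len(sequence))
    ]
    return CoarseStructure(sites, source_id="fixture")


@pytest.fixture(scope="session")
def single_tetra_structure():
    coords = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0],
                       [1.9, 3.3, 0.0], [1.9, 1.1, 3.1]])
    return make_structure(coords, "ACDE")


@pytest.fixture(scope="session")
def globule():
    """A 100-residue synthetic monomer."""
    return synthetic_structure(SyntheticSpec(n_residues=100, seed=11))


@pytest.fixture(scope="session")
def globule_tess(globule):
    return tessellate(globule)


@pytest.fixture(scope="session")
def toy_potential():
    """Smoothed potential from 10 synthetic training globules."""
    return synthetic_training_potential(n_structures=10, n_residues=90, seed=3)


@pytest.fixture(scope="session")
def dimer():
    """Asymmetric synthetic homodimer (mirror copy plus crystal-like jitter)."""
    return synthetic_structure(
        SyntheticSpec(n_residues=60, chains=2, asymmetry=0.3, seed=19))


@pytest.fixture(scope="session")
def dimer_tess(dimer):
    return tessellate(dimer)


@pytest.fixture(scope="session")
def study():
    """Small end-to-end synthetic variant study for feature/model tests."""
    return synthetic_variant_study(seed=7, n_residues=90, n_variants=150,
                                   noise_sd=0.5, n_training=10)
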