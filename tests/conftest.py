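"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from spo11dock.bdna import HelixParams, build_bform_duplex
from spo11dock.structures import Atom, Residue, Structure
from spo11dock.synthetic import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def helix_params() -> HelixParams:
    return HelixParams()


@pytest.fixture(scope="session")
def duplex12(helix_params) -> Structure:
    return build_bform_duplex("ACGTTGCAGCAT", helix_params)


@pytest.fixture(scope="session")
def toy_sphere():
    """Default sphere-envelope toy complex (session-scoped; treat as
    read-only)."""
    return make_toy_complex(ToyComplexSpec())


@pytest.fixture(scope="session")
def toy_wrap():
    """Wrap-envelope toy complex used for the dimer analyses."""
    return make_toy_complex(
        ToyComplexSpec(envelope="wrap", radius=12.0, pitch=30.0,
                       arc_deg=540.0))


def make_fake_protein(n_res: int = 12, chain: str = "P",
                      seed: int = 7) -> Structure:
    """A protein-classified chain of CA-only residues on a wiggly path."""
    rng = np.random.default_rng(seed)
    pos = np.cumsum(rng.normal(0, 1.5, size=(n_res, 3)), axis=0) + [0, 0, 5.0]
    residues = [Residue(chain, i + 1, "ALA",
                        [Atom("CA", "C", pos[i])]) for i in range(n_res)]
    return Structure("fake-protein", residues)


@pytest.fixture()
def fake_protein() -> Structure:
    return make_fake_protein()
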