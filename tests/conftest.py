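"""Shared fixtures: small toy complexes and prebuilt SASD machinery.

Everything is generated at run time; session scope keeps the expensive
voxel-grid construction to one instance per object.
"""

import numpy as np
import pytest

import xlscore as xs


@pytest.fixture(scope="session")
def toy_dimer():
    """Deterministic two-helix hetero-dimer with accessible surface lysines."""
    return xs.make_toy_complex(n_subunits=2, residues_per_subunit=24,
                               n_surface_lysines=8, rng_seed=7)


@pytest.fixture(scope="session")
def toy_grid(toy_dimer):
    return xs.build_grid(toy_dimer)


@pytest.fixture(scope="session")
def toy_calc(toy_grid):
    return xs.SASDCalculator(toy_grid)


@pytest.fixture(scope="session")
def toy_lysines(toy_dimer):
    return toy_dimer.crosslinkable_residues()


@pytest.fixture(scope="session")
def toy_homodimer():
    """Sequence-identical two-copy complex for chain-ambiguity handling."""
    return xs.make_toy_complex(n_subunits=2, residues_per_subunit=24,
                               n_surface_lysines=8, rng_seed=11,
                               identical_subunits=True)


@pytest.fixture(scope="session")
def homo_calc(toy_homodimer):
    return xs.SASDCalculator(xs.build_grid(toy_homodimer))


def make_pdb_text(chains, waters=False):
    """Tiny PDB with C-alpha-only chains given as {chain: n_residues}."""
    lines = []
    serial = 1
    for chain, n in chains.items():
        for i in range(n):
            x = 3.8 * i
            y = 5.0 * (ord(chain) - ord("A"))
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {chain}{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{0.0:8.3f}  1.00  0.00           C"
            )
            serial += 1
    if waters:
        lines.append(
            f"HETATM{serial:5d}  O   HOH A 900      99.000  99.000  99.000  1.00  0.00           O"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
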