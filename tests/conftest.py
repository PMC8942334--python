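"""Shared fixtures: synthetic bundles, hinge pairs, and small PDB texts."""

from __future__ import annotations

import numpy as np
import pytest

from structphylo.structio import ca_trace, parse_pdb
from structphylo.synthetic_data import (
    BundleSpec,
    apply_block_rotation,
    bundle_trace,
    make_bundle,
)
from structphylo.synthetic_refs import nr_like_structure, ts_like_structure


@pytest.fixture(scope="session")
def core_spec() -> BundleSpec:
    return BundleSpec(helix_lengths=(12,) * 7, loop_lengths=(6,) * 6, seed=1)


@pytest.fixture(scope="session")
def core_structure(core_spec):
    return make_bundle(core_spec)


@pytest.fixture(scope="session")
def core_trace(core_spec):
    return bundle_trace(core_spec)


@pytest.fixture(scope="session")
def hinge_pair(core_spec, core_structure, core_trace):
    """(trace, trace with the first three helices rotated 115° about z)."""
    stop = core_spec.helix_ranges[2][1] + 3
    rotated = apply_block_rotation(core_structure, (0, stop), [0, 0, 1],
                                   115.0, core_trace.coords[stop])
    return core_trace, ca_trace(rotated.models[0])


@pytest.fixture(scope="session")
def ts_nr_pair():
    """Synthetic TS-like / NR-LBD-like stand-in pair with their traces."""
    ts = ts_like_structure(seed=0)
    nr = nr_like_structure(seed=0)
    return ts, nr, ca_trace(ts.models[0]), ca_trace(nr.models[0])


SAMPLE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.804   6.900  -5.504  1.00  0.00           C
ATOM      3  CA ASER A   2      13.204   7.500  -4.204  0.60  0.00           C
ATOM      4  CA BSER A   2      13.404   7.700  -4.004  0.40  0.00           C
ATOM      5  CA  GLY A   3      14.604   8.100  -2.904  1.00  0.00           C
ATOM      6  CA  LEU A   4      16.004   8.700  -1.604  1.00  0.00           C
ATOM      7  CA  VAL A   5      17.404   9.300  -0.304  1.00  0.00           C
ATOM      8  CA  LYS A   6      18.804   9.900   0.996  1.00  0.00           C
TER
ATOM      9  CA  THR B  10       0.104   1.134   2.504  1.00  0.00           C
ATOM     10  CA  TRP B  11       1.504   1.734   3.804  1.00  0.00           C
HETATM   11  C1  EST B 101       5.000   5.000   5.000  1.00  0.00           C
HETATM   12  C2  EST B 101       6.000   5.000   5.000  1.00  0.00           C
HETATM   13  O   HOH B 201       8.000   8.000   8.000  1.00  0.00           O
END
"""


@pytest.fixture()
def sample_structure():
    return parse_pdb(SAMPLE_PDB, structure_id="sample")


def rigid_transform(coords: np.ndarray, seed: int) -> np.ndarray:
    """Apply a random proper rotation + translation (seeded)."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng)
    shift = rng.uniform(-20, 20, size=3)
    return rot.apply(coords) + shift
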