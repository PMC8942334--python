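"""Synthetic stand-ins for a terpene-synthase / nuclear-receptor pair.

These are *synthetic* structures built by :mod:`structphylo.synthetic_data`;
they are not crystallographic coordinates.  They encode, with known ground
truth, the architecture reported for the TS↔NR comparison so the full
pipeline can be exercised end to end without any external structure file:

* a shared seven-helix core (c1–c7) with identical packing in both models;
* in the TS-like model, the c1–c3 block rotated by 115° about the bundle
  z axis relative to the NR-like arrangement, plus two extra N-terminal
  helices standing in for the enzyme's terminal extensions;
* a TS-like sequence carrying the catalytic DDxxD motif at the c2/c3
  junction and a second (duplicated) DDxxD at the c6/c7 junction;
* an NR-like sequence in which the DDxxD position is replaced by a basic
  residue inside a WRS motif, as in the estrogen-receptor LBD;
* independent mild coordinate noise on both models.
"""

from __future__ import annotations

import numpy as np

from .structio import Structure, ca_trace
from .synthetic_data import (
    BundleSpec,
    _arc_points,
    _coords_to_structure,
    _substream,
    apply_block_rotation,
    ideal_helix,
    make_bundle,
    perturb,
)

__all__ = [
    "CORE_SPEC",
    "PLANTED_ROTATION_DEG",
    "nr_like_structure",
    "ts_like_structure",
    "ts_core_offset",
]

#: Seven-helix core layout shared by both stand-ins.
CORE_SPEC = BundleSpec(helix_lengths=(12,) * 7, loop_lengths=(6,) * 6, seed=11)

#: Hinge applied to the TS-like c1–c3 block (degrees, about +z).
PLANTED_ROTATION_DEG = 115.0

_NOISE_SD = 0.25  # Å, independent per model

# two N-terminal extension helices of the TS-like model
_EXT_LENGTHS = (10, 10)
_EXT_LOOPS = (6, 6)

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _background_sequence(n: int, rng: np.random.Generator) -> list[str]:
    return [
        _AA[i] for i in rng.integers(0, len(_AA), size=n)
    ]


def _plant(seq: list[str], start: int, motif: str) -> None:
    seq[start:start + len(motif)] = list(motif)


def _core_coords() -> np.ndarray:
    return ca_trace(make_bundle(CORE_SPEC).models[0]).coords


def _junction(core_ranges, a: int, b: int) -> int:
    """First residue index after core helix ``a`` (0-based), i.e. the a/b
    junction position."""
    del b
    return core_ranges[a][1] + 1


def nr_like_structure(seed: int = 0) -> Structure:
    """Synthetic NR-LBD-like model: the seven-helix core, WRS at the c2/c3
    junction, mild coordinate noise."""
    rng = _substream(seed, "nr-seq")
    n = CORE_SPEC.n_residues
    seq = _background_sequence(n, rng)
    j23 = _junction(CORE_SPEC.helix_ranges, 1, 2)
    _plant(seq, j23 - 1, "WRS")  # arginine replaces the acidic position
    s = _coords_to_structure(_core_coords(), "".join(seq), "NR_SYN")
    return perturb(s, _NOISE_SD, seed=_seed_of(seed, "nr-noise"))


def ts_core_offset() -> int:
    """Index of the first core residue within the TS-like model."""
    return sum(_EXT_LENGTHS) + sum(_EXT_LOOPS)


def ts_like_structure(seed: int = 0) -> Structure:
    """Synthetic terpene-synthase-like model.

    Same core as :func:`nr_like_structure` but with the c1–c3 block rotated
    by 115° about +z, two extra N-terminal helices, DDxxD at the c2/c3
    junction and a second DDxxD at the c6/c7 junction.
    """
    rng = _substream(seed, "ts-build")
    core = _core_coords()
    ranges = CORE_SPEC.helix_ranges
    # hinge the N-terminal three helices (and the start of the c3/c4 loop)
    stop = ranges[2][1] + 3
    pivot = core[stop]
    tmp = _coords_to_structure(core, None, "tmp")
    tmp = apply_block_rotation(tmp, (0, stop), axis=[0.0, 0.0, 1.0],
                               angle_deg=PLANTED_ROTATION_DEG, pivot=pivot)
    core_rot = ca_trace(tmp.models[0]).coords

    # N-terminal extension helices stacked above the core bundle
    z_top = core_rot[:, 2].max() + 8.0
    ext1 = ideal_helix(_EXT_LENGTHS[0]).coords + np.array([14.0, 6.0, z_top])
    ext2 = ideal_helix(_EXT_LENGTHS[1]).coords * np.array([1.0, -1.0, -1.0])
    ext2 = ext2 + np.array([2.0, -10.0, z_top + 16.0 - ext2[:, 2].min()])
    loop1 = _arc_points(ext1[-1], ext2[0], _EXT_LOOPS[0],
                        np.array([0.0, 0.0, 1.0]), rng, 0.15)
    loop2 = _arc_points(ext2[-1], core_rot[0], _EXT_LOOPS[1],
                        np.array([1.0, 1.0, 0.5]), rng, 0.15)
    coords = np.vstack([ext1, loop1, ext2, loop2, core_rot])

    seq = _background_sequence(len(coords), _substream(seed, "ts-seq"))
    off = ts_core_offset()
    j23 = off + _junction(ranges, 1, 2)
    j67 = off + _junction(ranges, 5, 6)
    _plant(seq, j23 - 2, "DDIMD")   # site 1: catalytic motif, c2/c3 junction
    _plant(seq, j67 - 2, "DDELD")   # site 2: ancestral duplication, c6/c7
    s = _coords_to_structure(coords, "".join(seq), "TS_SYN")
    return perturb(s, _NOISE_SD, seed=_seed_of(seed, "ts-noise"))


def _seed_of(seed: int, tag: str) -> int:
    return int(_substream(seed, tag).integers(2 ** 31))
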