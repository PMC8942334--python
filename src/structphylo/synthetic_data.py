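"""Synthetic Cα structures with known ground truth.

Generators for ideal α-helices, multi-helix bundles joined by loops,
coordinate noise, hinge rotations of residue blocks, families of structures
diverged along a guide tree, and planted ligand pockets.  Everything is a
pure function of its seed, so every pipeline stage can be tested against a
known answer without any external structure files.

All structures are Cα-only: one CA atom per residue, chain 'A', Ångström
coordinates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .structio import AtomRecord, CaTrace, LigandPose, Structure, ca_trace

__all__ = [
    "BundleSpec",
    "FamilyConfig",
    "ideal_helix",
    "make_bundle",
    "bundle_trace",
    "perturb",
    "apply_block_rotation",
    "evolve_family",
    "plant_ligand",
    "random_bundle_pair",
]

# ideal α-helix Cα geometry
HELIX_RISE = 1.5       # Å per residue
HELIX_RADIUS = 2.3     # Å
HELIX_TURN = 100.0     # degrees per residue
CA_STEP = 3.8          # Å, consecutive Cα spacing used for loops

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _substream(seed: int, tag: str) -> np.random.Generator:
    """Deterministic child RNG derived by hashing (tag, seed).

    Hash-derived substreams make results independent of traversal order.
    """
    h = zlib.crc32(f"{tag}|{seed}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(h)


def ideal_helix(n: int, start_res: int = 1) -> CaTrace:
    """Canonical α-helix Cα trace along +z.

    Rise 1.5 Å/residue, radius 2.3 Å, 100° turn/residue.
    """
    if n < 5:
        raise ValueError(f"helix needs >= 5 residues, got {n}")
    i = np.arange(n)
    phi = np.deg2rad(HELIX_TURN) * i
    coords = np.column_stack([
        HELIX_RADIUS * np.cos(phi),
        HELIX_RADIUS * np.sin(phi),
        HELIX_RISE * i,
    ])
    labels = [(start_res + int(k), "", "ALA", "A") for k in i]
    return CaTrace(labels, coords)


@dataclass(frozen=True)
class BundleSpec:
    """Layout of a synthetic multi-helix bundle.

    Helices sit on a ring of the given inter-helix spacing, antiparallel in
    alternation, joined by arc-shaped loops with ~3.8 Å Cα steps.
    """

    helix_lengths: tuple[int, ...]
    loop_lengths: tuple[int, ...]
    spacing: float = 10.5          # Å between neighbouring helix axes
    loop_jitter: float = 0.15      # Å perpendicular jitter on loop residues
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 5 for h in self.helix_lengths):
            raise ValueError("helix lengths must be >= 5")
        if any(l < 2 for l in self.loop_lengths):
            raise ValueError("loop lengths must be >= 2")
        if len(self.loop_lengths) != len(self.helix_lengths) - 1:
            raise ValueError("need exactly len(helix_lengths) - 1 loop lengths")

    @property
    def helix_ranges(self) -> list[tuple[int, int]]:
        """Inclusive 0-based trace index range of each helix."""
        out, pos = [], 0
        for h, l in zip(self.helix_lengths, list(self.loop_lengths) + [0]):
            out.append((pos, pos + h - 1))
            pos += h + l
        return out

    @property
    def n_residues(self) -> int:
        return sum(self.helix_lengths) + sum(self.loop_lengths)


def _arc_points(p: np.ndarray, q: np.ndarray, n_interior: int,
                bulge_dir: np.ndarray, rng: np.random.Generator,
                jitter: float) -> np.ndarray:
    """Interior points of a circular arc from p to q.

    The arc length is (n_interior + 1) · 3.8 Å so consecutive points step by
    about one Cα-Cα bond; the arc bulges towards ``bulge_dir``.
    """
    chord = q - p
    c = float(np.linalg.norm(chord))
    L = (n_interior + 1) * CA_STEP
    e1 = chord / c
    w = bulge_dir - np.dot(bulge_dir, e1) * e1
    if np.linalg.norm(w) < 1e-8:
        w = np.cross(e1, [0.0, 0.0, 1.0])
        if np.linalg.norm(w) < 1e-8:
            w = np.cross(e1, [0.0, 1.0, 0.0])
    e2 = w / np.linalg.norm(w)
    mid = 0.5 * (p + q)
    if L <= c * 1.0001:
        ts = np.arange(1, n_interior + 1) / (n_interior + 1)
        pts = p[None, :] + ts[:, None] * chord[None, :]
    else:
        # solve sin(θ/2)/(θ/2) = c/L for the arc's central angle θ
        ratio = c / L
        f = lambda th: np.sin(th / 2) / (th / 2) - ratio
        theta = brentq(f, 1e-6, 2 * np.pi - 1e-9)
        R = L / theta
        d = R * np.cos(theta / 2)  # signed: center flips sides when θ > π
        center = mid - d * e2
        # P and Q are symmetric about the e2 axis through the arc centre, so
        # the bulge-side traversal is exactly φ = π/2 + θ/2 → π/2 − θ/2.
        ts = np.arange(1, n_interior + 1) / (n_interior + 1)
        phis = (np.pi / 2 + theta / 2) - theta * ts
        pts = center[None, :] + R * (np.cos(phis)[:, None] * e1[None, :]
                                     + np.sin(phis)[:, None] * e2[None, :])
    if jitter > 0:
        pts = pts + rng.normal(0.0, jitter, size=pts.shape)
    return pts


def _bundle_coords(spec: BundleSpec, rng: np.random.Generator,
                   phase: float = 0.0, spacing_scale: float = 1.0) -> np.ndarray:
    H = len(spec.helix_lengths)
    spacing = spec.spacing * spacing_scale
    ring_r = spacing / (2 * np.sin(np.pi / max(H, 2))) if H > 1 else 0.0
    pieces: list[np.ndarray] = []
    prev_end: np.ndarray | None = None
    for k, hlen in enumerate(spec.helix_lengths):
        helix = ideal_helix(hlen).coords
        if k % 2 == 1:  # antiparallel: flip and shift back into the same z band
            helix = helix * np.array([1.0, -1.0, -1.0])
            helix = helix - [0.0, 0.0, helix[:, 2].min()]
        ang = 2 * np.pi * k / max(H, 1) + phase
        offset = np.array([ring_r * np.cos(ang), ring_r * np.sin(ang), 0.0])
        helix = helix + offset
        if prev_end is not None:
            nloop = spec.loop_lengths[k - 1]
            mid = 0.5 * (prev_end + helix[0])
            bulge = mid - np.array([0.0, 0.0, mid[2]])  # outward from the bundle axis
            if np.linalg.norm(bulge) < 1e-8:
                bulge = np.array([0.0, 0.0, 1.0])
            pieces.append(_arc_points(prev_end, helix[0], nloop, bulge, rng, spec.loop_jitter))
        pieces.append(helix)
        prev_end = helix[-1]
    return np.vstack(pieces)


def _coords_to_structure(coords: np.ndarray, sequence: str | None,
                         structure_id: str) -> Structure:
    n = len(coords)
    seq = sequence or "A" * n
    if len(seq) != n:
        raise ValueError(f"sequence length {len(seq)} != residue count {n}")
    atoms = [
        AtomRecord(
            serial=i + 1, atom_name="CA", alt_loc="",
            res_name=ONE_TO_THREE.get(seq[i], "ALA"), chain_id="A",
            res_seq=i + 1, insertion_code="", position=coords[i],
            element="C", occupancy=1.0, is_hetero=False,
        )
        for i in range(n)
    ]
    return Structure(id=structure_id, models=[atoms])


def make_bundle(spec: BundleSpec, sequence: str | None = None,
                structure_id: str = "bundle") -> Structure:
    """Build a helix bundle Structure from a :class:`BundleSpec`.

    Deterministic given the spec's seed.  Layouts where helices clash
    (any inter-helix Cα pair < 2 Å) are retried with a jittered ring phase
    and slightly larger spacing; after 100 attempts a ``RuntimeError`` is
    raised.
    """
    rng = _substream(spec.seed, "bundle")
    ranges = spec.helix_ranges
    for attempt in range(100):
        coords = _bundle_coords(spec, rng,
                                phase=0.05 * attempt,
                                spacing_scale=1.0 + 0.02 * attempt)
        ok = True
        for a in range(len(ranges)):
            for b in range(a + 1, len(ranges)):
                ca = coords[ranges[a][0]:ranges[a][1] + 1]
                cb = coords[ranges[b][0]:ranges[b][1] + 1]
                d2 = np.sum((ca[:, None, :] - cb[None, :, :]) ** 2, axis=-1)
                if d2.min() < 4.0:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return _coords_to_structure(coords, sequence, structure_id)
    raise RuntimeError("could not place helices without clashes after 100 attempts")


def bundle_trace(spec: BundleSpec, sequence: str | None = None) -> CaTrace:
    """Convenience: bundle directly as a CaTrace."""
    return ca_trace(make_bundle(spec, sequence).models[0])


def perturb(s: Structure, sigma: float, seed: int = 0) -> Structure:
    """Add i.i.d. Gaussian noise (sd ``sigma`` Å) to every polymer atom."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Structure(id=s.id, models=[list(m) for m in s.models])
    rng = _substream(seed, "perturb")
    models = []
    for atoms in s.models:
        out = []
        for a in atoms:
            if a.is_hetero:
                out.append(a)
            else:
                pos = a.position + rng.normal(0.0, sigma, size=3)
                out.append(AtomRecord(a.serial, a.atom_name, a.alt_loc, a.res_name,
                                      a.chain_id, a.res_seq, a.insertion_code,
                                      pos, a.element, a.occupancy, a.is_hetero))
        models.append(out)
    return Structure(id=s.id, models=models)


def _residue_order(atoms: list[AtomRecord]) -> list[tuple[str, int, str]]:
    seen: dict[tuple[str, int, str], None] = {}
    for a in atoms:
        seen.setdefault((a.chain_id, a.res_seq, a.insertion_code), None)
    return list(seen)


def apply_block_rotation(s: Structure, residue_range: tuple[int, int],
                         axis, angle_deg: float, pivot) -> Structure:
    """Rotate the residues in ``residue_range`` rigidly about (pivot, axis).

    ``residue_range`` is a half-open (start, stop) range of 0-based residue
    indices in file order; all other residues are untouched.
    """
    axis = np.asarray(axis, dtype=float)
    if np.linalg.norm(axis) == 0:
        raise ValueError("axis must be non-zero")
    pivot = np.asarray(pivot, dtype=float)
    start, stop = residue_range
    order = _residue_order(s.models[0])
    if not (0 <= start < stop <= len(order)):
        raise IndexError(f"residue range {residue_range} out of bounds (n={len(order)})")
    moving = set(order[start:stop])
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / np.linalg.norm(axis))
    models = []
    for atoms in s.models:
        out = []
        for a in atoms:
            if (a.chain_id, a.res_seq, a.insertion_code) in moving:
                pos = rot.apply(a.position - pivot) + pivot
                out.append(AtomRecord(a.serial, a.atom_name, a.alt_loc, a.res_name,
                                      a.chain_id, a.res_seq, a.insertion_code,
                                      pos, a.element, a.occupancy, a.is_hetero))
            else:
                out.append(a)
        models.append(out)
    return Structure(id=s.id, models=models)


@dataclass(frozen=True)
class FamilyConfig:
    """Divergence model for a structure family evolved along a guide tree.

    Brownian coordinate divergence: along each branch every Cα is displaced
    by Gaussian noise of variance ``noise_rate² × branch_length`` (sd
    ``noise_rate × √branch_length`` Å), so displacement variance — and with
    it the expected drop in alignment score — accumulates additively along
    the tree, which is what makes distance-based topology recovery a
    well-posed ground truth.  With probability ``hinge_rate ×
    branch_length`` a hinge rotation with angle drawn from
    Normal(0, ``hinge_angle_sd``) degrees is applied at a random hinge
    point.
    """

    guide_tree: object                      # skbio TreeNode with branch lengths
    noise_rate: float = 0.4                 # Å per unit branch length
    hinge_rate: float = 0.0                 # hinge events per unit branch length
    hinge_angle_sd: float = 30.0            # degrees
    hinge_points: tuple[int, ...] = ()      # candidate residue indices (loop midpoints)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_rate < 0 or self.hinge_rate < 0:
            raise ValueError("rates must be >= 0")


def _node_tag(node) -> str:
    return ",".join(sorted(t.name for t in node.tips())) or (node.name or "leaf")


def evolve_family(ancestor: Structure, cfg: FamilyConfig) -> dict[str, Structure]:
    """Evolve ``ancestor`` along ``cfg.guide_tree``; return {leaf name: Structure}."""
    tree = cfg.guide_tree
    tips = list(tree.tips())
    if len(tips) < 3:
        raise ValueError("guide tree needs >= 3 leaves")
    leaves: dict[str, Structure] = {}

    def walk(node, current: Structure) -> None:
        for child in node.children:
            tag = _node_tag(child)
            rng = _substream(cfg.seed, f"branch|{tag}")
            bl = float(child.length or 0.0)
            st = current
            if cfg.hinge_rate > 0 and cfg.hinge_points and rng.random() < cfg.hinge_rate * bl:
                point = int(rng.choice(cfg.hinge_points))
                angle = float(rng.normal(0.0, cfg.hinge_angle_sd))
                ax = rng.normal(size=3)
                tr = ca_trace(st.models[0])
                st = apply_block_rotation(st, (0, point), ax, angle, tr.coords[point])
            sigma = cfg.noise_rate * np.sqrt(bl)
            if sigma > 0:
                st = perturb(st, sigma, seed=int(rng.integers(2 ** 31)))
            if child.is_tip():
                leaves[child.name] = st
            else:
                walk(child, st)

    walk(tree, ancestor)
    return leaves


def plant_ligand(s: Structure, pocket_residue_indices, n_atoms: int = 8,
                 cutoff: float = 8.0, seed: int = 0,
                 ligand_name: str = "LIG") -> tuple[Structure, LigandPose]:
    """Place a hetero-atom cluster so that exactly the named residues contact it.

    Contact means Cα within ``cutoff`` Å of any ligand atom.  The cluster
    (radius 1.2 Å) is centred at a point found by seeded local search around
    the pocket centroid; raises ``RuntimeError`` if no placement separates
    the pocket from the rest of the chain.
    """
    pocket = sorted(int(i) for i in pocket_residue_indices)
    tr = ca_trace(s.models[0])
    n = len(tr)
    if not pocket or pocket[0] < 0 or pocket[-1] >= n:
        raise IndexError("pocket residue indices out of range")
    rng = _substream(seed, "ligand")
    coords = tr.coords
    pocket_set = set(pocket)
    lig_radius = 0.3

    def feasible(center: np.ndarray) -> bool:
        d = np.linalg.norm(coords - center, axis=1)
        inside = d <= cutoff - lig_radius - 0.05
        outside = d >= cutoff + lig_radius + 0.05
        return all(inside[i] for i in pocket) and \
            all(outside[i] for i in range(n) if i not in pocket_set)

    center0 = coords[pocket].mean(axis=0)
    candidates = [center0] + [center0 + rng.normal(0.0, sc, size=3)
                              for sc in np.repeat([0.5, 1.0, 2.0, 3.0], 125)]
    center = next((c for c in candidates if feasible(c)), None)
    if center is None:
        raise RuntimeError("no ligand placement realises exactly the requested pocket")
    dirs = rng.normal(size=(n_atoms, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    lig_coords = center + lig_radius * dirs
    names = [f"C{i+1}" for i in range(n_atoms)]
    pose = LigandPose(ligand_name, names, lig_coords)
    serial0 = max((a.serial for a in s.models[0]), default=0)
    het = [
        AtomRecord(serial0 + i + 1, names[i], "", ligand_name, "L", 900 + 1,
                   "", lig_coords[i], "C", 1.0, True)
        for i in range(n_atoms)
    ]
    new = Structure(id=s.id, models=[list(s.models[0]) + het] + [list(m) for m in s.models[1:]])
    return new, pose


def random_guide_tree(n_leaves: int, seed: int = 0,
                      min_bl: float = 0.15, max_bl: float = 1.0):
    """Random binary guide tree with uniform branch lengths.

    Topology by random sequential pair joining (seeded); leaf names are
    ``t0..t{n-1}``.  Returned as an skbio TreeNode rooted at the final
    join.
    """
    import skbio

    if n_leaves < 3:
        raise ValueError("need >= 3 leaves")
    rng = _substream(seed, "guidetree")
    nodes = []
    for i in range(n_leaves):
        tn = skbio.TreeNode(name=f"t{i}")
        tn.length = float(rng.uniform(min_bl, max_bl))
        nodes.append(tn)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = skbio.TreeNode()
        parent.length = float(rng.uniform(min_bl, max_bl))
        parent.append(nodes[i])
        parent.append(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = skbio.TreeNode()
    for x in nodes:
        root.append(x)
    return root


def find_pocket(s: Structure, cutoff: float = 8.0, seed: int = 0,
                min_size: int = 2, max_tries: int = 500) -> list[int]:
    """Find a residue set that a planted ligand can contact exactly.

    Searches seeded probe points near the bundle interior for one whose
    ``cutoff``-ball boundary is clear of Cα atoms (so the contact set is
    robust), and returns the residues inside the ball.  Raises
    ``RuntimeError`` when no such probe exists.
    """
    tr = ca_trace(s.models[0])
    rng = _substream(seed, "pocket")
    axis_pt = np.array([0.0, 0.0, tr.coords[:, 2].mean()])
    shell = 0.45  # Å clearance around the contact boundary
    for _ in range(max_tries):
        probe = axis_pt + rng.normal(0.0, 4.0, size=3)
        d = np.linalg.norm(tr.coords - probe, axis=1)
        if ((d > cutoff - shell) & (d < cutoff + shell)).any():
            continue
        pocket = np.nonzero(d <= cutoff)[0]
        if len(pocket) >= min_size:
            return [int(i) for i in pocket]
    raise RuntimeError("no robust pocket found in this structure")


def random_bundle_pair(seed: int) -> tuple[CaTrace, CaTrace]:
    """Two independent random helix bundles drawn from one architecture
    distribution (5-9 helices of 6-16 residues, loops of 4-9).

    The null model for raw-score calibration: both members come from the
    same length/architecture distribution but share no descent, so high
    scores between them are exactly the "fortuitous overlap" a P-value
    should measure.  Varying the helix count between members is what gives
    the score distribution its extreme-value (right-skewed) shape; bundles
    of one fixed architecture share genuine fold similarity and produce a
    left-skewed null instead.
    """
    rng = _substream(seed, "nullpair-het")
    traces = []
    for _ in range(2):
        n_hel = int(rng.integers(5, 10))
        hl = tuple(int(x) for x in rng.integers(6, 17, size=n_hel))
        ll = tuple(int(x) for x in rng.integers(4, 10, size=n_hel - 1))
        spec = BundleSpec(helix_lengths=hl, loop_lengths=ll,
                          seed=int(rng.integers(2 ** 31)))
        st = perturb(make_bundle(spec), 0.8, seed=int(rng.integers(2 ** 31)))
        traces.append(ca_trace(st.models[0]))
    return traces[0], traces[1]
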