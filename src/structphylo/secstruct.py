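"""α-helix detection from Cα geometry and matched core-helix assignment.

Helices are called from short-range Cα-Cα distances alone (in the style of
P-SEA), so the whole pipeline works on Cα traces without a full backbone.
The matched "core" between two structures is the longest contiguous run of
mutually equivalenced helices, labelled c1..cK from the N-terminus — the
seven-helix framework shared by terpene synthases and nuclear-receptor
ligand-binding domains being the motivating case (K = 7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align3d import StructAlignment
from .structio import CaTrace

__all__ = [
    "HelixSegment",
    "CoreAssignment",
    "detect_helices",
    "assign_core",
    "core_block",
    "CORE_TO_NR_HELIX",
]

# helical i→i+k Cα distance windows (Å): centre ± half-width.  Centres are
# the canonical α-helix values of this package's helix geometry (rise 1.5 Å,
# radius 2.3 Å, 100°/residue): d13 = 5.43, d14 = 5.05, d15 = 6.20; the
# half-widths carry a 0.1 Å allowance for coordinate noise on top of the
# classic P-SEA-style tolerances.
D13 = (5.43, 0.6)
D14 = (5.05, 0.7)
D15 = (6.20, 0.8)
MIN_RUN = 5  # flagged residues

#: Annotation only — correspondence between core helices and conventional
#: nuclear-receptor helix numbering; never used in any computation.
CORE_TO_NR_HELIX = {
    "c1": "H3", "c2": "H4/5", "c3": "H6/H7", "c4": "H8",
    "c5": "H9", "c6": "H10/11", "c7": "H12",
}


@dataclass
class HelixSegment:
    start_index: int
    end_index: int          # inclusive
    axis: np.ndarray        # unit vector, N→C
    centroid: np.ndarray

    def __post_init__(self) -> None:
        if self.end_index - self.start_index + 1 < 5:
            raise ValueError("helix segment must span >= 5 residues")
        self.axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("axis must be unit length")

    def __len__(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def indices(self) -> range:
        return range(self.start_index, self.end_index + 1)


@dataclass
class CoreAssignment:
    """Ordered matched helix pairs labelled c1..cK (K target 7)."""

    pairs: list[tuple[HelixSegment, HelixSegment]]

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> list[str]:
        return [f"c{i + 1}" for i in range(self.k)]

    def __getitem__(self, label: str) -> tuple[HelixSegment, HelixSegment]:
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise LookupError(f"core label {label!r} absent; have {self.labels}") from None
        return self.pairs[idx]


def _segment_axis(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def detect_helices(t: CaTrace) -> list[HelixSegment]:
    """α-helical segments of a Cα trace.

    The profiles d(i,i+2), d(i,i+3), d(i,i+4) are smoothed along the
    sequence with a 1-2-1 kernel — inside a helix they are constant, so
    smoothing suppresses coordinate noise without shifting the signal.  A
    five-residue window starting at i passes when all three smoothed
    distances fall in their ideal-helix ranges, with i..i+4 inside one
    unbroken chain segment; every residue covered by a passing window is
    helical (so isolated window failures inside a noisy helix do not
    fragment it).  Maximal helical runs become segments when they span ≥ 5
    residues and are supported by at least two passing windows (random
    chains produce single isolated passing windows, real helices several);
    runs separated by at most two non-helical residues are merged first.
    The axis is the principal component of the segment, oriented N→C.
    """
    n = len(t)
    if n < 5:
        raise ValueError(f"trace too short for helix detection: {n} residues")
    coords = t.coords
    # gate windows on genuine chain discontinuities only: the trace's QC
    # break window ([2.0, 4.5] Å) fires on ordinary coordinate noise, which
    # must not fragment helices
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    hard = (steps > 6.0) | (steps < 1.5)
    seg = np.concatenate([[0], np.cumsum(hard)])

    def dwin(k: int) -> np.ndarray:
        return np.linalg.norm(coords[k:] - coords[:-k], axis=1)

    def smooth(x: np.ndarray) -> np.ndarray:
        # 1-2-1 kernel, restricted to each unbroken segment of the profile
        y = x.copy()
        if len(x) >= 3:
            y[1:-1] = 0.25 * x[:-2] + 0.5 * x[1:-1] + 0.25 * x[2:]
        m = len(x)
        pseg = seg[:m]
        for i in range(1, m - 1):
            if pseg[i - 1] != pseg[i + 1]:
                y[i] = x[i]
        return y

    d2, d3, d4 = (smooth(dwin(k)) for k in (2, 3, 4))
    passing = np.zeros(max(n - 4, 0), dtype=bool)
    helical = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if seg[i] != seg[i + 4]:
            continue
        if (abs(d2[i] - D13[0]) <= D13[1]
                and abs(d3[i] - D14[0]) <= D14[1]
                and abs(d4[i] - D15[0]) <= D15[1]):
            passing[i] = True
            helical[i:i + 5] = True

    # maximal runs of helical residues, merging gaps of up to two residues
    runs: list[list[int]] = []
    for i in np.nonzero(helical)[0]:
        if runs and i - runs[-1][1] <= 3:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    out = []
    for a, b in runs:
        if b - a + 1 < MIN_RUN:
            continue
        if passing[a:min(b + 1, len(passing))].sum() < 2:
            continue
        out.append(HelixSegment(a, b,
                                _segment_axis(coords[a:b + 1]),
                                coords[a:b + 1].mean(axis=0)))
    return out


def assign_core(helA: list[HelixSegment], helB: list[HelixSegment],
                aln: StructAlignment, overlap_frac: float = 0.6) -> CoreAssignment:
    """Match helices of two structures through a structural alignment.

    Helices pair when ≥ ``overlap_frac`` of the shorter segment's residues
    are equivalenced into the other segment.  The returned core is the
    longest run of matched pairs consecutive in both structures — no
    intervening unmatched helix on either side — labelled c1..cK N→C.
    """
    if not helA or not helB:
        raise ValueError("both helix lists must be non-empty")
    fwd = aln.mapping()
    rev = {b: a for a, b in aln.pairs}
    matched: set[tuple[int, int]] = set()
    for ia, ha in enumerate(helA):
        for ib, hb in enumerate(helB):
            if len(ha) <= len(hb):
                hits = sum(1 for a in ha.indices if fwd.get(a, -1) in hb.indices)
                short = len(ha)
            else:
                hits = sum(1 for b in hb.indices if rev.get(b, -1) in ha.indices)
                short = len(hb)
            if hits >= overlap_frac * short:
                matched.add((ia, ib))
    if not matched:
        raise ValueError("no helix pairs matched through the alignment")
    # longest run of consecutive matches (ia, ib), (ia+1, ib+1), ...
    best_run: list[tuple[int, int]] = []
    for start in sorted(matched):
        if (start[0] - 1, start[1] - 1) in matched:
            continue  # not a run start
        run = [start]
        while (run[-1][0] + 1, run[-1][1] + 1) in matched:
            run.append((run[-1][0] + 1, run[-1][1] + 1))
        if len(run) > len(best_run):
            best_run = run
    return CoreAssignment(pairs=[(helA[ia], helB[ib]) for ia, ib in best_run])


def core_block(t: CaTrace, core: CoreAssignment, which,
               member: int = 0) -> CaTrace:
    """Concatenated Cα trace of the named core helices (order preserved).

    ``member`` selects the structure: 0 for the first (A), 1 for the
    second (B); ``t`` must be the corresponding trace.
    """
    labels = [lab for lab in core.labels if lab in set(which)]
    missing = set(which) - set(core.labels)
    if missing:
        raise LookupError(f"core labels {sorted(missing)} absent; have {core.labels}")
    if not labels:
        raise ValueError("empty core-helix selection")
    indices: list[int] = []
    for lab in labels:
        seg = core[lab][member]
        indices.extend(seg.indices)
    return t.subtrace(indices)
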