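"""Pairwise Cα structure alignment.

The aligner follows the classic AFP (aligned fragment pair) paradigm:
gapless fragment pairs that superpose within an RMSD threshold seed a
monotone chaining step; rigid alignment keeps one global superposition,
flexible alignment may introduce hinge "twists" that start a new rigid
block at a fixed score penalty.  Raw scores live on a 0-1000-ish scale —
each well-superposed position contributes up to ``s0`` points, falling off
quadratically to zero at the cutoff distance ``d_c`` — and are converted
to P-values against an extreme-value (Gumbel) null calibrated on random
helix-bundle pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

from .structio import CaTrace

__all__ = [
    "AlignParams",
    "Superposition",
    "AFP",
    "Twist",
    "StructAlignment",
    "NullCalibration",
    "RotationReport",
    "kabsch",
    "find_afps",
    "rigid_align",
    "flexible_align",
    "alignment_score",
    "calibrate_null",
    "score_pvalue",
    "block_rotation",
    "seq_identity",
]


@dataclass(frozen=True)
class AlignParams:
    """Tunable alignment constants (config-exposed).

    afp_len/afp_rmsd_max govern fragment detection, gap_max the chaining
    step, d_c and s0 the per-position score, twist_penalty and max_twists
    the flexible mode.
    """

    afp_len: int = 8
    afp_rmsd_max: float = 3.0     # Å
    gap_max: int = 30             # residues
    max_twists: int = 5
    twist_penalty: float = 50.0   # t0, score units per extra rigid block
    s0: float = 4.0               # score per perfectly superposed position
    d_c: float = 5.0              # Å, score falls to 0 at this deviation
    n_seeds: int = 12             # superposition seeds tried per rigid pass
    refine_iters: int = 3


@dataclass
class Superposition:
    """Proper rigid map x → R·x + t with the RMSD it achieves."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Superposition":
        return cls(np.eye(3), np.zeros(3), 0.0)


@dataclass(frozen=True)
class AFP:
    """Gapless aligned fragment pair: A[i:i+length] vs B[j:j+length]."""

    i: int
    j: int
    length: int


@dataclass
class Twist:
    """Start of a new rigid block within the equivalence list."""

    boundary: int
    transform: Superposition


@dataclass
class StructAlignment:
    """Equivalenced positions plus per-block transforms and quality scores."""

    pairs: list[tuple[int, int]]
    twists: list[Twist] = field(default_factory=list)
    rmsd: float = 0.0
    raw_score: float = 0.0
    p_value: float = 1.0
    seq_identity: float = 0.0
    superpositions: list[Superposition] = field(default_factory=list)

    @property
    def n_equiv(self) -> int:
        return len(self.pairs)

    def mapping(self) -> dict[int, int]:
        return dict(self.pairs)

    @classmethod
    def empty(cls) -> "StructAlignment":
        return cls(pairs=[], rmsd=0.0, raw_score=0.0, p_value=1.0)


@dataclass(frozen=True)
class NullCalibration:
    """Gumbel parameters of the null raw-score distribution."""

    location: float
    scale: float
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("Gumbel scale must be > 0")


@dataclass
class RotationReport:
    axis: np.ndarray
    angle: float                 # degrees, in [0, 180]
    reference_block: tuple[str, ...]
    moving_block: tuple[str, ...]

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("axis must be unit length")


def kabsch(P, Q) -> Superposition:
    """Least-squares proper rigid superposition of P onto Q.

    Standard SVD solution with reflection correction; raises on length
    mismatch or a degenerate (collinear) point set.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {P.shape} and {Q.shape}")
    n = len(P)
    if n < 3:
        raise ValueError("need at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    s = np.linalg.svd(P0, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return Superposition(R, t, rmsd)


def _windows(coords: np.ndarray, L: int) -> np.ndarray:
    n = len(coords) - L + 1
    idx = np.arange(L)[None, :] + np.arange(n)[:, None]
    return coords[idx]


def _pairwise_window_rmsd(wa: np.ndarray, wb: np.ndarray) -> np.ndarray:
    """RMSD of every window of A against every window of B (batched Kabsch).

    Uses the singular-value identity rmsd² = (Ga + Gb − 2·D)/L with the
    smallest singular value sign-flipped for improper covariance matrices.
    """
    L = wa.shape[1]
    ac = wa - wa.mean(axis=1, keepdims=True)
    bc = wb - wb.mean(axis=1, keepdims=True)
    ga = np.sum(ac ** 2, axis=(1, 2))
    gb = np.sum(bc ** 2, axis=(1, 2))
    H = np.einsum("aik,bim->abkm", ac, bc)
    S = np.linalg.svd(H, compute_uv=False)
    sign = np.sign(np.linalg.det(H))
    sign[sign == 0] = 1.0
    D = S[..., 0] + S[..., 1] + sign * S[..., 2]
    msd = (ga[:, None] + gb[None, :] - 2.0 * D) / L
    return np.sqrt(np.maximum(msd, 0.0))


def _afp_arrays(A: CaTrace, B: CaTrace, afp_len: int, afp_rmsd_max: float
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(A) < afp_len or len(B) < afp_len:
        raise ValueError(f"both traces must have >= {afp_len} residues")
    r = _pairwise_window_rmsd(_windows(A.coords, afp_len), _windows(B.coords, afp_len))
    ii, jj = np.nonzero(r <= afp_rmsd_max)
    return ii, jj, r[ii, jj]


def find_afps(A: CaTrace, B: CaTrace, afp_len: int = 8,
              afp_rmsd_max: float = 3.0) -> list[AFP]:
    """All gapless window pairs of length ``afp_len`` superposing within
    ``afp_rmsd_max`` Å."""
    ii, jj, _ = _afp_arrays(A, B, afp_len, afp_rmsd_max)
    return [AFP(int(i), int(j), afp_len) for i, j in zip(ii, jj)]


def _match_scores(da: np.ndarray, d_c: float) -> np.ndarray:
    return np.maximum(0.0, 1.0 - (da / d_c) ** 2)


def _monotone_dp(S: np.ndarray) -> tuple[list[tuple[int, int]], float]:
    """Best strictly-increasing matching maximizing Σ S over matched cells.

    Cells with S ≤ 0 cannot be matched.  O(n·m) via row-wise prefix maxima.
    """
    n, m = S.shape
    NEG = -1.0
    B = np.zeros((n + 1, m + 1))
    M = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        row = np.where(S[i - 1] > 0.0, S[i - 1] + B[i - 1, :-1], NEG)
        M[i, 1:] = row
        B[i, 1:] = np.maximum.accumulate(np.maximum(row, B[i - 1, 1:]))
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0 and B[i, j] > 0:
        if B[i, j] == B[i - 1, j]:
            i -= 1
        elif B[i, j] == B[i, j - 1]:
            j -= 1
        else:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
    pairs.reverse()
    return pairs, float(B[n, m])


def _filter_short_runs(pairs: list[tuple[int, int]], S: np.ndarray,
                       min_run: int = 4) -> tuple[list[tuple[int, int]], float]:
    """Drop matched runs shorter than ``min_run`` consecutive equivalences.

    Keeps the equivalence list at fragment granularity: isolated one- or
    two-residue coincidences are noise, and they fragment the unaligned
    intervals that flexible alignment needs for additional blocks.
    """
    kept: list[tuple[int, int]] = []
    run: list[tuple[int, int]] = []
    for p in pairs:
        if run and p[0] == run[-1][0] + 1 and p[1] == run[-1][1] + 1:
            run.append(p)
        else:
            if len(run) >= min_run:
                kept.extend(run)
            run = [p]
    if len(run) >= min_run:
        kept.extend(run)
    total = float(sum(S[a, b] for a, b in kept))
    return kept, total


def _seed_transforms(A: CaTrace, B: CaTrace,
                     ii: np.ndarray, jj: np.ndarray, rr: np.ndarray,
                     params: AlignParams) -> list[Superposition]:
    """Diverse, low-RMSD AFP superpositions to seed the iterative matching.

    Only the chosen seeds (one per diagonal/position bucket) get a full
    Kabsch solve.  Candidates are ranked by the support of their diagonal
    (how many AFPs share the same i→j offset — long alignable runs beat
    isolated helix-on-helix coincidences), then by window RMSD.
    """
    L = params.afp_len
    diag = jj - ii
    uniq, inv, counts = np.unique(diag, return_inverse=True, return_counts=True)
    support = counts[inv]
    order = np.lexsort((jj, ii, rr, -support))
    seeds, seen = [], set()
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        bucket = ((j - i) // L, i // (2 * L))
        if bucket in seen:
            continue
        seen.add(bucket)
        seeds.append(kabsch(A.coords[i:i + L], B.coords[j:j + L]))
        if len(seeds) >= params.n_seeds:
            break
    return seeds


def _refine(A: CaTrace, B: CaTrace, sup: Superposition,
            params: AlignParams) -> tuple[list[tuple[int, int]], Superposition, float]:
    """Iterate (superpose → monotone match → re-superpose) from a seed."""
    best: tuple[list[tuple[int, int]], Superposition, float] = ([], sup, 0.0)
    for _ in range(params.refine_iters):
        moved = sup.apply(A.coords)
        d = np.linalg.norm(moved[:, None, :] - B.coords[None, :, :], axis=-1)
        S = _match_scores(d, params.d_c)
        pairs, _ = _monotone_dp(S)
        pairs, total = _filter_short_runs(pairs, S)
        if len(pairs) < 3:
            break
        if total > best[2]:
            best = (pairs, sup, total)
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        try:
            sup = kabsch(A.coords[ia], B.coords[ib])
        except ValueError:
            break
    return best


def _rigid_core(A: CaTrace, B: CaTrace, params: AlignParams
                ) -> tuple[list[tuple[int, int]], Superposition, float]:
    """Best single-superposition matching; returns (pairs, sup, Σ position scores)."""
    try:
        ii, jj, rr = _afp_arrays(A, B, params.afp_len, params.afp_rmsd_max)
    except ValueError:
        return [], Superposition.identity(), 0.0
    if len(ii) == 0:
        return [], Superposition.identity(), 0.0
    best: tuple[list[tuple[int, int]], Superposition, float] = ([], Superposition.identity(), 0.0)
    for seed in _seed_transforms(A, B, ii, jj, rr, params):
        cand = _refine(A, B, seed, params)
        if cand[2] > best[2]:
            best = cand
    return best


def _finish(A: CaTrace, B: CaTrace, blocks, params: AlignParams) -> StructAlignment:
    """Assemble a StructAlignment from per-block (pairs, superposition)."""
    blocks = [b for b in blocks if b[0]]
    if not blocks:
        return StructAlignment.empty()
    blocks.sort(key=lambda b: b[0][0][0])
    pairs: list[tuple[int, int]] = []
    sups: list[Superposition] = []
    twists: list[Twist] = []
    dev2 = []
    score_sum = 0.0
    for k, (bp, sup) in enumerate(blocks):
        if k > 0:
            twists.append(Twist(boundary=len(pairs), transform=sup))
        ia = [p[0] for p in bp]
        ib = [p[1] for p in bp]
        d = np.linalg.norm(sup.apply(A.coords[ia]) - B.coords[ib], axis=1)
        score_sum += float(np.sum(_match_scores(d, params.d_c)))
        dev2.append(d ** 2)
        pairs.extend(bp)
        sups.append(sup)
    n_twists = len(blocks) - 1
    raw = max(0.0, params.s0 * score_sum - params.twist_penalty * n_twists)
    rmsd = float(np.sqrt(np.mean(np.concatenate(dev2))))
    ident = _seq_identity_from_pairs(pairs, A.sequence, B.sequence)
    return StructAlignment(pairs=pairs, twists=twists, rmsd=rmsd,
                           raw_score=raw, p_value=1.0, seq_identity=ident,
                           superpositions=sups)


def _canonical_order(A: CaTrace, B: CaTrace) -> bool:
    """True when (A, B) should be swapped before aligning.

    The key is rigid-invariant (length, internal step-length signature,
    sequence), so the same unordered pair is always computed in the same
    direction and raw_score(A, B) == raw_score(B, A) exactly.
    """

    def key(t: CaTrace):
        steps = np.linalg.norm(np.diff(t.coords, axis=0), axis=1)
        return (len(t), round(float(steps.sum()), 4), t.sequence)

    return key(A) > key(B)


def _mirror(aln: StructAlignment) -> StructAlignment:
    pairs = [(b, a) for a, b in aln.pairs]
    sups = []
    for sup in aln.superpositions:
        R = sup.rotation.T
        sups.append(Superposition(R, -R @ sup.translation, sup.rmsd))
    twists = [Twist(t.boundary, sups[k + 1]) for k, t in enumerate(aln.twists)]
    return StructAlignment(pairs=pairs, twists=twists, rmsd=aln.rmsd,
                           raw_score=aln.raw_score, p_value=aln.p_value,
                           seq_identity=aln.seq_identity, superpositions=sups)


def rigid_align(A: CaTrace, B: CaTrace, params: AlignParams | None = None) -> StructAlignment:
    """Rigid-body alignment: one global superposition, monotone equivalences.

    Returns an empty alignment (n_equiv 0, p 1) when no fragment pair can
    be chained.
    """
    params = params or AlignParams()
    if _canonical_order(A, B):
        return _mirror(rigid_align(B, A, params))
    pairs, sup, _ = _rigid_core(A, B, params)
    if not pairs:
        return StructAlignment.empty()
    return _finish(A, B, [(pairs, sup)], params)


def _gap_intervals(pairs: list[tuple[int, int]], nA: int, nB: int, min_len: int
                   ) -> list[tuple[int, int, int, int]]:
    """Unaligned (a0, a1, b0, b1) index ranges consistent with the matching."""
    out = []
    ext = [(-1, -1)] + pairs + [(nA, nB)]
    for (a0, b0), (a1, b1) in zip(ext[:-1], ext[1:]):
        if a1 - a0 - 1 >= min_len and b1 - b0 - 1 >= min_len:
            out.append((a0 + 1, a1, b0 + 1, b1))
    return out


def flexible_align(A: CaTrace, B: CaTrace, params: AlignParams | None = None) -> StructAlignment:
    """Flexible alignment: rigid blocks joined by twists.

    Starts from the rigid solution and greedily aligns the leftover
    sequence intervals as additional rigid blocks; a block is kept only if
    its score gain exceeds the twist penalty, so the flexible score is
    never below the rigid one.
    """
    params = params or AlignParams()
    if _canonical_order(A, B):
        return _mirror(flexible_align(B, A, params))
    base = _rigid_core(A, B, params)
    if not base[0]:
        return StructAlignment.empty()
    blocks = [(base[0], base[1])]
    while len(blocks) - 1 < params.max_twists:
        matched = sorted(p for b in blocks for p in b[0])
        intervals = _gap_intervals(matched, len(A), len(B), params.afp_len)
        best_gain, best_block = 0.0, None
        for a0, a1, b0, b1 in intervals:
            subA = A.subtrace(range(a0, a1))
            subB = B.subtrace(range(b0, b1))
            bp, sup, total = _rigid_core(subA, subB, params)
            gain = params.s0 * total - params.twist_penalty
            if bp and gain > best_gain:
                best_block = ([(a + a0, b + b0) for a, b in bp], sup)
                best_gain = gain
        if best_block is None:
            break
        blocks.append(best_block)
    return _finish(A, B, blocks, params)


def alignment_score(deviations, n_twists: int = 0,
                    params: AlignParams | None = None) -> float:
    """Raw score s0·Σ max(0, 1 − (d/d_c)²) − t0·n_twists, floored at 0."""
    params = params or AlignParams()
    d = np.asarray(deviations, dtype=float)
    if np.any(d < 0):
        raise ValueError("deviations must be >= 0")
    core = float(np.sum(_match_scores(d, params.d_c)))
    return max(0.0, params.s0 * core - params.twist_penalty * n_twists)


def calibrate_null(bundle_pair_generator, n: int, seed: int,
                   params: AlignParams | None = None) -> NullCalibration:
    """Fit a Gumbel null to raw scores of unrelated structure pairs.

    ``bundle_pair_generator(seed) -> (CaTrace, CaTrace)`` supplies random,
    independently generated pairs with a matched length distribution; the
    maximum-likelihood Gumbel fit over their flexible-alignment scores
    defines the P-value map.
    """
    if n < 50:
        raise ValueError("need n >= 50 null samples")
    params = params or AlignParams()
    scores = []
    for k in range(n):
        A, B = bundle_pair_generator(seed * 100003 + k)
        scores.append(flexible_align(A, B, params).raw_score)
    scores = np.asarray(scores)
    if np.ptp(scores) < 1e-9:
        raise ValueError("degenerate null: all scores equal")
    loc, scale = stats.gumbel_r.fit(scores)
    return NullCalibration(location=float(loc), scale=float(scale),
                           n_samples=n, seed=seed)


def score_pvalue(score: float, cal: NullCalibration) -> float:
    """Right-tail Gumbel probability of a null score ≥ ``score``."""
    z = (score - cal.location) / cal.scale
    if z < -30.0:
        return 1.0
    p = float(-np.expm1(-np.exp(-z)))
    return min(1.0, max(1e-300, p))


def _core_block_coords(trace: CaTrace, core, labels, member: int) -> np.ndarray:
    chunks = []
    for lab in labels:
        seg_a, seg_b = core[lab]
        seg = (seg_a, seg_b)[member]
        other = (seg_a, seg_b)[1 - member]
        L = min(seg.end_index - seg.start_index, other.end_index - other.start_index) + 1
        chunks.append(trace.coords[seg.start_index:seg.start_index + L])
    return np.vstack(chunks)


def block_rotation(A: CaTrace, B: CaTrace, core,
                   ref: tuple[str, ...] = ("c4", "c5", "c6"),
                   moving: tuple[str, ...] = ("c1", "c2", "c3")) -> RotationReport:
    """Rotation of one core-helix block relative to another between structures.

    After superposing the reference block of A onto that of B, the residual
    rotation that maps A's moving block onto B's is reported as axis-angle
    (angle in [0, 180]°, axis right-handed).  Matched helices are truncated
    to common length from their N-terminal ends.
    """
    ref = tuple(ref)
    moving = tuple(moving)
    for lab in ref + moving:
        if lab not in core.labels:
            raise LookupError(f"core label {lab!r} absent; have {core.labels}")
    refA = _core_block_coords(A, core, ref, 0)
    refB = _core_block_coords(B, core, ref, 1)
    movA = _core_block_coords(A, core, moving, 0)
    movB = _core_block_coords(B, core, moving, 1)
    if len(refA) < 9 or len(movA) < 9:
        raise ValueError("blocks must contain at least 9 residues")
    sup_ref = kabsch(refA, refB)
    sup_res = kabsch(sup_ref.apply(movA), movB)
    rotvec = Rotation.from_matrix(sup_res.rotation).as_rotvec()
    angle = float(np.rad2deg(np.linalg.norm(rotvec)))
    axis = rotvec / np.linalg.norm(rotvec) if angle > 1e-9 else np.array([0.0, 0.0, 1.0])
    return RotationReport(axis=axis, angle=angle,
                          reference_block=ref, moving_block=moving)


def _seq_identity_from_pairs(pairs, seqA: str, seqB: str) -> float:
    if not pairs:
        return 0.0
    same = sum(1 for a, b in pairs if seqA[a] == seqB[b])
    return 100.0 * same / len(pairs)


def seq_identity(aln: StructAlignment, seqA: str, seqB: str) -> float:
    """Percent identical one-letter codes over equivalenced pairs."""
    if aln.n_equiv == 0:
        raise ValueError("sequence identity undefined for an empty alignment")
    return _seq_identity_from_pairs(aln.pairs, seqA, seqB)
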