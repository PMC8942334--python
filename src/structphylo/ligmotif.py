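"""Sequence motifs, ligand coordinate transfer, and contact-site conservation.

Covers the catalytic aspartate-rich DDxxD motif of terpene synthases, the
WRS motif whose arginine is the major ligand contact in estrogen-receptor
LBDs, and the basic residues (Arg/Lys/Gln) that replace DDxxD in nuclear
receptors.  Ligand "overlap" claims are evaluated geometrically: crystal
or planted ligand poses are carried through a structural superposition by
rigid coordinate transfer and contact residues are compared across the
equivalence map — no docking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .align3d import StructAlignment, Superposition
from .structio import CaTrace, LigandPose

__all__ = [
    "MotifHit",
    "ContactSet",
    "ContactOverlap",
    "MOTIF_PATTERNS",
    "find_motifs",
    "transfer_ligand",
    "contact_residues",
    "contact_overlap",
]

#: Registered motif patterns (regular expressions over one-letter codes).
#: BASIC includes Gln alongside the true basics, matching the replacement
#: set observed at the DDxxD-equivalent position in nuclear receptors.
MOTIF_PATTERNS: dict[str, str] = {
    "DDxxD": "DD..D",
    "WRS": "WRS",
    "BASIC": "[RKQ]",
}

DEFAULT_CUTOFF = {"all-atom": 4.5, "ca-only": 8.0}


@dataclass(frozen=True)
class MotifHit:
    pattern_name: str
    start_index: int
    matched_text: str
    residue_numbers: tuple[int, ...]  # author numbering when known


@dataclass
class ContactSet:
    """Residues (trace indices) within ``cutoff`` of any ligand atom."""

    indices: list[int]
    cutoff: float
    mode: str

    def __post_init__(self) -> None:
        self.indices = sorted(int(i) for i in self.indices)

    def __contains__(self, i: int) -> bool:
        return i in set(self.indices)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class ContactOverlap:
    a_in_b: float    # fraction of A's contacts equivalenced onto B contacts
    b_in_a: float
    jaccard: float   # over equivalenced pairs


def find_motifs(seq: str, pattern_name: str,
                residue_numbers=None) -> list[MotifHit]:
    """All matches of a registered motif, left to right.

    Overlapping matches are reported as long as they start at distinct
    positions (lookahead search).  ``residue_numbers`` optionally maps
    sequence positions to author numbering for reporting.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    try:
        pattern = MOTIF_PATTERNS[pattern_name]
    except KeyError:
        raise LookupError(
            f"unknown motif {pattern_name!r}; registered: {sorted(MOTIF_PATTERNS)}"
        ) from None
    hits = []
    for m in re.finditer(f"(?=({pattern}))", seq):
        start = m.start()
        text = m.group(1)
        nums = tuple(residue_numbers[start:start + len(text)]) if residue_numbers else \
            tuple(range(start + 1, start + len(text) + 1))
        hits.append(MotifHit(pattern_name, start, text, nums))
    return hits


def transfer_ligand(pose: LigandPose, sup: Superposition) -> LigandPose:
    """Map every ligand atom x → R·x + t; names preserved (rigid transfer)."""
    return LigandPose(pose.ligand_name, list(pose.atom_names),
                      sup.apply(pose.coords))


def contact_residues(target, pose: LigandPose, cutoff: float | None = None,
                     mode: str = "ca-only") -> ContactSet:
    """Residues whose atoms come within ``cutoff`` Å of any ligand atom.

    ``target`` is a CaTrace (ca-only mode, default cutoff 8 Å) or a list of
    AtomRecord (all-atom mode, default 4.5 Å); indices refer to residue
    order in the target.
    """
    if mode not in DEFAULT_CUTOFF:
        raise ValueError(f"mode must be one of {sorted(DEFAULT_CUTOFF)}")
    cutoff = DEFAULT_CUTOFF[mode] if cutoff is None else cutoff
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if len(pose.coords) == 0:
        raise ValueError("ligand pose is empty")
    if isinstance(target, CaTrace):
        d = np.linalg.norm(target.coords[:, None, :] - pose.coords[None, :, :], axis=-1)
        idx = np.nonzero(d.min(axis=1) <= cutoff)[0]
        return ContactSet(list(idx), cutoff, mode)
    # all-atom: group AtomRecords by residue in order of first appearance
    residues: dict[tuple, list[np.ndarray]] = {}
    for a in target:
        if a.is_hetero:
            continue
        residues.setdefault((a.chain_id, a.res_seq, a.insertion_code), []).append(a.position)
    idx = []
    for i, (key, coords) in enumerate(residues.items()):
        arr = np.asarray(coords)
        d = np.linalg.norm(arr[:, None, :] - pose.coords[None, :, :], axis=-1)
        if d.min() <= cutoff:
            idx.append(i)
    return ContactSet(idx, cutoff, mode)


def contact_overlap(aln: StructAlignment, cA: ContactSet, cB: ContactSet) -> ContactOverlap:
    """Conservation of contact sites across an alignment.

    ``a_in_b``: fraction of A's contact residues whose equivalenced partner
    is a contact residue of B; ``b_in_a`` the reverse; ``jaccard`` over the
    equivalenced pairs touching either contact set.
    """
    if len(cA) == 0:
        raise ValueError("contact overlap undefined: contact set A is empty")
    fwd = aln.mapping()
    rev = {b: a for a, b in aln.pairs}
    setA, setB = set(cA.indices), set(cB.indices)
    a_in_b = sum(1 for a in setA if fwd.get(a) in setB) / len(setA)
    b_in_a = (sum(1 for b in setB if rev.get(b) in setA) / len(setB)) if setB else 0.0
    both = sum(1 for a, b in aln.pairs if a in setA and b in setB)
    either = sum(1 for a, b in aln.pairs if a in setA or b in setB)
    jac = both / either if either else 0.0
    return ContactOverlap(a_in_b=a_in_b, b_in_a=b_in_a, jaccard=jac)
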