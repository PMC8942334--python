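"""PDB-format coordinate I/O and extraction of chains, Cα traces, and ligands.

Fixed-column PDB v3.3 ATOM/HETATM/MODEL/TER/ENDMDL records are supported;
gemmi does the heavy lifting behind a small record model suited to the
Cα-level geometry used everywhere else in the package.  Coordinates are
Ångström throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "CaTrace",
    "LigandPose",
    "PDBParseError",
    "parse_pdb",
    "write_pdb",
    "select_chain",
    "ca_trace",
    "extract_ligands",
]

# Cα-Cα distance window treated as a connected peptide step.
CA_STEP_MIN = 2.0
CA_STEP_MAX = 4.5

#: minimum number of amino-acid residues for AUTO chain selection
AUTO_MIN_RESIDUES = 30

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class PDBParseError(ValueError):
    """Raised for malformed PDB input."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    alt_loc: str          # '' when blank
    res_name: str
    chain_id: str
    res_seq: int
    insertion_code: str   # '' when blank
    position: np.ndarray  # shape (3,), Å
    element: str
    occupancy: float
    is_hetero: bool

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Structure:
    """Parsed coordinate set: one or more models, each a flat atom list."""

    id: str
    models: list[list[AtomRecord]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.models:
            self.models = [[]]

    @property
    def n_models(self) -> int:
        return len(self.models)

    def chains(self, model_index: int = 0) -> list[str]:
        """Chain ids present in a model, in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.models[model_index]:
            seen.setdefault(a.chain_id, None)
        return list(seen)


@dataclass
class CaTrace:
    """Ordered Cα coordinates with residue labels; the unit of all alignment.

    ``labels[i]`` is ``(res_seq, insertion_code, res_name, one_letter)``.
    ``breaks`` holds indices i where the i→i+1 step falls outside the
    peptide-bond window [2.0, 4.5] Å (recorded, never fatal).
    """

    labels: list[tuple[int, str, str, str]]
    coords: np.ndarray
    breaks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.labels) != len(self.coords):
            raise ValueError("labels and coords must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def sequence(self) -> str:
        return "".join(lab[3] for lab in self.labels)

    def segment_id(self) -> np.ndarray:
        """Integer id of the unbroken chain segment each residue belongs to."""
        seg = np.zeros(len(self), dtype=int)
        k = 0
        brk = set(self.breaks)
        for i in range(1, len(self)):
            if i - 1 in brk:
                k += 1
            seg[i] = k
        return seg

    def subtrace(self, indices) -> "CaTrace":
        idx = list(indices)
        labels = [self.labels[i] for i in idx]
        coords = self.coords[idx]
        iset = set(idx)
        pos = {v: k for k, v in enumerate(idx)}
        breaks = [pos[i] for i in self.breaks if i in iset and i + 1 in iset and pos.get(i + 1, -1) == pos[i] + 1]
        return CaTrace(labels, coords, breaks)


@dataclass
class LigandPose:
    ligand_name: str
    atom_names: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.coords) == 0:
            raise ValueError("ligand pose must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("ligand coordinates must be finite")
        if len(self.atom_names) != len(self.coords):
            raise ValueError("atom_names and coords must have equal length")


def _validate_coordinate_columns(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fieldtxt = line[lo:hi]
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed {what} coordinate field {fieldtxt!r}"
                    ) from None


def one_letter_code(res_name: str) -> str:
    """Three-letter → one-letter residue code.

    Nonstandard amino acids (MSE, ...) map to their parent one-letter code
    via gemmi's residue table; anything unresolved becomes 'X'.
    """
    info = gemmi.find_tabulated_residue(res_name)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _is_amino_acid(res_name: str) -> bool:
    info = gemmi.find_tabulated_residue(res_name)
    return info is not None and info.is_amino_acid()


def parse_pdb(text: str, structure_id: str = "") -> Structure:
    """Parse a PDB-format string into a :class:`Structure`.

    MODEL blocks become separate models; TER delimits chains.  A malformed
    fixed-width coordinate field raises :class:`PDBParseError` naming the
    line; input without any ATOM/HETATM record is an error.
    """
    _validate_coordinate_columns(text)
    try:
        gst = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi message passthrough
        raise PDBParseError(str(exc)) from exc
    models: list[list[AtomRecord]] = []
    for model in gst:
        atoms: list[AtomRecord] = []
        for chain in model:
            for res in chain:
                het = res.het_flag == "H"
                for atom in res:
                    alt = atom.altloc if atom.altloc not in ("\x00", " ") else ""
                    atoms.append(
                        AtomRecord(
                            serial=atom.serial,
                            atom_name=atom.name,
                            alt_loc=alt,
                            res_name=res.name,
                            chain_id=chain.name,
                            res_seq=res.seqid.num,
                            insertion_code=(res.seqid.icode or "").strip(),
                            position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            element=atom.element.name,
                            occupancy=float(atom.occ),
                            is_hetero=het,
                        )
                    )
        models.append(atoms)
    if not any(models):
        raise PDBParseError("no ATOM or HETATM records found")
    return Structure(id=structure_id or (gst.name or ""), models=models)


def write_pdb(s: Structure) -> str:
    """Serialize a :class:`Structure` as fixed-column PDB text.

    Coordinates are written to 3 decimals and round-trip through
    :func:`parse_pdb`.  A coordinate of magnitude ≥ 10000 Å cannot be
    represented in the fixed 8-column field and raises ``ValueError``.
    """
    for atoms in s.models:
        for a in atoms:
            if np.any(np.abs(a.position) >= 10000.0):
                raise ValueError(
                    f"atom {a.serial}: coordinate magnitude >= 10000 Å overflows PDB columns"
                )
    gst = gemmi.Structure()
    gst.name = s.id or "XXXX"
    for mi, atoms in enumerate(s.models):
        model = gemmi.Model(mi + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        for a in atoms:
            if a.chain_id not in chain_map:
                chain_map[a.chain_id] = gemmi.Chain(a.chain_id or "A")
            chain = chain_map[a.chain_id]
            key = (a.res_seq, a.insertion_code, a.res_name)
            if len(chain) == 0 or (chain[-1].seqid.num, (chain[-1].seqid.icode or "").strip(), chain[-1].name) != key:
                res = gemmi.Residue()
                res.name = a.res_name
                res.seqid = gemmi.SeqId(a.res_seq, a.insertion_code or " ")
                res.het_flag = "H" if a.is_hetero else "A"
                chain.add_residue(res)
            res = chain[-1]
            atom = gemmi.Atom()
            atom.name = a.atom_name
            atom.altloc = a.alt_loc or "\x00"
            atom.pos = gemmi.Position(*a.position)
            atom.occ = a.occupancy
            atom.element = gemmi.Element(a.element or "X")
            atom.serial = a.serial
            res.add_atom(atom)
        for chain in chain_map.values():
            model.add_chain(chain)
        gst.add_model(model)
    gst.setup_entities()
    opts = gemmi.PdbWriteOptions()
    opts.cryst1_record = False
    return gst.make_pdb_string(opts)


def select_chain(s: Structure, chain_id: str = "AUTO", model_index: int = 0) -> list[AtomRecord]:
    """Atoms of one chain of one model.

    ``AUTO`` picks the first chain with ≥ 30 amino-acid residues
    (hetero-only chains are skipped); an explicit id must exist.
    """
    if not 0 <= model_index < s.n_models:
        raise IndexError(f"model {model_index} absent; structure has {s.n_models} model(s)")
    atoms = s.models[model_index]
    if chain_id == "AUTO":
        for cid in s.chains(model_index):
            n_aa = len({(a.res_seq, a.insertion_code) for a in atoms
                        if a.chain_id == cid and not a.is_hetero and _is_amino_acid(a.res_name)})
            if n_aa >= AUTO_MIN_RESIDUES:
                return [a for a in atoms if a.chain_id == cid]
        # fall back to the largest polymer chain
        best, best_n = None, -1
        for cid in s.chains(model_index):
            n_aa = len({(a.res_seq, a.insertion_code) for a in atoms
                        if a.chain_id == cid and not a.is_hetero and _is_amino_acid(a.res_name)})
            if n_aa > best_n:
                best, best_n = cid, n_aa
        if best is None or best_n == 0:
            raise LookupError("no polymer chain found for AUTO selection")
        return [a for a in atoms if a.chain_id == best]
    available = s.chains(model_index)
    if chain_id not in available:
        raise LookupError(f"chain {chain_id!r} absent; available: {available}")
    return [a for a in atoms if a.chain_id == chain_id]


def ca_trace(chain_atoms: list[AtomRecord]) -> CaTrace:
    """Cα trace of a chain: one Cα per amino-acid residue.

    altLoc duplicates resolve to the highest occupancy (ties alphabetical);
    hetero residues are excluded; residues are ordered by
    (res_seq, insertion_code).  Steps outside [2.0, 4.5] Å are recorded as
    chain breaks.
    """
    per_res: dict[tuple[int, str], AtomRecord] = {}
    res_names: dict[tuple[int, str], str] = {}
    for a in chain_atoms:
        if a.is_hetero or a.atom_name != "CA" or not _is_amino_acid(a.res_name):
            continue
        key = (a.res_seq, a.insertion_code)
        cur = per_res.get(key)
        if cur is None or (a.occupancy, _alt_rank(a.alt_loc)) > (cur.occupancy, _alt_rank(cur.alt_loc)):
            per_res[key] = a
            res_names[key] = a.res_name
    if len(per_res) < 5:
        raise ValueError(f"chain too short: {len(per_res)} residues with a CA atom (need >= 5)")
    keys = sorted(per_res)
    labels = [(k[0], k[1], res_names[k], one_letter_code(res_names[k])) for k in keys]
    coords = np.array([per_res[k].position for k in keys])
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    breaks = [int(i) for i in np.nonzero((steps < CA_STEP_MIN) | (steps > CA_STEP_MAX))[0]]
    return CaTrace(labels, coords, breaks)


def _alt_rank(alt: str) -> float:
    # higher is better; blank altloc wins over lettered at equal occupancy,
    # and 'A' beats 'B' (alphabetical tie-break)
    if alt == "":
        return 0.0
    return -ord(alt)


def extract_ligands(s: Structure, exclude: frozenset[str] = frozenset(),
                    model_index: int = 0) -> list[LigandPose]:
    """Hetero residues as ligand poses, excluding water and ``exclude`` names.

    One pose per hetero residue instance, in file order.
    """
    skip = WATER_NAMES | set(exclude)
    poses: list[LigandPose] = []
    order: list[tuple[str, int, str, str]] = []
    grouped: dict[tuple[str, int, str, str], list[AtomRecord]] = {}
    for a in s.models[model_index]:
        if not a.is_hetero or a.res_name in skip or _is_amino_acid(a.res_name):
            continue
        key = (a.chain_id, a.res_seq, a.insertion_code, a.res_name)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(a)
    for key in order:
        atoms = grouped[key]
        poses.append(
            LigandPose(
                ligand_name=key[3],
                atom_names=[a.atom_name for a in atoms],
                coords=np.array([a.position for a in atoms]),
            )
        )
    return poses
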