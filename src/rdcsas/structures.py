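"""Coordinate models, multi-model PDB I/O, and idealized A-form helix construction.

The in-memory model is deliberately small: a :class:`Conformer` is an ordered
list of residues with named atoms, and a :class:`ConformerLibrary` is a pool
of conformers sharing one sequence and residue numbering — the object the
sample-and-select stage draws from.

The A-form builder places rigid idealized nucleotide templates (see
``_templates``) with a screw operator (one helical twist + rise per base-pair
step), so the helical parameters recomputed from its output match the
parameter table exactly.  Strand II is generated from strand I by the pair
dyad.  The same operator drives in-silico elongation of helix termini, which
mimics the experimentally elongated constructs used to modulate alignment.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import _templates
from ._geometry import kabsch, rotation_z

__all__ = [
    "Atom",
    "Residue",
    "Conformer",
    "ConformerLibrary",
    "HelixSpec",
    "StructureFormatError",
    "AFORM",
    "read_models",
    "write_models",
    "read_energy_table",
    "write_energy_table",
    "build_aform_helix",
    "elongate_in_silico",
    "filter_library",
    "is_complementary",
]


class StructureFormatError(ValueError):
    """Raised for structurally malformed or inconsistent coordinate input."""


#: Idealized A-form helix parameters (editable in one place).  Twist/rise are
#: fiber-diffraction A-RNA values.  The placement entries are the rigid-body
#: pose of the strand-I nucleotide in the level-0 base-pair frame (glycosidic
#: nitrogen position plus the orientation of the N->C1' axis and the spin
#: about it), calibrated once against backbone O3'-P connectivity under the
#: screw operator, Watson-Crick hydrogen-bond distances across the pair dyad,
#: and sequential base-stacking overlap.  Strand II is the dyad image.
AFORM = {
    "twist_deg": 32.7,        # helical twist per bp step
    "rise": 2.81,             # A per bp step along the axis
    "c1_c1_pair": 10.46,      # resulting C1'-C1' span across a pair (info)
    "pucker_p": 18.0,         # ribose pseudorotation phase of helical residues
    "glyc_pos": (2.18428245, 3.29247565, -2.95243265),
    "axis_theta": 1.97032364,  # polar angle of the N->C1' direction (rad)
    "axis_phi": 0.43522585,    # azimuth of the N->C1' direction (rad)
    "spin": 2.02991668,        # rotation about the N->C1' axis (rad)
}

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def is_complementary(a: str, b: str) -> bool:
    """Watson-Crick or G-U wobble complementarity."""
    return (a.upper(), b.upper()) in _WC_PAIRS


def wc_partner(base: str) -> str:
    return {"A": "U", "U": "A", "G": "C", "C": "G"}[base.upper()]


def _norm_atom_name(name: str) -> str:
    """Canonical atom naming: primes written as ', not *."""
    return name.replace("*", "'").strip()


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self):
        self.name = _norm_atom_name(self.name)
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coordinate must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class Residue:
    index: int
    name: str
    chain: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            if a.name in seen:
                raise ValueError(f"residue {self.index}: duplicate atom {a.name!r}")
            seen.add(a.name)

    @property
    def base(self) -> str:
        """One-letter base identity (strips modification decorations)."""
        return self.name.strip()[-1].upper()

    def atom(self, name: str) -> Atom:
        name = _norm_atom_name(name)
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.chain}{self.index}: no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        name = _norm_atom_name(name)
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() != "H"]


@dataclass
class Conformer:
    residues: list[Residue]
    model_id: int = 1
    energy: float | None = None

    def __post_init__(self):
        by_chain: dict[str, int] = {}
        for r in self.residues:
            prev = by_chain.get(r.chain)
            if prev is not None and r.index <= prev:
                raise ValueError(
                    f"residue indices must strictly increase within chain "
                    f"{r.chain!r} (got {r.index} after {prev})")
            by_chain[r.chain] = r.index

    def residue(self, index: int, chain: str | None = None) -> Residue:
        for r in self.residues:
            if r.index == index and (chain is None or r.chain == chain):
                return r
        raise KeyError(f"no residue with index {index}")

    def has_residue(self, index: int) -> bool:
        return any(r.index == index for r in self.residues)

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        rows = []
        for r in self.residues:
            for a in (r.heavy_atoms() if heavy_only else r.atoms):
                rows.append(a.coord)
        return np.array(rows)

    def atom_coords(self, selection: list[tuple[int, str]]) -> np.ndarray:
        """Coordinates for an explicit list of (residue_index, atom_name)."""
        return np.array([self.residue(i).atom(n).coord for i, n in selection])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Conformer":
        """A copy with every coordinate mapped through x -> R x + t."""
        out = copy.deepcopy(self)
        for r in out.residues:
            for a in r.atoms:
                a.coord = R @ a.coord + t
        return out

    @property
    def sequence(self) -> str:
        return "".join(r.base for r in self.residues)


@dataclass
class ConformerLibrary:
    conformers: list[Conformer]
    sequence: str = ""
    source: str = ""

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("a conformer library must contain at least one conformer")
        if not self.sequence:
            self.sequence = self.conformers[0].sequence
        ref = [(r.chain, r.index, r.name) for r in self.conformers[0].residues]
        for c in self.conformers:
            ids = [(r.chain, r.index, r.name) for r in c.residues]
            if ids != ref:
                raise StructureFormatError(
                    f"model {c.model_id}: residue set differs from model "
                    f"{self.conformers[0].model_id}")

    def __len__(self) -> int:
        return len(self.conformers)

    def __getitem__(self, i: int) -> Conformer:
        return self.conformers[i]

    def __iter__(self):
        return iter(self.conformers)


@dataclass
class HelixSpec:
    strand1_seq: str
    strand2_seq: str
    strand1_numbers: tuple[int, ...]
    strand2_numbers: tuple[int, ...]
    chain: str = "A"
    allow_noncomplementary: bool = False

    def __post_init__(self):
        self.strand1_seq = self.strand1_seq.upper()
        self.strand2_seq = self.strand2_seq.upper()
        self.strand1_numbers = tuple(self.strand1_numbers)
        self.strand2_numbers = tuple(self.strand2_numbers)
        n = len(self.strand1_seq)
        if len(self.strand2_seq) != n:
            raise ValueError("strand sequences must have equal length")
        if len(self.strand1_numbers) != n or len(self.strand2_numbers) != n:
            raise ValueError("residue number lists must match strand length")
        if not self.allow_noncomplementary:
            for k in range(n):
                a, b = self.strand1_seq[k], self.strand2_seq[n - 1 - k]
                if not is_complementary(a, b):
                    raise ValueError(
                        f"strands not reverse-complementary at pair {k} "
                        f"({a}-{b}); set allow_noncomplementary to override")

    def __len__(self) -> int:
        return len(self.strand1_seq)


# ---------------------------------------------------------------------------
# multi-model PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _element_of(name: str) -> str:
    stripped = name.strip("0123456789'")
    return stripped[0].upper() if stripped else "X"


def read_models(path: str | Path, model_range: tuple[int, int] | None = None,
                energy_table: str | Path | None = None) -> ConformerLibrary:
    """Read a (multi-model) PDB file into a :class:`ConformerLibrary`.

    ``model_range`` keeps only MODEL ids in ``[lo, hi]`` (inclusive).
    ``energy_table`` optionally attaches per-model scores from a TSV sidecar
    with columns ``model_id<TAB>energy``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    conformers = []
    for model in st:
        mid = int(model.num) if str(model.num).isdigit() else len(conformers) + 1
        if model_range is not None and not (model_range[0] <= mid <= model_range[1]):
            continue
        residues = []
        for chain in model:
            for res in chain:
                atoms = [Atom(a.name, a.element.name or _element_of(a.name),
                              np.array([a.pos.x, a.pos.y, a.pos.z]))
                         for a in res]
                residues.append(Residue(res.seqid.num, res.name.strip(), chain.name, atoms))
        if not residues:
            continue
        conformers.append(Conformer(residues, model_id=mid))
    if not conformers:
        raise StructureFormatError(f"{path}: no models found")
    if energy_table is not None:
        energies = read_energy_table(energy_table)
        for c in conformers:
            c.energy = energies.get(c.model_id)
    return ConformerLibrary(conformers, source=str(path))


def write_models(library: ConformerLibrary, path: str | Path) -> None:
    """Write a library as a standards-conformant multi-model PDB file.

    MODEL ids are renumbered sequentially from 1.
    """
    if len(library) == 0:
        raise ValueError("cannot write an empty library")
    st = gemmi.Structure()
    st.name = "rdcsas"
    for k, conf in enumerate(library, start=1):
        model = gemmi.Model(k)
        chains: dict[str, gemmi.Chain] = {}
        for r in conf.residues:
            ch = chains.get(r.chain)
            if ch is None:
                ch = gemmi.Chain(r.chain)
                chains[r.chain] = ch
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.index, " ")
            for a in r.atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.coord)
                res.add_atom(at)
            ch.add_residue(res)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
    st.renumber_models()
    doc_path = Path(path)
    try:
        st.write_pdb(str(doc_path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write {doc_path}: {exc}") from exc


def read_energy_table(path: str | Path) -> dict[int, float]:
    """Parse a ``model_id<TAB>energy`` sidecar table."""
    energies: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("model"):
                continue
            mid, val = line.split("\t")[:2]
            energies[int(mid)] = float(val)
    return energies


def write_energy_table(library: ConformerLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("model_id\tenergy\n")
        for c in library:
            if c.energy is not None:
                fh.write(f"{c.model_id}\t{c.energy:.6g}\n")


# ---------------------------------------------------------------------------
# idealized A-form construction
# ---------------------------------------------------------------------------

_PLACEMENT_CACHE: dict[tuple, dict[str, np.ndarray]] = {}


def _template_frame(tpl: dict[str, np.ndarray], base: str
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Body frame of a template nucleotide: origin at the glycosidic N,
    e1 along N->C1', e3 the base-normal component orthogonal to e1 (sign
    fixed against sugar chirality so purines and pyrimidines, whose ring
    lists wind oppositely, end up on the same face)."""
    glyc = _templates.glycosidic_atom(base)
    ring = np.array([tpl[a] for a in _templates.base_ring_atoms(base)])
    centroid = ring.mean(axis=0)
    normal = np.zeros(3)
    for i in range(len(ring)):
        normal += np.cross(ring[i] - centroid, ring[(i + 1) % len(ring)] - centroid)
    normal /= np.linalg.norm(normal)
    handed = np.cross(tpl["C1'"] - tpl["O4'"], tpl[glyc] - tpl["C1'"])
    if normal @ handed > 0:
        normal = -normal
    e1 = tpl["C1'"] - tpl[glyc]
    e1 /= np.linalg.norm(e1)
    e3 = normal - (normal @ e1) * e1
    e3 /= np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    return tpl[glyc], np.column_stack([e1, e2, e3])


def _pair_frame_nucleotide(base: str, strand: int, pucker_p: float | None = None,
                           params: dict = AFORM) -> dict[str, np.ndarray]:
    """Rigidly place a template nucleotide into the level-0 base-pair frame.

    ``strand`` is +1 for strand I (5'->3' ascending levels) and -1 for
    strand II, which is the image under the pair dyad (180 degrees about x).
    """
    if pucker_p is None:
        pucker_p = params["pucker_p"]
    key = (base, strand, round(float(pucker_p), 6), id(params))
    cached = _PLACEMENT_CACHE.get(key)
    if cached is not None:
        return {n: xyz.copy() for n, xyz in cached.items()}
    tpl = _templates.build_nucleotide(base, pucker_p)
    origin, F = _template_frame(tpl, base)
    th, ph, sg = params["axis_theta"], params["axis_phi"], params["spin"]
    u = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) <= 0.95 else np.array([1.0, 0.0, 0.0])
    w = np.cross(u, ref)
    w /= np.linalg.norm(w)
    v = np.cross(w, u)
    e3p = np.cos(sg) * w + np.sin(sg) * v
    e2p = np.cross(e3p, u)
    Fd = np.column_stack([u, e2p, e3p])
    R = Fd @ F.T
    t = np.asarray(params["glyc_pos"], dtype=float) - R @ origin
    placed = {name: R @ xyz + t for name, xyz in tpl.items()}
    if strand == -1:
        D = np.diag([1.0, -1.0, -1.0])  # pair dyad: 180 degrees about x
        placed = {name: D @ xyz for name, xyz in placed.items()}
    _PLACEMENT_CACHE[key] = {n: xyz.copy() for n, xyz in placed.items()}
    return placed


def _screw(level: int, params: dict = AFORM) -> tuple[np.ndarray, np.ndarray]:
    """Helix operator for base-pair level ``level``: rotation and translation."""
    R = rotation_z(level * params["twist_deg"])
    t = np.array([0.0, 0.0, level * params["rise"]])
    return R, t


def _residue_from_template(tpl: dict[str, np.ndarray], base: str, index: int,
                           chain: str) -> Residue:
    atoms = [Atom(name, _element_of(name), xyz) for name, xyz in tpl.items()]
    return Residue(index, base, chain, atoms)


def build_aform_helix(spec: HelixSpec, params: dict = AFORM) -> Conformer:
    """Construct an idealized double-stranded A-form helix.

    Base pair ``k`` pairs ``strand1_seq[k]`` with ``strand2_seq[n-1-k]``;
    strand I ascends the helix axis 5'->3'.  All residues share one chain
    label and are ordered by residue number.
    """
    n = len(spec)
    residues = []
    for k in range(n):
        Rk, tk = _screw(k, params)
        b1 = spec.strand1_seq[k]
        tpl1 = _pair_frame_nucleotide(b1, +1, params=params)
        tpl1 = {name: Rk @ xyz + tk for name, xyz in tpl1.items()}
        residues.append(_residue_from_template(tpl1, b1, spec.strand1_numbers[k], spec.chain))
        b2 = spec.strand2_seq[n - 1 - k]
        tpl2 = _pair_frame_nucleotide(b2, -1, params=params)
        tpl2 = {name: Rk @ xyz + tk for name, xyz in tpl2.items()}
        residues.append(_residue_from_template(tpl2, b2, spec.strand2_numbers[n - 1 - k], spec.chain))
    residues.sort(key=lambda r: (r.chain, r.index))
    return Conformer(residues, model_id=1)


def _terminal_bp_frame(conformer: Conformer, res_i: int, res_j: int,
                       params: dict = AFORM) -> tuple[np.ndarray, np.ndarray, Residue, Residue]:
    """Superpose an idealized level-0 pair onto the named terminal base pair."""
    ri = conformer.residue(res_i)
    rj = conformer.residue(res_j)
    if not is_complementary(ri.base, rj.base):
        raise ValueError(
            f"residues {res_i}({ri.base}) and {res_j}({rj.base}) are not a "
            f"complementary pair; cannot elongate here")
    d = np.linalg.norm(ri.atom("C1'").coord - rj.atom("C1'").coord)
    if not (params["c1_c1_pair"] - 3.0 <= d <= params["c1_c1_pair"] + 3.0):
        raise ValueError(
            f"residues {res_i}/{res_j}: C1'-C1' distance {d:.1f} A is not "
            f"consistent with a paired terminus")
    ref_i = _pair_frame_nucleotide(ri.base, +1, params=params)
    ref_j = _pair_frame_nucleotide(rj.base, -1, params=params)
    src, dst = [], []
    for tpl, res in ((ref_i, ri), (ref_j, rj)):
        for name, xyz in tpl.items():
            if name.startswith("H"):
                continue
            if res.has_atom(name):
                src.append(xyz)
                dst.append(res.atom(name).coord)
    R, t = kabsch(np.array(src), np.array(dst))
    return R, t, ri, rj


def elongate_in_silico(conformer: Conformer, helix_end: tuple[int, int],
                       n_bp: int, seq_pattern: str = "GC",
                       params: dict = AFORM) -> Conformer:
    """Append ``n_bp`` idealized A-form pairs coaxially at a helix terminus.

    ``helix_end`` names the terminal base pair as residue numbers
    ``(i, j)``.  Added residues extend the two strands outward, numbered
    away from the existing construct (e.g. terminal pair (17, 45) grows
    16, 15, ... and 46, 47, ...).  Original coordinates are untouched.
    """
    if n_bp < 0:
        raise ValueError("n_bp must be >= 0")
    out = copy.deepcopy(conformer)
    if n_bp == 0:
        return out
    if not seq_pattern:
        raise ValueError("seq_pattern must be non-empty")
    R, t, ri, rj = _terminal_bp_frame(conformer, *helix_end, params=params)
    # outward = the axis direction pointing away from the body of the molecule
    bp_center = 0.5 * (ri.atom("C1'").coord + rj.atom("C1'").coord)
    axis = R @ np.array([0.0, 0.0, 1.0])
    body = conformer.coords().mean(axis=0) - bp_center
    sign = -1 if np.dot(axis, body) > 0 else 1
    step_i = -1 if helix_end[0] < helix_end[1] else 1
    existing = {r.index for r in conformer.residues}
    new_residues = []
    for k in range(1, n_bp + 1):
        base1 = seq_pattern[(k - 1) % len(seq_pattern)].upper()
        base2 = wc_partner(base1)
        idx_i = helix_end[0] + step_i * k
        idx_j = helix_end[1] - step_i * k
        if idx_i in existing or idx_j in existing:
            raise ValueError(f"elongation residue number {idx_i or idx_j} collides "
                             f"with an existing residue")
        Rk, tk = _screw(sign * k, params)
        for base, strand, idx in ((base1, +1, idx_i), (base2, -1, idx_j)):
            tpl = _pair_frame_nucleotide(base, strand, params=params)
            tpl = {n_: R @ (Rk @ xyz + tk) + t for n_, xyz in tpl.items()}
            new_residues.append(_residue_from_template(tpl, base, idx, ri.chain))
    out.residues.extend(new_residues)
    out.residues.sort(key=lambda r: (r.chain, r.index))
    return Conformer(out.residues, model_id=out.model_id, energy=out.energy)


def filter_library(library: ConformerLibrary, energy_cutoff: float,
                   target_size: int, seed: int) -> ConformerLibrary:
    """Energy-filter a library and down-sample to ``target_size``.

    Keeps conformers with ``energy < energy_cutoff``; if more survive than
    ``target_size``, draws that many uniformly without replacement
    (library order preserved).  Deterministic for a given ``seed``.
    """
    if np.isfinite(energy_cutoff):
        missing = [c.model_id for c in library if c.energy is None]
        if missing:
            raise ValueError(
                f"finite energy cutoff but models {missing[:5]} carry no energy")
        survivors = [c for c in library if c.energy < energy_cutoff]
    else:
        survivors = list(library.conformers)
    if not survivors:
        raise ValueError("energy filter removed every conformer (0 survivors)")
    if len(survivors) > target_size:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(survivors), size=target_size, replace=False))
        survivors = [survivors[i] for i in keep]
    return ConformerLibrary([copy.deepcopy(c) for c in survivors],
                            sequence=library.sequence,
                            source=f"{library.source} [filtered]")
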