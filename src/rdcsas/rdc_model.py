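"""Residual dipolar coupling prediction, averaging, scaling, and tensor fits.

The observable is the residual dipolar coupling (RDC) of a bonded atom pair,

    D = D_max * sum_ij S_ij u_i u_j   [Hz],

where ``u`` is the unit bond vector in the molecular frame, ``S`` the
symmetric traceless Saupe order matrix describing partial alignment, and
``D_max`` the rigid-limit dipolar constant of the pair type.  Alignment by a
steric medium (e.g. Pf1 phage) is predicted from molecular shape with a
planar-obstruction model; alternatively an order tensor can be fit to
measured couplings by SVD.  Ensemble-averaged predictions are compared with
measurements after per-construct scaling, because each elongated construct
aligns with its own magnitude.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._geometry import fibonacci_sphere
from .structures import Conformer, ConformerLibrary

__all__ = [
    "RDCRecord",
    "RDCDataset",
    "AlignmentTensor",
    "BondConstants",
    "RDCMatrix",
    "steric_tensor",
    "predict_rdcs",
    "ensemble_average",
    "fit_scale_factors",
    "rdc_rmsd",
    "fit_svd_tensor",
    "precompute_matrix",
    "load_rdc_tsv",
    "write_rdc_tsv",
]

# physical constants (SI)
_MU0 = 4e-7 * np.pi        # T m / A
_HBAR = 1.054571817e-34    # J s
_GAMMA = {                 # gyromagnetic ratios, rad / (s T)
    "H": 26.7522128e7,
    "C": 6.728284e7,
    "N": -2.7116e7,
}


def _dmax_hz(elem_a: str, elem_b: str, r_angstrom: float) -> float:
    """Rigid-limit dipolar constant D_max in Hz for a bonded pair.

    Only ratios between pair types matter downstream (per-construct scale
    factors absorb the overall magnitude), but the absolute values are kept
    physical so predicted couplings land on the experimental scale.
    """
    r = r_angstrom * 1e-10
    d = -(_MU0 / (4.0 * np.pi)) * _GAMMA[elem_a] * _GAMMA[elem_b] * _HBAR / r**3
    return float(d / (2.0 * np.pi))


@dataclass(frozen=True)
class BondConstants:
    """Supported bonded pair types with effective bond lengths and D_max.

    Defaults cover the sugar C-H, base C-H, and imino N-H vectors used in
    RNA RDC work; C-H pairs use an effective 1.104 A bond, N-H 1.041 A.
    """
    bond_lengths: dict = field(default_factory=lambda: {
        ("C", "H"): 1.104,
        ("N", "H"): 1.041,
    })

    def supported(self, atom1: str, atom2: str) -> bool:
        try:
            self.dmax(atom1, atom2)
            return True
        except (KeyError, ValueError):
            return False

    def dmax(self, atom1: str, atom2: str) -> float:
        e1, e2 = atom1[0].upper(), atom2[0].upper()
        if (e1, e2) not in self.bond_lengths and (e2, e1) in self.bond_lengths:
            e1, e2 = e2, e1
        r = self.bond_lengths[(e1, e2)]
        val = _dmax_hz(e1, e2, r)
        if val == 0:
            raise ValueError(f"zero D_max for pair {atom1}-{atom2}")
        return val


@dataclass(frozen=True)
class RDCRecord:
    construct_id: str
    residue_index: int
    atom_pair: tuple[str, str]
    value: float
    error: float = 2.0

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("RDC value must be finite")


@dataclass
class RDCDataset:
    records: list[RDCRecord]

    def __post_init__(self):
        keys = [(r.construct_id, r.residue_index, r.atom_pair) for r in self.records]
        if len(set(keys)) != len(keys):
            dup = [k for k in keys if keys.count(k) > 1][0]
            raise ValueError(f"duplicate RDC record {dup}")

    @property
    def constructs(self) -> list[str]:
        seen = []
        for r in self.records:
            if r.construct_id not in seen:
                seen.append(r.construct_id)
        return seen

    def __len__(self) -> int:
        return len(self.records)

    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.records])

    def construct_codes(self) -> np.ndarray:
        """Integer construct label per record, in first-appearance order."""
        order = {c: k for k, c in enumerate(self.constructs)}
        return np.array([order[r.construct_id] for r in self.records])

    def subset(self, indices: np.ndarray | list[int]) -> "RDCDataset":
        return RDCDataset([self.records[i] for i in indices])

    def validate_supported(self, constants: BondConstants) -> None:
        for r in self.records:
            if not constants.supported(*r.atom_pair):
                raise ValueError(
                    f"unsupported atom pair {r.atom_pair} at construct "
                    f"{r.construct_id} residue {r.residue_index}")


@dataclass
class AlignmentTensor:
    saupe: np.ndarray
    frame: str = "molecular"

    def __post_init__(self):
        S = np.asarray(self.saupe, dtype=float)
        if S.shape != (3, 3):
            raise ValueError("Saupe matrix must be 3x3")
        if not np.allclose(S, S.T, atol=1e-9):
            raise ValueError("Saupe matrix must be symmetric")
        S = 0.5 * (S + S.T)
        S -= np.eye(3) * (np.trace(S) / 3.0)
        self.saupe = S

    @property
    def eigenvalues(self) -> np.ndarray:
        """Principal order parameters sorted |Szz| >= |Syy| >= |Sxx|."""
        w = np.linalg.eigvalsh(self.saupe)
        return w[np.argsort(np.abs(w))[::-1]]

    @property
    def asymmetry(self) -> float:
        """eta = (Syy - Sxx) / Szz, 0 for an axially symmetric tensor."""
        szz, syy, sxx = self.eigenvalues
        return float(abs((syy - sxx) / szz))

    @property
    def principal_axes(self) -> np.ndarray:
        """Columns are principal axes ordered like :attr:`eigenvalues`."""
        w, v = np.linalg.eigh(self.saupe)
        order = np.argsort(np.abs(w))[::-1]
        return v[:, order]

    def rotated(self, R: np.ndarray) -> "AlignmentTensor":
        return AlignmentTensor(R @ self.saupe @ R.T, frame=self.frame)


@dataclass
class RDCMatrix:
    """Per-conformer predicted couplings: one row per conformer, one column
    per dataset record."""
    values: np.ndarray
    dataset: RDCDataset
    conformer_ids: list[int]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.conformer_ids), len(self.dataset)):
            raise ValueError("matrix shape inconsistent with library/dataset")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite predictions")

    @property
    def n_conformers(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# steric alignment prediction
# ---------------------------------------------------------------------------

def _barrier_spacing(concentration: float) -> float:
    """Inter-barrier spacing (A) for a planar-obstruction medium.

    Modeled as d = t / phi for barriers of effective thickness t at volume
    fraction phi ~ concentration (g/mL) / rod density (~1 g/mL); t = 60 A
    (the Pf1 virion diameter) gives d ~ 2700 A at the 0.022 g/mL used for
    phage alignment.  Only the ratio extent/d matters and per-construct
    scaling absorbs the prefactor.
    """
    if concentration <= 0:
        raise ValueError("medium concentration must be positive")
    return 60.0 / concentration / 1000.0 * 1000.0  # t=60 A, density 1 g/mL


def steric_tensor(conformer: Conformer, medium: str = "rod",
                  concentration: float = 0.022,
                  orient_grid: int = 10000) -> AlignmentTensor:
    """Predict the Saupe matrix of a conformer from molecular shape.

    Planar-obstruction approximation: for each direction ``n`` of the
    obstruction normal on a deterministic near-uniform grid, the accessible
    fraction is ``f(n) = max(0, 1 - extent(n)/d)`` with ``extent(n)`` the
    molecule's span along ``n`` and ``d`` the barrier spacing set by the
    medium concentration.  The order matrix is the f-weighted average
    ``<f (3 n n^T - I)/2> / <f>``.  ``medium`` ("rod" or "wall") controls
    the sign convention: in a rod medium the unique axis of an elongated
    molecule aligns along the field, in a wall medium orthogonal to it.
    """
    if medium not in ("rod", "wall"):
        raise ValueError("medium must be 'rod' or 'wall'")
    xyz = conformer.coords(heavy_only=True)
    if len(xyz) < 4:
        raise ValueError("need at least 4 heavy atoms for shape alignment")
    # collinearity check
    c = xyz - xyz.mean(axis=0)
    sv = np.linalg.svd(c, compute_uv=False)
    if sv[1] < 1e-6 * sv[0]:
        raise ValueError("degenerate (collinear) coordinates")
    d = _barrier_spacing(concentration)
    grid = fibonacci_sphere(orient_grid)
    proj = c @ grid.T                       # atoms x directions
    extent = proj.max(axis=0) - proj.min(axis=0)
    f = np.maximum(0.0, 1.0 - extent / d)
    if f.sum() <= 0:
        raise ValueError("molecule larger than barrier spacing in all directions")
    outer = grid[:, :, None] * grid[:, None, :]
    Q = 1.5 * outer - 0.5 * np.eye(3)
    S = np.tensordot(f, Q, axes=1) / f.sum()
    if medium == "rod":
        # the obstruction normal is orthogonal to the aligned field direction:
        # the field-frame order matrix is -1/2 the normal-frame one
        S = -0.5 * S
    return AlignmentTensor(0.5 * (S + S.T))


# ---------------------------------------------------------------------------
# prediction and scoring
# ---------------------------------------------------------------------------

def _bond_vectors(conformer: Conformer, dataset: RDCDataset) -> np.ndarray:
    vecs = np.empty((len(dataset), 3))
    problems = []
    for k, rec in enumerate(dataset.records):
        try:
            res = conformer.residue(rec.residue_index)
            a = res.atom(rec.atom_pair[0]).coord
            b = res.atom(rec.atom_pair[1]).coord
        except KeyError:
            problems.append((rec.construct_id, rec.residue_index, rec.atom_pair))
            continue
        v = b - a
        vecs[k] = v / np.linalg.norm(v)
    if problems:
        raise KeyError(f"missing atoms for records: {problems[:5]}"
                       + ("..." if len(problems) > 5 else ""))
    return vecs


def predict_rdcs(conformer: Conformer, tensor: AlignmentTensor,
                 dataset: RDCDataset,
                 constants: BondConstants | None = None) -> np.ndarray:
    """Predicted coupling (Hz) per dataset record for one conformer."""
    constants = constants or BondConstants()
    dataset.validate_supported(constants)
    u = _bond_vectors(conformer, dataset)
    dmax = np.array([constants.dmax(*r.atom_pair) for r in dataset.records])
    return dmax * np.einsum("ki,ij,kj->k", u, tensor.saupe, u)


def ensemble_average(matrix: RDCMatrix, member_indices: list[int]) -> np.ndarray:
    """Equal-weight mean prediction over ensemble members (duplicates count)."""
    if len(member_indices) == 0:
        raise ValueError("ensemble member list is empty")
    idx = np.asarray(member_indices)
    if idx.min() < 0 or idx.max() >= matrix.n_conformers:
        raise IndexError("member index outside library")
    return matrix.values[idx].mean(axis=0)


def fit_scale_factors(calc: np.ndarray, dataset: RDCDataset) -> dict[str, float]:
    """Per-construct least-squares scale L_j minimizing sum (L*calc - exp)^2.

    Closed form L_j = sum(exp*calc) / sum(calc^2) over construct j's records.
    """
    calc = np.asarray(calc, dtype=float)
    exp = dataset.values()
    codes = dataset.construct_codes()
    scales = {}
    for j, cid in enumerate(dataset.constructs):
        m = codes == j
        denom = float(np.sum(calc[m] ** 2))
        if denom <= 0:
            raise ZeroDivisionError(
                f"all-zero predictions for construct {cid}: scale undefined")
        scales[cid] = float(np.sum(exp[m] * calc[m]) / denom)
    return scales


def rdc_rmsd(calc: np.ndarray, dataset: RDCDataset,
             scales: dict[str, float] | None = None,
             subset: np.ndarray | list[int] | None = None) -> float:
    """Root-mean-square deviation (Hz) between scaled predictions and data."""
    calc = np.asarray(calc, dtype=float)
    exp = dataset.values()
    if scales is None:
        L = np.ones(len(dataset))
    else:
        missing = [c for c in dataset.constructs if c not in scales]
        if missing:
            raise KeyError(f"no scale factor for constructs {missing}")
        L = np.array([scales[r.construct_id] for r in dataset.records])
    resid = L * calc - exp
    if subset is not None:
        idx = np.asarray(subset, dtype=int)
        if idx.size == 0:
            raise ValueError("empty record subset")
        resid = resid[idx]
    if resid.size == 0:
        raise ValueError("empty record subset")
    return float(np.sqrt(np.mean(resid ** 2)))


def fit_svd_tensor(dataset: RDCDataset, conformer: Conformer,
                   constants: BondConstants | None = None
                   ) -> tuple[AlignmentTensor, float, float]:
    """Least-squares Saupe tensor from measured couplings (order tensor fit).

    Solves D/D_max = A s for the five independent Saupe elements
    s = (Sxx, Syy, Sxy, Sxz, Syz) via SVD of the direction-cosine design
    matrix.  Returns (tensor, back-calculated RMSD in Hz, condition number).
    """
    constants = constants or BondConstants()
    if len(dataset) < 5:
        raise ValueError(f"need >= 5 couplings to fit an order tensor, "
                         f"got {len(dataset)}")
    u = _bond_vectors(conformer, dataset)
    dmax = np.array([constants.dmax(*r.atom_pair) for r in dataset.records])
    x, y, z = u.T
    A = np.column_stack([x*x - z*z, y*y - z*z, 2*x*y, 2*x*z, 2*y*z])
    b = dataset.values() / dmax
    U, sv, Vt = np.linalg.svd(A, full_matrices=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise ValueError("bond-vector orientations are degenerate: "
                         "order tensor underdetermined (rank < 5)")
    cond = float(sv[0] / sv[-1])
    s = Vt.T @ ((U.T @ b) / sv)
    sxx, syy, sxy, sxz, syz = s
    S = np.array([[sxx, sxy, sxz],
                  [sxy, syy, syz],
                  [sxz, syz, -sxx - syy]])
    tensor = AlignmentTensor(S)
    rmsd = float(np.sqrt(np.mean((dmax * (A @ s) - dataset.values()) ** 2)))
    return tensor, rmsd, cond


# ---------------------------------------------------------------------------
# per-library prediction matrix
# ---------------------------------------------------------------------------

def _content_hash(library: ConformerLibrary, dataset: RDCDataset,
                  mode: str) -> str:
    h = hashlib.sha256()
    h.update(mode.encode())
    for r in dataset.records:
        h.update(f"{r.construct_id}|{r.residue_index}|{r.atom_pair}".encode())
    for c in library:
        h.update(np.round(c.coords(), 4).tobytes())
    return h.hexdigest()[:16]


def precompute_matrix(library: ConformerLibrary, dataset: RDCDataset,
                      mode: str = "steric",
                      tensors: dict[str, AlignmentTensor] | None = None,
                      elongation: dict | None = None,
                      constants: BondConstants | None = None,
                      medium: str = "rod", concentration: float = 0.022,
                      orient_grid: int = 2000,
                      cache_dir: str | Path | None = None) -> RDCMatrix:
    """Predict every record for every conformer in the library.

    ``mode='steric'`` recomputes a shape-based tensor per conformer and per
    construct (after optional in-silico elongation given as
    ``{construct_id: (helix_end, n_bp, seq_pattern)}``); ``mode='fixed-tensor'``
    uses one supplied lab-frame tensor per construct, which is the fast path
    when conformers share a common reference frame.  Results are cached as
    TSV keyed by a content hash of library + dataset.
    """
    from .structures import elongate_in_silico  # local import to avoid cycle

    constants = constants or BondConstants()
    dataset.validate_supported(constants)
    if mode not in ("steric", "fixed-tensor"):
        raise ValueError("mode must be 'steric' or 'fixed-tensor'")
    if mode == "fixed-tensor":
        if tensors is None:
            raise ValueError("fixed-tensor mode requires per-construct tensors")
        missing = [c for c in dataset.constructs if c not in tensors]
        if missing:
            raise ValueError(f"no tensor supplied for constructs {missing}")

    cache_file = None
    if cache_dir is not None:
        tag = _content_hash(library, dataset, mode)
        cache_file = Path(cache_dir) / f"rdcmatrix_{tag}.tsv"
        if cache_file.exists():
            vals = np.loadtxt(cache_file, delimiter="\t", ndmin=2)
            return RDCMatrix(vals, dataset,
                             [c.model_id for c in library])

    codes = dataset.construct_codes()
    values = np.empty((len(library), len(dataset)))
    for i, conf in enumerate(library):
        for j, cid in enumerate(dataset.constructs):
            cols = np.flatnonzero(codes == j)
            sub = dataset.subset(cols)
            if mode == "fixed-tensor":
                tensor = tensors[cid]
                work = conf
            else:
                work = conf
                if elongation and cid in elongation:
                    helix_end, n_bp, pattern = elongation[cid]
                    work = elongate_in_silico(conf, helix_end, n_bp, pattern)
                tensor = steric_tensor(work, medium=medium,
                                       concentration=concentration,
                                       orient_grid=orient_grid)
            try:
                values[i, cols] = predict_rdcs(work, tensor, sub, constants)
            except KeyError as exc:
                raise KeyError(f"conformer {conf.model_id}: {exc}") from exc
    out = RDCMatrix(values, dataset, [c.model_id for c in library])
    if cache_file is not None:
        cache_file.parent.mkdir(parents=True, exist_ok=True)
        np.savetxt(cache_file, out.values, delimiter="\t", fmt="%.17g")
    return out


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["construct", "residue", "atom1", "atom2", "rdc_hz", "error_hz"]


def load_rdc_tsv(path: str | Path | io.TextIOBase,
                 constants: BondConstants | None = None) -> RDCDataset:
    """Read the canonical tab-separated RDC table.

    Columns: ``construct  residue  atom1  atom2  rdc_hz  error_hz`` (the
    error column is optional, default 2.0 Hz).  Unsupported atom-pair types
    raise a named error rather than being skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"RDC table lacks columns {missing}")
    if "error_hz" not in df.columns:
        df["error_hz"] = 2.0
    records = [
        RDCRecord(str(row.construct), int(row.residue),
                  (str(row.atom1), str(row.atom2)),
                  float(row.rdc_hz), float(row.error_hz))
        for row in df.itertuples()
    ]
    ds = RDCDataset(records)
    ds.validate_supported(constants or BondConstants())
    return ds


def write_rdc_tsv(dataset: RDCDataset, path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.construct_id, r.residue_index, *r.atom_pair, r.value, r.error)
         for r in dataset.records], columns=_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
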