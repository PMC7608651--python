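"""Synthetic two-helix bulge conformers and RDC datasets.

Emulates the statistical structure of a bulge-junction RNA ensemble problem
without any external data: two idealized A-form helices joined by a 1-7 nt
bulge, a bimodal inter-helical bend-angle distribution (a narrow
coaxially-stacked mode plus a broad kinked mode), heterogeneous bulge sugar
puckers, extra-helical flips optionally coupled to the stacked state, and
multi-construct RDC sets with per-construct alignment tensors, scale
factors, and ~2 Hz Gaussian noise (the experimental uncertainty the method
is designed around).

Geometry is analytic rigid-template placement with a clash check — adequate
because the downstream mathematics needs plausible, not physical,
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _templates
from ._geometry import rotation_y, rotation_z
from .rdc_model import (AlignmentTensor, BondConstants, RDCDataset, RDCMatrix,
                        RDCRecord, precompute_matrix, predict_rdcs)
from .structures import (AFORM, Conformer, ConformerLibrary,
                         _pair_frame_nucleotide, _residue_from_template,
                         _screw)

__all__ = [
    "JunctionModel",
    "SimulatedTruth",
    "RecoveryReport",
    "generate_library",
    "simulate_rdc_dataset",
    "recovery_experiment",
    "random_tensor",
    "default_record_schema",
]


@dataclass
class JunctionModel:
    """Statistical model of a two-helix junction ensemble.

    ``bend_modes`` is a mixture of (mean |beta_h| deg, sd deg, weight);
    the default pairs a narrow near-coaxial mode with a broad kinked one,
    the bimodal character expected for bulge junctions.  ``pucker_prob``
    and ``flip_prob`` are per-bulge-residue probabilities of the C2'-endo
    sugar and of the extra-helical (flipped-out) state; ``flip_coupling``
    in [0, 1] ties flipping to the stacked mode (in the first bend mode the
    flip-out probability is boosted toward 1, in the others suppressed),
    which is how coaxial stacking and cooperative flipping co-occur.
    """
    bulge_length: int = 3
    bend_modes: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(20.0, 8.0, 0.5), (75.0, 12.0, 0.5)])
    twist_sd: float = 20.0
    pucker_prob: float = 0.5
    flip_prob: float = 0.5
    flip_coupling: float = 0.0
    lower_strand1: str = "GCAG"
    upper_strand1: str = "GAGC"
    bulge_pattern: str = "UCU"
    random_orientation: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.bulge_length <= 7):
            raise ValueError("bulge_length must be in 1..7")
        w = sum(m[2] for m in self.bend_modes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"bend-mode weights must sum to 1 (got {w})")
        for p in (self.pucker_prob, self.flip_prob, self.flip_coupling):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")

    # --- derived layout -------------------------------------------------
    @property
    def n_lower(self) -> int:
        return len(self.lower_strand1)

    @property
    def n_upper(self) -> int:
        return len(self.upper_strand1)

    @property
    def bulge_seq(self) -> str:
        reps = -(-self.bulge_length // len(self.bulge_pattern))
        return (self.bulge_pattern * reps)[: self.bulge_length]

    def numbering(self) -> dict[str, tuple[int, ...]]:
        """Residue numbers along the chain 5'->3': lower strand I, bulge,
        upper strand I, upper strand II, lower strand II."""
        n1, nb, n2 = self.n_lower, self.bulge_length, self.n_upper
        pos = 1
        lower1 = tuple(range(pos, pos + n1)); pos += n1
        bulge = tuple(range(pos, pos + nb)); pos += nb
        upper1 = tuple(range(pos, pos + n2)); pos += n2
        upper2 = tuple(range(pos, pos + n2)); pos += n2
        lower2 = tuple(range(pos, pos + n1)); pos += n1
        return {"lower1": lower1, "bulge": bulge, "upper1": upper1,
                "upper2": upper2, "lower2": lower2}

    def euler_ranges(self):
        """(upper_bp_range, lower_bp_range) for inter-helical Euler angles:
        up to 3 bp of each helix nearest the junction."""
        num = self.numbering()
        k = min(3, self.n_upper, self.n_lower)
        up1 = num["upper1"][:k]
        up2 = num["upper2"][-k:][::-1][:k]
        lo1 = num["lower1"][-k:]
        lo2 = num["lower2"][:k][::-1]
        return ((up1, tuple(sorted(up2))), (lo1, tuple(sorted(lo2))))

    def flanking_bp_residues(self) -> tuple[int, ...]:
        """Residues of the two junction-closing base pairs."""
        num = self.numbering()
        return (num["lower1"][-1], num["lower2"][0],
                num["upper1"][0], num["upper2"][-1])

    def bridging_pairs(self):
        """Cross-junction bp combinations whose stacking defines coaxiality."""
        num = self.numbering()
        lower_bp = (num["lower1"][-1], num["lower2"][0])
        upper_bp = (num["upper1"][0], num["upper2"][-1])
        return [(lower_bp, upper_bp)]


@dataclass
class SimulatedTruth:
    true_member_indices: list[int]
    true_tensors: dict[str, AlignmentTensor]
    true_scales: dict[str, float]
    noise_sd: float = 2.0


@dataclass
class RecoveryReport:
    success_rate: float
    rmsd_hz: list[float]
    true_rmsd_hz: list[float]
    jaccard: list[float]
    repeats: int


_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp(seq: str) -> str:
    return "".join(_WC[b] for b in reversed(seq.upper()))


def _helix_residues(strand1: str, numbers1, numbers2, base_level: int,
                    transform=None) -> list:
    """Residues of an idealized duplex with bp k at screw level
    base_level + k, optionally post-transformed by (R, t)."""
    from .structures import Residue  # noqa: F401  (type only)
    strand2 = _revcomp(strand1)
    n = len(strand1)
    out = []
    for k in range(n):
        Rk, tk = _screw(base_level + k)
        placements = [
            (strand1[k], +1, numbers1[k]),
            (strand2[n - 1 - k], -1, numbers2[n - 1 - k]),
        ]
        for base, strand, idx in placements:
            tpl = _pair_frame_nucleotide(base, strand)
            tpl = {nm: Rk @ xyz + tk for nm, xyz in tpl.items()}
            if transform is not None:
                R, t = transform
                tpl = {nm: R @ xyz + t for nm, xyz in tpl.items()}
            out.append(_residue_from_template(tpl, base, idx, "A"))
    return out


def _min_interresidue_distance(res, others) -> float:
    a = np.array([at.coord for at in res.atoms])
    best = np.inf
    for o in others:
        b = np.array([at.coord for at in o.atoms])
        d = np.linalg.norm(a[:, None] - b[None], axis=-1).min()
        best = min(best, d)
    return best


def _build_conformer(model: JunctionModel, beta: float, twist_dev: float,
                     puckers: list[float], flips: list[bool],
                     rng: np.random.Generator, model_id: int,
                     clash_tol: float = 1.2, max_retries: int = 10) -> Conformer:
    num = model.numbering()
    n1 = model.n_lower
    rise = AFORM["rise"]
    twist = AFORM["twist_deg"]

    residues = _helix_residues(model.lower_strand1, num["lower1"],
                               num["lower2"], 0)

    n_in = sum(not f for f in flips)
    top_level = n1 + n_in
    # coaxial-register continuation, then the junction rotation
    Rj = (rotation_z(top_level * twist)
          @ rotation_z(-twist_dev / 2.0) @ rotation_y(beta)
          @ rotation_z(-twist_dev / 2.0))
    tj = np.array([0.0, 0.0, top_level * rise])
    residues += _helix_residues(model.upper_strand1, num["upper1"],
                                num["upper2"], 0, transform=(Rj, tj))

    # bulge nucleotides: flipped-in residues take intermediate helical
    # levels; flipped-out residues swing laterally away from the axis
    helix_res = list(residues)
    level = n1
    bulge_seq = model.bulge_seq
    for j, idx in enumerate(num["bulge"]):
        base = bulge_seq[j]
        tpl0 = _pair_frame_nucleotide(base, +1, pucker_p=puckers[j])
        if not flips[j]:
            Rk, tk = _screw(level)
            level += 1
            tpl = {nm: Rk @ xyz + tk for nm, xyz in tpl0.items()}
            residues.append(_residue_from_template(tpl, base, idx, "A"))
            continue
        placed = None
        centroid = np.mean([xyz for xyz in tpl0.values()], axis=0)
        z_out = (n1 - 0.5) * rise + (j - (len(num["bulge"]) - 1) / 2.0) * 3.5
        for attempt in range(max_retries):
            psi = rng.uniform(0.0, 360.0)
            Rpsi = rotation_z(psi)
            anchor = Rpsi @ np.array([13.0, 0.0, 0.0]) + np.array([0.0, 0.0, z_out])
            tpl = {nm: Rpsi @ (xyz - centroid) + anchor for nm, xyz in tpl0.items()}
            cand = _residue_from_template(tpl, base, idx, "A")
            if _min_interresidue_distance(cand, helix_res) > clash_tol:
                placed = cand
                break
        if placed is None:
            raise RuntimeError(
                f"could not place flipped-out bulge residue {idx} without "
                f"clashes after {max_retries} attempts")
        residues.append(placed)
        helix_res.append(placed)

    residues.sort(key=lambda r: r.index)
    return Conformer(residues, model_id=model_id)


def generate_library(model: JunctionModel, size: int) -> ConformerLibrary:
    """Sample a conformer library from the junction model (seeded)."""
    if size < 1:
        raise ValueError("library size must be >= 1")
    rng = np.random.default_rng(model.seed)
    means = np.array([m[0] for m in model.bend_modes])
    sds = np.array([m[1] for m in model.bend_modes])
    weights = np.array([m[2] for m in model.bend_modes])
    conformers = []
    for i in range(size):
        mode = rng.choice(len(weights), p=weights)
        beta = float(np.clip(abs(rng.normal(means[mode], sds[mode])), 0.0, 178.0))
        twist_dev = float(rng.normal(0.0, model.twist_sd))
        puckers = [162.0 if rng.random() < model.pucker_prob else 18.0
                   for _ in range(model.bulge_length)]
        if model.flip_coupling > 0.0:
            if mode == 0:
                p_flip = model.flip_prob + model.flip_coupling * (1.0 - model.flip_prob)
            else:
                p_flip = model.flip_prob * (1.0 - model.flip_coupling)
        else:
            p_flip = model.flip_prob
        flips = [bool(rng.random() < p_flip) for _ in range(model.bulge_length)]
        conf = _build_conformer(model, beta, twist_dev, puckers,
                                flips, rng, model_id=i + 1)
        if model.random_orientation:
            # each conformer carries its own overall orientation, as in a
            # real library where every structure defines its own alignment
            # frame; this also makes every record informative for selection
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            R = np.array([
                [1 - 2*(y*y + z*z), 2*(x*y - w*z), 2*(x*z + w*y)],
                [2*(x*y + w*z), 1 - 2*(x*x + z*z), 2*(y*z - w*x)],
                [2*(x*z - w*y), 2*(y*z + w*x), 1 - 2*(x*x + y*y)],
            ])
            conf = conf.transformed(R, np.zeros(3))
        conformers.append(conf)
    return ConformerLibrary(conformers, source=f"synthetic junction seed={model.seed}")


def random_tensor(rng: np.random.Generator, magnitude: float = 6e-4
                  ) -> AlignmentTensor:
    """Random symmetric traceless Saupe tensor with entries ~ magnitude,
    the order of alignment induced by dilute liquid-crystal media."""
    A = rng.normal(0.0, magnitude, size=(3, 3))
    S = 0.5 * (A + A.T)
    S -= np.eye(3) * (np.trace(S) / 3.0)
    return AlignmentTensor(S)


def default_record_schema(model: JunctionModel) -> list[tuple[int, tuple[str, str]]]:
    """(residue, atom pair) candidates: sugar C1'-H1'/C2'-H2' and a base
    C-H per residue, mirroring the multiple-RDCs-per-nucleotide datasets."""
    num = model.numbering()
    order = (num["lower1"] + num["bulge"] + num["upper1"]
             + num["upper2"] + num["lower2"])
    seq = {}
    for group, key in ((num["lower1"], "lower1"), (num["bulge"], "bulge"),
                       (num["upper1"], "upper1"), (num["upper2"], "upper2"),
                       (num["lower2"], "lower2")):
        for j, idx in enumerate(group):
            if key == "bulge":
                seq[idx] = model.bulge_seq[j]
            elif key == "lower1":
                seq[idx] = model.lower_strand1[j]
            elif key == "upper1":
                seq[idx] = model.upper_strand1[j]
            elif key == "upper2":
                seq[idx] = _revcomp(model.upper_strand1)[j]
            else:
                seq[idx] = _revcomp(model.lower_strand1)[j]
    out = []
    for idx in order:
        base = seq[idx]
        out.append((idx, ("C1'", "H1'")))
        out.append((idx, ("C2'", "H2'")))
        if base in _templates.PURINES:
            out.append((idx, ("C8", "H8")))
        else:
            out.append((idx, ("C6", "H6")))
    return out


def simulate_rdc_dataset(library: ConformerLibrary, truth: SimulatedTruth,
                         constructs: int | list[str] = 3,
                         records_per_construct: int = 40,
                         model: JunctionModel | None = None,
                         schema: list[tuple[int, tuple[str, str]]] | None = None,
                         seed: int = 0,
                         constants: BondConstants | None = None) -> RDCDataset:
    """Noisy multi-construct RDC measurements from a known sub-ensemble.

    For each construct the equal-weight average prediction of the true
    members under that construct's tensor is scaled by the true scale and
    perturbed with Gaussian noise of sd ``truth.noise_sd``.
    """
    constants = constants or BondConstants()
    if isinstance(constructs, int):
        construct_ids = [f"construct{k+1}" for k in range(constructs)]
    else:
        construct_ids = list(constructs)
    if set(construct_ids) - set(truth.true_tensors):
        raise ValueError("truth lacks tensors for some constructs")
    if schema is None:
        if model is None:
            raise ValueError("need a JunctionModel or an explicit record schema")
        schema = default_record_schema(model)
    schema = schema[:records_per_construct]
    if len(schema) < records_per_construct:
        raise ValueError(f"schema provides only {len(schema)} of "
                         f"{records_per_construct} requested records")
    rng = np.random.default_rng(seed)
    members = [library[i] for i in truth.true_member_indices]
    records = []
    for cid in construct_ids:
        probe = RDCDataset([RDCRecord(cid, idx, pair, 0.0) for idx, pair in schema])
        preds = np.mean([predict_rdcs(c, truth.true_tensors[cid], probe, constants)
                         for c in members], axis=0)
        noisy = (truth.true_scales.get(cid, 1.0) * preds
                 + rng.normal(0.0, truth.noise_sd, size=len(schema)))
        for (idx, pair), val in zip(schema, noisy):
            records.append(RDCRecord(cid, idx, pair, float(val),
                                     error=max(truth.noise_sd, 1e-6)))
    return RDCDataset(records)


def recovery_experiment(model: JunctionModel, library_size: int, true_n: int,
                        sas_config=None, repeats: int = 10,
                        noise_sd: float = 0.0, constructs: int = 3,
                        records_per_construct: int = 40,
                        seed: int = 0) -> RecoveryReport:
    """End-to-end generate -> simulate -> select -> compare harness.

    Success means the selected ensemble's cost is no worse than the
    exhaustively evaluated cost of the generating member set (degenerate
    alternative solutions count as success; with noise the generating set
    is not necessarily the minimizer, so the Jaccard overlap is reported
    without a hard threshold).
    """
    from .selection import SASConfig, derive_seed, ensemble_cost, sas_select

    if true_n > library_size:
        raise ValueError("true_n cannot exceed library_size")
    sas_config = sas_config or SASConfig(ensemble_size=true_n)
    successes, rmsds, true_rmsds, jac = 0, [], [], []
    for rep in range(repeats):
        rep_seed = derive_seed(seed, rep)
        lib_model = JunctionModel(**{**model.__dict__, "seed": derive_seed(rep_seed, 1)})
        library = generate_library(lib_model, library_size)
        rng = np.random.default_rng(derive_seed(rep_seed, 2))
        true_members = sorted(rng.choice(library_size, size=true_n,
                                         replace=False).tolist())
        cids = [f"construct{k+1}" for k in range(constructs)]
        truth = SimulatedTruth(
            true_member_indices=true_members,
            true_tensors={c: random_tensor(rng) for c in cids},
            true_scales={c: float(rng.uniform(0.7, 1.3)) for c in cids},
            noise_sd=noise_sd)
        dataset = simulate_rdc_dataset(library, truth, cids,
                                       records_per_construct, model=lib_model,
                                       seed=derive_seed(rep_seed, 3))
        matrix = precompute_matrix(library, dataset, mode="fixed-tensor",
                                   tensors=truth.true_tensors)
        from dataclasses import replace
        cfg = replace(sas_config, ensemble_size=true_n,
                      seed=derive_seed(rep_seed, 4))
        res = sas_select(matrix, dataset, cfg)
        true_chi2, true_rmsd, _ = ensemble_cost(matrix, dataset, true_members)
        successes += res.chi2 <= true_chi2 + 1e-9 * max(1.0, true_chi2)
        rmsds.append(res.rmsd_hz)
        true_rmsds.append(true_rmsd)
        sel = set(res.member_indices)
        tru = set(true_members)
        jac.append(len(sel & tru) / len(sel | tru))
    return RecoveryReport(success_rate=successes / repeats, rmsd_hz=rmsds,
                          true_rmsd_hz=true_rmsds, jaccard=jac, repeats=repeats)
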