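"""Structural analytics for conformers and ensembles.

Covers backbone/sugar torsions and pseudorotation, sugar-pucker calls and
the C1' chemical-shift mapping of C2'-endo populations, inter-helical
Euler angles and bend categories, base stacking / extra-helical flips,
flip-out cooperativity, and superposition-based ensemble distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _templates
from ._geometry import dihedral, euler_zyz, kabsch, superposed_rmsd
from .structures import Conformer, HelixSpec, build_aform_helix, is_complementary

__all__ = [
    "TorsionSet",
    "PuckerCall",
    "ShiftPuckerMap",
    "InterhelicalOrientation",
    "FlipStackReport",
    "CooperativityResult",
    "StackingCriterion",
    "compute_torsions",
    "classify_pucker",
    "pucker_population",
    "shift_to_c2endo",
    "interhelical_euler",
    "bend_category",
    "detect_stacking",
    "detect_coaxial",
    "detect_extra_helical",
    "flip_stack_report",
    "cooperativity",
    "superpose_rmsd",
    "ensemble_distance",
]

GAS_CONSTANT_KCAL = 1.987204259e-3  # kcal / (mol K)

_BACKBONE_DEFS = {
    # name: (atoms, residue offsets) — offset -1 means previous residue
    "alpha": ((("O3'", -1), ("P", 0), ("O5'", 0), ("C5'", 0))),
    "beta": ((("P", 0), ("O5'", 0), ("C5'", 0), ("C4'", 0))),
    "gamma": ((("O5'", 0), ("C5'", 0), ("C4'", 0), ("C3'", 0))),
    "delta": ((("C5'", 0), ("C4'", 0), ("C3'", 0), ("O3'", 0))),
    "epsilon": ((("C4'", 0), ("C3'", 0), ("O3'", 0), ("P", 1))),
    "zeta": ((("C3'", 0), ("O3'", 0), ("P", 1), ("O5'", 1))),
}

_NU_DEFS = [
    ("nu0", ("C4'", "O4'", "C1'", "C2'")),
    ("nu1", ("O4'", "C1'", "C2'", "C3'")),
    ("nu2", ("C1'", "C2'", "C3'", "C4'")),
    ("nu3", ("C2'", "C3'", "C4'", "O4'")),
    ("nu4", ("C3'", "C4'", "O4'", "C1'")),
]


@dataclass
class TorsionSet:
    """Per-residue torsions in degrees; missing values are NaN."""
    angles: dict[int, dict[str, float]]
    incomplete: dict[int, list[str]] = field(default_factory=dict)

    def residue(self, index: int) -> dict[str, float]:
        return self.angles[index]


@dataclass(frozen=True)
class PuckerCall:
    state: str            # "C2'-endo" | "C3'-endo" | "ambiguous"
    P: float
    amplitude: float
    reason: str = ""


@dataclass(frozen=True)
class ShiftPuckerMap:
    """Linear C1' chemical-shift mapping of the sugar-pucker equilibrium.

    86 ppm anchors 100% C2'-endo, 94 ppm anchors 100% C3'-endo.
    """
    shift_c2endo: float = 86.0
    shift_c3endo: float = 94.0
    clamp: bool = True

    def __post_init__(self):
        if self.shift_c2endo == self.shift_c3endo:
            raise ValueError("shift anchors must be distinct")


@dataclass(frozen=True)
class InterhelicalOrientation:
    alpha_h: float
    beta_h: float
    gamma_h: float
    frame_rmsd_upper: float = 0.0
    frame_rmsd_lower: float = 0.0
    unreliable: bool = False

    @property
    def bend_magnitude(self) -> float:
        return abs(self.beta_h)

    @property
    def twist(self) -> float:
        return self.alpha_h + self.gamma_h

    @property
    def rotation(self) -> np.ndarray:
        """Relative rotation rebuilt from the angles (sign-inverted ZYZ)."""
        from ._geometry import compose_zyz
        return compose_zyz(-self.alpha_h, self.beta_h, -self.gamma_h)


@dataclass(frozen=True)
class StackingCriterion:
    """Geometric base-stacking rule: ring-centroid distance, inter-normal
    angle, and the centroid offset component perpendicular to the mean
    normal ("lateral slide")."""
    max_centroid_distance: float = 4.5
    max_normal_angle: float = 30.0
    max_lateral_offset: float = 2.5


@dataclass
class FlipStackReport:
    extra_helical: dict[int, bool | None]
    stacked_pairs: dict[tuple[int, int], bool | None]
    coaxial: bool | None


@dataclass
class CooperativityResult:
    p_out: dict[int, float]
    p_independent: float
    p_observed: float
    delta_g: float
    temperature: float = 298.0

    @property
    def magnitude(self) -> float:
        return abs(self.delta_g)


# ---------------------------------------------------------------------------
# torsions & pucker
# ---------------------------------------------------------------------------

def compute_torsions(conformer: Conformer) -> TorsionSet:
    """Backbone (alpha..zeta), glycosidic chi, ring torsions, and the
    Altona-Sundaralingam pseudorotation phase P / amplitude nu_max.

    Residues with missing atoms get NaN for the affected angles and are
    listed in ``incomplete``; nothing raises.
    """
    residues = conformer.residues
    angles: dict[int, dict[str, float]] = {}
    incomplete: dict[int, list[str]] = {}
    for i, res in enumerate(residues):
        prev_res = residues[i - 1] if i > 0 and residues[i - 1].chain == res.chain else None
        next_res = residues[i + 1] if i + 1 < len(residues) and residues[i + 1].chain == res.chain else None
        out: dict[str, float] = {}
        missing: list[str] = []

        def grab(atom: str, offset: int):
            target = {0: res, -1: prev_res, 1: next_res}[offset]
            if target is None or not target.has_atom(atom):
                return None
            return target.atom(atom).coord

        for name, spec in _BACKBONE_DEFS.items():
            pts = [grab(a, off) for a, off in spec]
            if any(p is None for p in pts):
                out[name] = math.nan
                missing.append(name)
            else:
                out[name] = dihedral(*pts)

        # glycosidic
        try:
            glyc = _templates.glycosidic_atom(res.base)
            ref = "C4" if res.base in _templates.PURINES else "C2"
            pts = [res.atom(a).coord for a in ("O4'", "C1'", glyc, ref)]
            out["chi"] = dihedral(*pts)
        except KeyError:
            out["chi"] = math.nan
            missing.append("chi")

        nus = {}
        ok = True
        for nu_name, quad in _NU_DEFS:
            if all(res.has_atom(a) for a in quad):
                nus[nu_name] = dihedral(*(res.atom(a).coord for a in quad))
            else:
                ok = False
        if ok:
            ring = {a: res.atom(a).coord for a in _templates.RING_ATOMS}
            P, nu_max = _templates.pseudorotation_phase(ring)
            out.update(nus)
            out["P"] = P
            out["nu_max"] = nu_max
        else:
            out["P"] = math.nan
            out["nu_max"] = math.nan
            missing.append("P")
        angles[res.index] = out
        if missing:
            incomplete[res.index] = missing
    return TorsionSet(angles, incomplete)


def classify_pucker(tors: TorsionSet, residue: int,
                    amplitude_floor: float = 10.0) -> PuckerCall:
    """North/South pucker call from pseudorotation phase.

    C2'-endo (South) for P in [90, 270); C3'-endo (North) otherwise.
    A puckering amplitude below ``amplitude_floor`` makes the ring nearly
    planar and the phase meaningless -> ambiguous.
    """
    ang = tors.residue(residue)
    P, amp = ang.get("P", math.nan), ang.get("nu_max", math.nan)
    if math.isnan(P):
        return PuckerCall("ambiguous", math.nan, math.nan,
                          reason="pseudorotation undefined (missing ring atoms)")
    if amp < amplitude_floor:
        return PuckerCall("ambiguous", P, amp,
                          reason=f"amplitude {amp:.1f} below {amplitude_floor} deg")
    state = "C2'-endo" if 90.0 <= P < 270.0 else "C3'-endo"
    return PuckerCall(state, P, amp)


def pucker_population(ensemble: list[Conformer], residue: int,
                      amplitude_floor: float = 10.0) -> float:
    """Fraction of unambiguous ensemble members with C2'-endo pucker."""
    n_south = n_defined = 0
    for conf in ensemble:
        call = classify_pucker(compute_torsions(conf), residue, amplitude_floor)
        if call.state == "ambiguous":
            continue
        n_defined += 1
        n_south += call.state == "C2'-endo"
    if n_defined == 0:
        raise ValueError(f"residue {residue}: pucker ambiguous in every member")
    return n_south / n_defined


def shift_to_c2endo(shift_ppm: float,
                    pucker_map: ShiftPuckerMap | None = None) -> float:
    """Percent C2'-endo from a C1' chemical shift by linear interpolation
    between the two anchors (default 86 ppm = 100%, 94 ppm = 0%)."""
    m = pucker_map or ShiftPuckerMap()
    frac = (shift_ppm - m.shift_c3endo) / (m.shift_c2endo - m.shift_c3endo)
    pct = 100.0 * frac
    if m.clamp:
        pct = min(100.0, max(0.0, pct))
    return pct


# ---------------------------------------------------------------------------
# inter-helical orientation
# ---------------------------------------------------------------------------

def _helix_reference(conformer: Conformer,
                     bp_range: tuple[tuple[int, ...], tuple[int, ...]]
                     ) -> Conformer:
    """Idealized A-form reference helix matching a base-paired segment."""
    s1_nums, s2_nums = (tuple(bp_range[0]), tuple(bp_range[1]))
    s1 = "".join(conformer.residue(i).base for i in s1_nums)
    s2 = "".join(conformer.residue(i).base for i in s2_nums)
    spec = HelixSpec(s1, s2, s1_nums, s2_nums, allow_noncomplementary=True)
    return build_aform_helix(spec)


def _segment_rotation(conformer: Conformer, reference: Conformer,
                      numbers: tuple[int, ...]) -> tuple[np.ndarray, float]:
    src, dst = [], []
    for idx in numbers:
        ref_res = reference.residue(idx)
        con_res = conformer.residue(idx)
        for a in ref_res.heavy_atoms():
            if con_res.has_atom(a.name):
                src.append(a.coord)
                dst.append(con_res.atom(a.name).coord)
    if len(src) < 3:
        raise ValueError(f"too few common atoms to orient residues {numbers}")
    src, dst = np.array(src), np.array(dst)
    R, t = kabsch(src, dst)
    rmsd = float(np.sqrt(np.mean(np.sum((src @ R.T + t - dst) ** 2, axis=1))))
    return R, rmsd


def interhelical_euler(conformer: Conformer,
                       upper_bp_range: tuple[tuple[int, ...], tuple[int, ...]],
                       lower_bp_range: tuple[tuple[int, ...], tuple[int, ...]],
                       rmsd_warn: float = 2.0) -> InterhelicalOrientation:
    """Inter-helical Euler angles (alpha_h, beta_h, gamma_h) in degrees.

    Each bp range is ``((strand1 residue numbers), (strand2 residue
    numbers))`` for >= 2 bp of helix.  An idealized A-form reference is
    least-squares superposed (heavy atoms) onto each segment; the relative
    rotation R_upper R_lower^T is decomposed as ZYZ Euler angles.  |beta_h|
    is the inter-helical bend; alpha_h and gamma_h carry a sign flip so a
    positive twist alpha_h + gamma_h means over-twisting of the junction.
    A superposition worse than ``rmsd_warn`` A marks the frame unreliable.
    """
    all_upper = tuple(upper_bp_range[0]) + tuple(upper_bp_range[1])
    all_lower = tuple(lower_bp_range[0]) + tuple(lower_bp_range[1])
    ref_upper = _helix_reference(conformer, upper_bp_range)
    ref_lower = _helix_reference(conformer, lower_bp_range)
    R_up, rms_up = _segment_rotation(conformer, ref_upper, all_upper)
    R_lo, rms_lo = _segment_rotation(conformer, ref_lower, all_lower)
    # relative rotation expressed in the lower-helix reference frame; this
    # form is invariant under global rigid motion of the conformer
    R_rel = R_lo.T @ R_up
    a, b, c = euler_zyz(R_rel)
    return InterhelicalOrientation(
        alpha_h=-a, beta_h=b, gamma_h=-c,
        frame_rmsd_upper=rms_up, frame_rmsd_lower=rms_lo,
        unreliable=(rms_up > rmsd_warn or rms_lo > rmsd_warn))


def bend_category(orientation: InterhelicalOrientation) -> str:
    """Bend classes: linear (|beta| < 45), intermediate (45-70), kinked
    (> 70); boundary values go to the lower-bend class."""
    b = orientation.bend_magnitude
    if b <= 45.0:
        return "linear"
    if b <= 70.0:
        return "intermediate"
    return "kinked"


# ---------------------------------------------------------------------------
# stacking / flipping
# ---------------------------------------------------------------------------

def _ring_centroid_normal(res) -> tuple[np.ndarray, np.ndarray] | None:
    names = _templates.base_ring_atoms(res.base)
    if not all(res.has_atom(a) for a in names):
        return None
    ring = np.array([res.atom(a).coord for a in names])
    centroid = ring.mean(axis=0)
    normal = np.linalg.svd(ring - centroid)[2][2]
    return centroid, normal


def detect_stacking(conformer: Conformer, residue_a: int, residue_b: int,
                    criterion: StackingCriterion | None = None) -> bool | None:
    """Geometric stacking call for two bases; None if rings incomplete."""
    crit = criterion or StackingCriterion()
    ga = _ring_centroid_normal(conformer.residue(residue_a))
    gb = _ring_centroid_normal(conformer.residue(residue_b))
    if ga is None or gb is None:
        return None
    ca, na = ga
    cb, nb = gb
    d = cb - ca
    if np.linalg.norm(d) > crit.max_centroid_distance:
        return False
    cosang = abs(float(na @ nb))
    if np.degrees(np.arccos(min(1.0, cosang))) > crit.max_normal_angle:
        return False
    nav = na + (nb if na @ nb > 0 else -nb)
    nav /= np.linalg.norm(nav)
    lateral = np.linalg.norm(d - (d @ nav) * nav)
    return bool(lateral <= crit.max_lateral_offset)


def detect_coaxial(conformer: Conformer,
                   bridging_pairs: list[tuple[tuple[int, int], tuple[int, int]]],
                   criterion: StackingCriterion | None = None) -> bool | None:
    """Coaxial-stacking call: true iff the bases of any configured
    cross-junction pair of base pairs stack with each other.

    ``bridging_pairs`` lists ((a1, a2), (b1, b2)) combinations, each a bp
    from one helix paired against a bp from the other; the two bp stack
    when some base of the first stacks with some base of the second.
    """
    if not bridging_pairs:
        raise ValueError("bridging pair list must be non-empty")
    any_undetermined = False
    for (a1, a2), (b1, b2) in bridging_pairs:
        for x in (a1, a2):
            for y in (b1, b2):
                if not conformer.has_residue(x) or not conformer.has_residue(y):
                    raise ValueError(f"bridging residues {x}/{y} not in conformer")
                call = detect_stacking(conformer, x, y, criterion)
                if call is None:
                    any_undetermined = True
                elif call:
                    return True
    return None if any_undetermined else False


def detect_extra_helical(conformer: Conformer, residue: int,
                         flanking_bp_residues: tuple[int, ...],
                         criterion: StackingCriterion | None = None
                         ) -> bool | None:
    """Extra-helical ("flipped out") call for an unpaired residue.

    True iff the base stacks with no base of the flanking closing pairs
    (the junction-proximal bp on each side).  None when any stacking call
    is undetermined.
    """
    any_undetermined = False
    for other in flanking_bp_residues:
        call = detect_stacking(conformer, residue, other, criterion)
        if call is None:
            any_undetermined = True
        elif call:
            return False
    return None if any_undetermined else True


def flip_stack_report(conformer: Conformer, bulge_residues: list[int],
                      flanking_bp_residues: tuple[int, ...],
                      bridging_pairs: list[tuple[tuple[int, int], tuple[int, int]]],
                      criterion: StackingCriterion | None = None
                      ) -> FlipStackReport:
    extra = {r: detect_extra_helical(conformer, r, flanking_bp_residues, criterion)
             for r in bulge_residues}
    stacked = {}
    for (a1, a2), (b1, b2) in bridging_pairs:
        best = False
        for x in (a1, a2):
            for y in (b1, b2):
                call = detect_stacking(conformer, x, y, criterion)
                if call is None:
                    best = None
                    break
                best = best or call
            if best is None:
                break
        stacked[(a1, b1)] = best
    return FlipStackReport(extra_helical=extra, stacked_pairs=stacked,
                           coaxial=detect_coaxial(conformer, bridging_pairs, criterion))


# ---------------------------------------------------------------------------
# cooperativity of bulge flipping
# ---------------------------------------------------------------------------

def cooperativity(flip_table: np.ndarray, temperature: float = 298.0
                  ) -> CooperativityResult:
    """Flip-out cooperativity from per-conformer flags (members x residues).

    The independent flip-out probability of residue k is estimated from
    conformers whose other residues are all flipped in:

        P_k = N(k out | others in) / (N(k out | others in) + N(all in)).

    Their product is the no-cooperativity prediction for all residues
    flipping out together; comparing it with the observed all-out fraction
    gives the coupling free energy -RT ln(P_obs / P_indep) at 298 K
    (negative = favorable cooperativity).
    """
    table = np.asarray(flip_table, dtype=bool)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("flip table must be members x residues with >= 2 residues")
    n, k = table.shape
    all_in = int(np.sum(~table.any(axis=1)))
    p_out = {}
    for j in range(k):
        others_in = ~np.delete(table, j, axis=1).any(axis=1)
        out_alone = int(np.sum(table[:, j] & others_in))
        denom = out_alone + all_in
        if denom == 0:
            raise ZeroDivisionError(
                f"residue column {j}: no conformers with the other residues "
                f"flipped in (N(out|in)={out_alone}, N(all in)={all_in})")
        p_out[j] = out_alone / denom
    p_indep = float(np.prod(list(p_out.values())))
    p_obs = float(np.mean(table.all(axis=1)))
    if p_indep == 0.0:
        raise ZeroDivisionError(
            f"independent all-out probability is zero (p_out={p_out}); "
            f"cooperativity undefined")
    if p_obs == 0.0:
        delta_g = math.inf
    else:
        delta_g = -GAS_CONSTANT_KCAL * temperature * math.log(p_obs / p_indep)
    return CooperativityResult(p_out=p_out, p_independent=p_indep,
                               p_observed=p_obs, delta_g=delta_g,
                               temperature=temperature)


# ---------------------------------------------------------------------------
# superposition RMSD / ensemble distance
# ---------------------------------------------------------------------------

def _selection_coords(conf: Conformer,
                      atom_selection: list[tuple[int, str]] | None,
                      heavy_only: bool = True) -> np.ndarray:
    if atom_selection is None:
        return conf.coords(heavy_only=heavy_only)
    return conf.atom_coords(atom_selection)


def superpose_rmsd(mobile: Conformer, reference: Conformer,
                   atom_selection: list[tuple[int, str]] | None = None) -> float:
    """Heavy-atom (or explicit-selection) RMSD after optimal rigid
    superposition."""
    a = _selection_coords(mobile, atom_selection)
    b = _selection_coords(reference, atom_selection)
    if a.shape != b.shape:
        raise ValueError(f"selection mismatch: {a.shape[0]} vs {b.shape[0]} atoms")
    return superposed_rmsd(a, b)


def ensemble_distance(A: list[Conformer], B: list[Conformer],
                      atom_selection: list[tuple[int, str]] | None = None
                      ) -> float:
    """Lower-bound inter-ensemble distance (A).

    For each member of A, the minimum superposition RMSD to any member of
    B; root-mean-square of those N_A values; symmetrized by repeating from
    B and taking the smaller of the two directions.
    """
    if not A or not B:
        raise ValueError("both ensembles must be non-empty")
    coords_a = [_selection_coords(c, atom_selection) for c in A]
    coords_b = [_selection_coords(c, atom_selection) for c in B]

    def directed(xs, ys):
        mins = []
        for x in xs:
            mins.append(min(superposed_rmsd(x, y) for y in ys))
        return float(np.sqrt(np.mean(np.square(mins))))

    return min(directed(coords_a, coords_b), directed(coords_b, coords_a))
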