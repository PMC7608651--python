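"""Sample-and-select (SAS) ensemble refinement against measured RDCs.

SAS picks an N-member sub-ensemble from a conformer pool so that the
equal-weight ensemble-averaged predicted couplings best match the measured
ones, with one free scale factor per construct absorbing alignment-magnitude
differences.  The cost is the squared-residual form

    chi^2 = sum_j sum_i (L_j D_calc_ij - D_exp_ij)^2,

minimized by a simulated-annealing Monte Carlo chain over member swaps: the
effective temperature starts at 100 and is multiplied by 0.9 every proposal
step (with a floor), for 5x10^5 steps by default, which makes the chain
effectively greedy after the first few hundred steps.  Larger analysis
ensembles are produced by pooling many independent runs.  Two
cross-validation modes (random record hold-out, leave-one-construct-out)
test for over-fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .rdc_model import RDCDataset, RDCMatrix, fit_scale_factors, rdc_rmsd

__all__ = [
    "SASConfig",
    "SASResult",
    "CrossValResult",
    "PooledRuns",
    "sas_select",
    "size_scan",
    "find_plateau",
    "pool_runs",
    "crossval_random",
    "crossval_media",
    "derive_seed",
    "ensemble_cost",
]


def derive_seed(master: int, *keys: int) -> int:
    """Counter-based child seed: hash of (master, keys) via SeedSequence."""
    ss = np.random.SeedSequence([int(master), *map(int, keys)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SASConfig:
    ensemble_size: int = 20
    t_initial: float = 100.0
    cool_factor: float = 0.9
    n_steps: int = 500_000
    temperature_floor: float = 1e-12
    seed: int = 0
    refit_scales: bool = True
    cool_block: int = 1          # steps between temperature multiplications
    reheat: bool = True          # restart at t_initial once the floor is hit
    trace_points: int = 200

    def __post_init__(self):
        if not (0.0 < self.cool_factor < 1.0):
            raise ValueError("cool_factor must be in (0, 1)")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.cool_block < 1:
            raise ValueError("cool_block must be >= 1")


@dataclass
class SASResult:
    member_indices: list[int]
    scales: dict[str, float]
    chi2: float
    rmsd_hz: float
    trace: np.ndarray
    seed: int
    config: SASConfig

    def __post_init__(self):
        if np.any(np.diff(self.trace) > 1e-9):
            raise ValueError("best-cost trace must be non-increasing")


@dataclass
class CrossValResult:
    mode: str
    heldout_rmsd_hz: float
    per_fold: list[float]
    repeats: int
    training_rmsd_hz: list[float] = field(default_factory=list)


@dataclass
class PooledRuns:
    member_indices: list[int]
    runs: list[SASResult]


def _group_matrix(dataset: RDCDataset) -> np.ndarray:
    """Construct-indicator matrix G (constructs x records)."""
    codes = dataset.construct_codes()
    n_c = codes.max() + 1
    G = np.zeros((n_c, len(dataset)))
    G[codes, np.arange(len(dataset))] = 1.0
    return G


def _sse_refit(mean_row: np.ndarray, exp: np.ndarray, G: np.ndarray,
               sum_exp2_per: np.ndarray) -> float:
    """SSE after per-construct least-squares scaling, in closed form.

    Per construct: min_L sum (L*calc - exp)^2 = sum exp^2 - (sum exp*calc)^2
    / sum calc^2.
    """
    a = G @ (exp * mean_row)
    b = G @ (mean_row * mean_row)
    red = np.divide(a * a, b, out=np.zeros_like(a), where=b > 1e-300)
    return float(np.sum(sum_exp2_per - red))


def ensemble_cost(matrix: RDCMatrix, dataset: RDCDataset,
                  members: list[int], refit_scales: bool = True,
                  scales: dict[str, float] | None = None
                  ) -> tuple[float, float, dict[str, float]]:
    """Direct evaluation of (chi2, rmsd, scales) for a member set.

    Recomputes everything from scratch; used for final reporting, tests,
    and as the ground truth the annealing loop must agree with.
    """
    mean_row = matrix.values[np.asarray(members)].mean(axis=0)
    if refit_scales or scales is None:
        scales = fit_scale_factors(mean_row, dataset)
    L = np.array([scales[r.construct_id] for r in dataset.records])
    resid = L * mean_row - dataset.values()
    chi2 = float(np.sum(resid ** 2))
    return chi2, float(np.sqrt(chi2 / len(dataset))), scales


def sas_select(matrix: RDCMatrix, dataset: RDCDataset,
               config: SASConfig) -> SASResult:
    """Simulated-annealing Monte Carlo selection of an N-member ensemble.

    Each step proposes replacing one uniformly chosen member with a
    uniformly chosen non-member; the move is accepted with probability
    min(1, exp(-d(chi2/N_rec)/T)).  Members within one ensemble are
    distinct.  Returns the best ensemble ever visited.  Bit-reproducible
    for a given seed.
    """
    n_lib = matrix.n_conformers
    N = config.ensemble_size
    if N > n_lib:
        raise ValueError(f"ensemble size {N} exceeds library size {n_lib}")
    V = matrix.values
    exp = dataset.values()
    n_rec = len(dataset)
    G = _group_matrix(dataset)
    sum_exp2_per = G @ (exp * exp)

    rng = np.random.default_rng(config.seed)
    if N == n_lib:
        # the whole library is the only N-member ensemble; nothing to sample
        members = np.arange(n_lib)
        chi2, rmsd, scales = ensemble_cost(matrix, dataset, list(members),
                                           refit_scales=config.refit_scales)
        return SASResult(member_indices=list(range(n_lib)), scales=scales,
                         chi2=chi2, rmsd_hz=rmsd,
                         trace=np.array([chi2 / len(dataset)]),
                         seed=config.seed, config=config)
    members = rng.choice(n_lib, size=N, replace=False)
    is_member = np.zeros(n_lib, dtype=bool)
    is_member[members] = True
    mean_row = V[members].mean(axis=0)

    fixed_L = None
    if not config.refit_scales:
        fixed_scales = fit_scale_factors(mean_row, dataset)
        fixed_L = np.array([fixed_scales[r.construct_id] for r in dataset.records])

    def cost_of(row: np.ndarray) -> float:
        if fixed_L is None:
            return _sse_refit(row, exp, G, sum_exp2_per)
        r = fixed_L * row - exp
        return float(r @ r)

    cost = cost_of(mean_row)
    best_cost = cost
    best_members = members.copy()

    n_steps = config.n_steps
    exponents = np.arange(n_steps) // config.cool_block
    if config.reheat:
        # geometric cooling down to the floor, then reheat to t_initial:
        # each cycle anneals anew from the current ensemble, so one long
        # run behaves like many short annealing quenches (basin hopping)
        # while the best-ever ensemble is retained
        cycle = int(np.ceil(np.log(config.temperature_floor / config.t_initial)
                            / np.log(config.cool_factor)))
        exponents = exponents % max(cycle, 1)
    with np.errstate(under="ignore"):
        temps = np.maximum(config.t_initial * config.cool_factor ** exponents,
                           config.temperature_floor)
    trace_every = max(1, n_steps // config.trace_points)
    trace = []

    chunk = 8192
    pos = chunk  # force first refill
    for step in range(n_steps):
        if pos >= chunk:
            slots = rng.integers(0, N, size=chunk)
            cands = rng.integers(0, n_lib, size=chunk)
            unifs = rng.random(chunk)
            pos = 0
        slot = slots[pos]
        cand = cands[pos]
        u = unifs[pos]
        pos += 1
        while is_member[cand]:
            cand = int(rng.integers(0, n_lib))
        old = members[slot]
        new_row = mean_row + (V[cand] - V[old]) / N
        new_cost = cost_of(new_row)
        d = (new_cost - cost) / n_rec  # Metropolis on the mean-squared scale
        if d <= 0.0 or u < np.exp(-d / temps[step]):
            members[slot] = cand
            is_member[old] = False
            is_member[cand] = True
            mean_row = new_row
            cost = new_cost
            if cost < best_cost:
                best_cost = cost
                best_members = members.copy()
        if step % trace_every == 0:
            trace.append(best_cost / n_rec)

    chi2, rmsd, scales = ensemble_cost(matrix, dataset, best_members,
                                       refit_scales=config.refit_scales)
    return SASResult(member_indices=sorted(int(i) for i in best_members),
                     scales=scales, chi2=chi2, rmsd_hz=rmsd,
                     trace=np.array(trace), seed=config.seed, config=config)


def find_plateau(means: list[float] | np.ndarray, tol: float) -> int | None:
    """Index of the first entry whose improvement over its predecessor is
    below ``tol`` (the RMSD-vs-N plateau); None if never reached."""
    means = np.asarray(means, dtype=float)
    for i in range(1, len(means)):
        if means[i - 1] - means[i] < tol:
            return i
    return None


def size_scan(matrix: RDCMatrix, dataset: RDCDataset, sizes: list[int],
              replicates: int, seed: int,
              config: SASConfig | None = None,
              plateau_tol: float = 0.2):
    """RMSD as a function of ensemble size N, averaged over replicates.

    Returns a pandas DataFrame with columns N, mean_rmsd, sd_rmsd, plateau
    (bool flag at the first size where improvement drops below
    ``plateau_tol`` Hz).  Each (N, replicate) runs an independent
    :func:`sas_select` with a derived seed.
    """
    import pandas as pd

    if not sizes:
        raise ValueError("sizes list must be non-empty")
    config = config or SASConfig()
    rows = []
    for si, n in enumerate(sizes):
        rmsds = []
        for rep in range(replicates):
            cfg = replace(config, ensemble_size=n,
                          seed=derive_seed(seed, si, rep))
            rmsds.append(sas_select(matrix, dataset, cfg).rmsd_hz)
        rows.append((n, float(np.mean(rmsds)), float(np.std(rmsds))))
    df = pd.DataFrame(rows, columns=["N", "mean_rmsd", "sd_rmsd"])
    p = find_plateau(df["mean_rmsd"].to_numpy(), plateau_tol)
    df["plateau"] = [p is not None and i >= p for i in range(len(df))]
    return df


def pool_runs(matrix: RDCMatrix, dataset: RDCDataset, config: SASConfig,
              total_size: int) -> PooledRuns:
    """Pool total_size/N independent SAS runs into one large multiset.

    Used to build the large (e.g. N = 20 x 100 = 2000) ensembles on which
    structural distributions are analyzed.  Duplicates across runs are kept
    and counted.
    """
    N = config.ensemble_size
    if total_size % N != 0:
        raise ValueError(f"total_size {total_size} not divisible by "
                         f"ensemble size {N}")
    n_runs = total_size // N
    runs = []
    pooled: list[int] = []
    for k in range(n_runs):
        cfg = replace(config, seed=derive_seed(config.seed, k))
        res = sas_select(matrix, dataset, cfg)
        runs.append(res)
        pooled.extend(res.member_indices)
    return PooledRuns(member_indices=pooled, runs=runs)


def crossval_random(matrix: RDCMatrix, dataset: RDCDataset,
                    config: SASConfig, fraction: float = 0.10,
                    repeats: int = 10, seed: int | None = None
                    ) -> CrossValResult:
    """Hold out a random fraction of records, select on the rest, score the
    held-out records with the training-fit scales; average over repeats."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("held-out fraction must be in (0, 1)")
    n_rec = len(dataset)
    n_hold = int(np.floor(fraction * n_rec))
    if n_hold < 1:
        raise ValueError(f"fraction {fraction} holds out zero of {n_rec} records")
    seed = config.seed if seed is None else seed
    per_fold, train_rmsds = [], []
    for rep in range(repeats):
        rng = np.random.default_rng(derive_seed(seed, 7, rep))
        held = np.sort(rng.choice(n_rec, size=n_hold, replace=False))
        train = np.setdiff1d(np.arange(n_rec), held)
        ds_train = dataset.subset(train)
        m_train = RDCMatrix(matrix.values[:, train], ds_train,
                            matrix.conformer_ids)
        cfg = replace(config, seed=derive_seed(seed, 11, rep))
        res = sas_select(m_train, ds_train, cfg)
        train_rmsds.append(res.rmsd_hz)
        mean_row = matrix.values[np.asarray(res.member_indices)].mean(axis=0)
        ds_held = dataset.subset(held)
        per_fold.append(rdc_rmsd(mean_row[held], ds_held, res.scales))
    return CrossValResult(mode="inactive_random",
                          heldout_rmsd_hz=float(np.mean(per_fold)),
                          per_fold=per_fold, repeats=repeats,
                          training_rmsd_hz=train_rmsds)


def crossval_media(matrix: RDCMatrix, dataset: RDCDataset,
                   config: SASConfig) -> CrossValResult:
    """Leave out each construct's dataset in turn, select on the others.

    The held-out construct's scale cannot come from training (alignment
    magnitude is construct-specific), so a single free scale is fit post
    hoc on its own data; only the relative RDC pattern is therefore tested.
    """
    constructs = dataset.constructs
    if len(constructs) < 2:
        raise ValueError("leave-one-construct-out needs >= 2 constructs")
    codes = dataset.construct_codes()
    per_fold, train_rmsds = [], []
    for j, cid in enumerate(constructs):
        held = np.flatnonzero(codes == j)
        train = np.flatnonzero(codes != j)
        ds_train = dataset.subset(train)
        m_train = RDCMatrix(matrix.values[:, train], ds_train,
                            matrix.conformer_ids)
        cfg = replace(config, seed=derive_seed(config.seed, 13, j))
        res = sas_select(m_train, ds_train, cfg)
        train_rmsds.append(res.rmsd_hz)
        ds_held = dataset.subset(held)
        mean_row = matrix.values[np.asarray(res.member_indices)].mean(axis=0)
        held_scales = fit_scale_factors(mean_row[held], ds_held)
        per_fold.append(rdc_rmsd(mean_row[held], ds_held, held_scales))
    return CrossValResult(mode="inactive_media",
                          heldout_rmsd_hz=float(np.mean(per_fold)),
                          per_fold=per_fold, repeats=len(constructs),
                          training_rmsd_hz=train_rmsds)
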