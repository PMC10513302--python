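"""Simulated-annealing mate selection.

Joint selection and mate allocation in one parental population (La Me):
the decision variable is the upper triangle + diagonal of a 0/1 cross
matrix X over the preselected candidates; exactly ``n_cross`` cells are
set.  The objective E is the *negative* mean expected hybrid FFB over all
pairs of (fixed Deli cross, La Me cross), so lower is better, and the
admissible set is

    (i)   x_ij in {0, 1}
    (ii)  sum x_ij = n_cross
    (iii) (1/n_cross) sum x_ij f_ij  <  F(n) + dF(n)

with f the kinship (pedigree) or genomic coancestry matrix of the
candidates and an adaptive threshold increment

    dF(n) = (Frand(n+1) - F(n)) + c_dF * (Fconv(n+1) - Frand(n+1)),

interpolating between the inbreeding reached by random selection-and-
mating (lower anchor, 12 replicates) and by the conventional method
(upper anchor, 7 replicates).

Cooling is geometric (T <- 0.95 T); the neighbourhood swaps ``nr`` set
and unset cells, with nr = 3 at the first five temperature levels, 2 up
to level 15, then 1.  T0 is calibrated so a non-improving move is
accepted with probability ~0.5 at the start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mating import CrossMatrix, conventional_mating
from .inbreeding import progeny_inbreeding_of_design


@dataclass
class SAConfig:
    """Tuning constants of the annealer (defaults: 120-candidate preset)."""

    n_presel: int = 50
    n1: int = 80                  # max temperature reductions
    n2: int = 50                  # iterations per temperature
    n_m: int = 30                 # max acceptances per temperature
    cooling_factor: float = 0.95
    nr_schedule: tuple[tuple[int, int], ...] = ((5, 3), (15, 2))  # (up-to-level, nr)
    nr_final: int = 1
    neighbor_attempt_cap: int = 5000
    t0_probe_count: int = 10
    t0_target_accept: float = 0.5
    x0_retry_cap: int = 5
    t0_floor: float = 0.15
    n_restarts: int = 96
    n_cross: int = 32
    n_select_init: int = 16

    def __post_init__(self) -> None:
        if not (0 < self.cooling_factor < 1):
            raise ValueError("cooling factor must be in (0, 1)")
        for name in ("n_presel", "n1", "n2", "n_m", "n_cross", "n_select_init"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def nr_at_level(self, level: int) -> int:
        """nr for the given temperature level (1-based count of levels)."""
        for upto, nr in self.nr_schedule:
            if level <= upto:
                return nr
        return self.nr_final

    @classmethod
    def preset_120(cls) -> "SAConfig":
        return cls(n_presel=50, n1=80, n2=50, n_m=30)

    @classmethod
    def preset_330(cls) -> "SAConfig":
        return cls(n_presel=60, n1=100, n2=100, n_m=60)


@dataclass
class ThresholdSpec:
    """Adaptive inbreeding bound for constraint (iii)."""

    c_delta_f: float
    f_n: float           # mean inbreeding of the current candidates
    f_rand_next: float   # random selection + random mating anchor (12 reps)
    f_conv_next: float   # conventional method anchor (7 reps)

    @property
    def delta_f(self) -> float:
        return (self.f_rand_next - self.f_n) + self.c_delta_f * (
            self.f_conv_next - self.f_rand_next
        )

    @property
    def bound(self) -> float:
        return self.f_n + self.delta_f


def compute_threshold(
    candidate_ids,
    kinship,
    ranked_ids,
    f_n: float,
    c_delta_f: float,
    rng: np.random.Generator,
    n_select: int = 16,
    n_cross: int = 32,
    crosses_per_parent: int = 4,
    n_rand_reps: int = 12,
    n_conv_reps: int = 7,
) -> ThresholdSpec:
    """Adaptive threshold from random-mating and conventional-design anchors.

    ``kinship`` is the full candidate coancestry matrix (RelationshipMatrix);
    ``ranked_ids`` the conventional ranking of all candidates.  Both anchors
    are mean progeny inbreeding of simulated designs: random selection and
    random mating for the lower one, conventional top-``n_select`` selection
    and random mating for the upper one.
    """
    candidate_ids = np.asarray(candidate_ids)
    rand_vals = []
    for _ in range(n_rand_reps):
        perm = rng.permutation(candidate_ids)
        X = conventional_mating(
            perm, n_select, n_cross, crosses_per_parent, True, rng
        )
        rand_vals.append(progeny_inbreeding_of_design(X.cells, kinship, ids=X.ids))
    conv_vals = []
    for _ in range(n_conv_reps):
        X = conventional_mating(
            np.asarray(ranked_ids), n_select, n_cross, crosses_per_parent, True, rng
        )
        conv_vals.append(progeny_inbreeding_of_design(X.cells, kinship, ids=X.ids))
    return ThresholdSpec(
        c_delta_f=c_delta_f,
        f_n=float(f_n),
        f_rand_next=float(np.mean(rand_vals)),
        f_conv_next=float(np.mean(conv_vals)),
    )


# ---------------------------------------------------------------------------
# Problem container
# ---------------------------------------------------------------------------


@dataclass
class MateSelectionProblem:
    """One mate-selection instance over the preselected candidates.

    ``ids`` are the preselected La Me candidates in rank order (rank 1
    first); ``g_bn``/``g_bw`` their (G)EBVs on the absolute half-scale;
    ``kinship`` their coancestry matrix f_ij; the Deli side enters only
    through the three statistics of its fixed conventional design.
    """

    ids: np.ndarray
    g_bn: np.ndarray
    g_bw: np.ndarray
    kinship: np.ndarray          # (n, n) f_ij among the preselected
    deli_mean_a: float           # mean over Deli crosses of 0.5(g_i+g_j)(BN)
    deli_mean_b: float           # same for BW
    deli_mean_ab: float          # mean of the product a*b over Deli crosses
    bound: float | None = None   # F(n) + dF(n); None disables (iii)
    n_cross: int = 32

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.g_bn = np.asarray(self.g_bn, dtype=float)
        self.g_bw = np.asarray(self.g_bw, dtype=float)
        self.kinship = np.asarray(self.kinship, dtype=float)
        n = self.ids.size
        if not (self.g_bn.size == self.g_bw.size == n == self.kinship.shape[0]):
            raise ValueError("inconsistent problem dimensions")
        iu, ju = np.triu_indices(n)
        self._iu, self._ju = iu, ju
        # per-cell cross statistics
        self._cell_a = 0.5 * (self.g_bn[iu] + self.g_bn[ju])
        self._cell_b = 0.5 * (self.g_bw[iu] + self.g_bw[ju])
        self._cell_ab = self._cell_a * self._cell_b
        self._cell_f = self.kinship[iu, ju]
        self._cell_index = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}

    @property
    def n_candidates(self) -> int:
        return self.ids.size

    @property
    def n_cells(self) -> int:
        return self._iu.size

    def cell_of(self, i: int, j: int) -> int:
        return self._cell_index[(min(i, j), max(i, j))]

    def cells_to_pairs(self, cell_idx) -> list[tuple[int, int]]:
        return [(int(self._iu[k]), int(self._ju[k])) for k in cell_idx]

    # -- evaluation --------------------------------------------------------

    def evaluate_cells(self, cell_idx: np.ndarray) -> float:
        """E for the design given by flat cell indices (lower is better)."""
        a = self._cell_a[cell_idx]
        b = self._cell_b[cell_idx]
        mean_ffb = (
            self.deli_mean_ab
            + self.deli_mean_a * b.mean()
            + self.deli_mean_b * a.mean()
            + (a * b).mean()
        )
        return -float(mean_ffb)

    def mean_kinship(self, cell_idx: np.ndarray) -> float:
        return float(self._cell_f[cell_idx].mean())

    def feasible(self, cell_idx: np.ndarray) -> bool:
        if self.bound is None:
            return True
        return self.mean_kinship(cell_idx) < self.bound

    def cross_matrix(self, cell_idx: np.ndarray) -> CrossMatrix:
        return CrossMatrix(self.ids, self.cells_to_pairs(cell_idx))


def deli_design_stats(deli_design: CrossMatrix, deli_ebvs: pd.DataFrame) -> tuple[float, float, float]:
    """(mean a, mean b, mean a*b) over the crosses of the fixed Deli design."""
    tab = deli_ebvs.set_index("individual_id")
    a_vals, b_vals = [], []
    for i, j in deli_design.cells:
        gi = tab.loc[int(deli_design.ids[i])]
        gj = tab.loc[int(deli_design.ids[j])]
        a_vals.append(0.5 * (gi["g_bn"] + gj["g_bn"]))
        b_vals.append(0.5 * (gi["g_bw"] + gj["g_bw"]))
    a = np.asarray(a_vals)
    b = np.asarray(b_vals)
    return float(a.mean()), float(b.mean()), float((a * b).mean())


def evaluate_E(
    X: CrossMatrix,
    deli_design: CrossMatrix,
    deli_ebvs: pd.DataFrame,
    lame_ebvs: pd.DataFrame,
) -> float:
    """Reference evaluation: explicit double loop over all cross pairs.

    Used as the plain-definition counterpart of the factorized incremental
    evaluation inside the annealer.
    """
    from .evaluation import expected_hybrid_ffb

    dtab = deli_ebvs.set_index("individual_id")
    ltab = lame_ebvs.set_index("individual_id")
    vals = []
    for di, dj in deli_design.cells:
        gd_i = dtab.loc[int(deli_design.ids[di])]
        gd_j = dtab.loc[int(deli_design.ids[dj])]
        for li, lj in X.cells:
            gl_i = ltab.loc[int(X.ids[li])]
            gl_j = ltab.loc[int(X.ids[lj])]
            vals.append(
                expected_hybrid_ffb(
                    (gd_i["g_bn"], gd_i["g_bw"]),
                    (gd_j["g_bn"], gd_j["g_bw"]),
                    (gl_i["g_bn"], gl_i["g_bw"]),
                    (gl_j["g_bn"], gl_j["g_bw"]),
                )
            )
    return -float(np.mean(vals))


# ---------------------------------------------------------------------------
# SA primitives
# ---------------------------------------------------------------------------


class RestartAborted(RuntimeError):
    """A restart could not build a usable initial solution."""


def initial_solution(
    problem: MateSelectionProblem,
    config: SAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random X0: select ``n_select_init`` candidates, mate them at random.

    Rules (i)-(ii) hold by construction; the kinship constraint (iii) is not
    enforced on X0 (the neighbourhood enforces it on every later solution).
    Returns flat cell indices.
    """
    n = problem.n_candidates
    chosen = rng.choice(n, size=min(config.n_select_init, n), replace=False)
    # random cells among the chosen subset, every chosen individual involved
    for _ in range(10_000):
        sub_cells = [
            (min(a, b), max(a, b))
            for a in chosen
            for b in chosen
            if a <= b
        ]
        picks = rng.choice(len(sub_cells), size=problem.n_cross, replace=False)
        cells = [sub_cells[k] for k in picks]
        involved = set(k for c in cells for k in c)
        if involved == set(int(c) for c in chosen):
            return np.array([problem.cell_of(i, j) for i, j in cells])
    raise RestartAborted("could not build an initial solution")


def neighbor(
    cell_idx: np.ndarray,
    nr: int,
    problem: MateSelectionProblem,
    config: SAConfig,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Replacement function: drop nr set cells, set nr unset cells.

    Retries until the alternative satisfies rules (i)-(iii), up to the
    attempt cap; ``None`` signals exhaustion (the caller keeps the input as
    the final solution and stops).
    """
    cur = np.asarray(cell_idx)
    in_x = np.zeros(problem.n_cells, dtype=bool)
    in_x[cur] = True
    unset = np.flatnonzero(~in_x)
    for _ in range(config.neighbor_attempt_cap):
        drop = rng.choice(cur.size, size=nr, replace=False)
        add = rng.choice(unset.size, size=nr, replace=False)
        cand = cur.copy()
        cand[drop] = unset[add]
        if problem.feasible(cand):
            return cand
    return None


def calibrate_T0(
    x0: np.ndarray,
    problem: MateSelectionProblem,
    config: SAConfig,
    rng: np.random.Generator,
) -> float | None:
    """Initial temperature giving ~0.5 acceptance of non-improving probes.

    Probes ``t0_probe_count`` alternatives to X0; with d the mean positive
    energy difference, T0 = d / ln 2 solves exp(-d/T0) = 0.5.  Returns the
    floor when every probe improves (or d <= 0), ``None`` when no valid
    alternative to X0 exists at all (the caller regenerates X0).
    """
    e0 = problem.evaluate_cells(x0)
    nr0 = config.nr_at_level(1)
    deltas = []
    found_any = False
    for _ in range(config.t0_probe_count):
        alt = neighbor(x0, nr0, problem, config, rng)
        if alt is None:
            continue
        found_any = True
        deltas.append(problem.evaluate_cells(alt) - e0)
    if not found_any:
        return None
    positive = [d for d in deltas if d > 0]
    if not positive:
        return config.t0_floor
    t0 = float(np.mean(positive)) / math.log(2.0)
    return t0 if t0 > 0 else config.t0_floor


@dataclass
class SAResult:
    best_cells: np.ndarray
    best_e: float
    trace: pd.DataFrame
    status: str              # "converged", "levels_exhausted", "neighbor_exhausted"
    n_levels: int
    acceptance_log: list = field(default_factory=list)

    def cross_matrix(self, problem: MateSelectionProblem) -> CrossMatrix:
        return problem.cross_matrix(self.best_cells)


def anneal(
    problem: MateSelectionProblem,
    config: SAConfig,
    rng: np.random.Generator,
) -> SAResult:
    """One annealing run from a random initial solution.

    Metropolis acceptance (DELTA_E < 0 always accepted, otherwise with
    probability exp(-DELTA_E / T), so DELTA_E = 0 is accepted); the
    temperature drops by the cooling factor when ``n2`` iterations or
    ``n_m`` acceptances are reached at the current level; the run converges
    when a level ends with zero acceptances, stops on neighbourhood
    exhaustion, or after ``n1`` reductions.
    """
    x0 = None
    t0 = None
    for _ in range(config.x0_retry_cap):
        x0 = initial_solution(problem, config, rng)
        t0 = calibrate_T0(x0, problem, config, rng)
        if t0 is not None:
            break
    if t0 is None:
        raise RestartAborted(
            f"no valid alternative to X0 over {config.x0_retry_cap} regenerations"
        )
    current = x0
    e_cur = problem.evaluate_cells(current)
    # X0 is exempt from constraint (iii); the best-ever solution is tracked
    # over constraint-satisfying solutions only, falling back to X0 when
    # nothing feasible was ever accepted
    best, e_best = (current, e_cur) if problem.feasible(current) else (None, math.inf)
    temp = t0
    trace_rows = []
    accept_log: list[np.ndarray] = []
    status = "levels_exhausted"
    n_levels = 0
    for level in range(1, config.n1 + 1):
        n_levels = level
        nr = config.nr_at_level(level)
        n_accept = 0
        stop = False
        for _ in range(config.n2):
            alt = neighbor(current, nr, problem, config, rng)
            if alt is None:
                status = "neighbor_exhausted"
                stop = True
                break
            delta = problem.evaluate_cells(alt) - e_cur
            if delta < 0 or rng.random() < math.exp(-min(delta / temp, 700.0)):
                current, e_cur = alt, e_cur + delta
                n_accept += 1
                accept_log.append(current)
                if e_cur < e_best:
                    best, e_best = current, e_cur
                if n_accept >= config.n_m:
                    break
        trace_rows.append(
            {
                "level": level,
                "temperature": temp,
                "nr": nr,
                "n_accepted": n_accept,
                "e_current": e_cur,
                "e_best": e_best,
            }
        )
        if stop:
            break
        if n_accept == 0:
            status = "converged"
            break
        temp *= config.cooling_factor
    if best is None:
        best, e_best = current, e_cur
    return SAResult(
        best_cells=np.asarray(best),
        best_e=float(e_best),
        trace=pd.DataFrame(trace_rows),
        status=status,
        n_levels=n_levels,
        acceptance_log=accept_log,
    )


def parallel_restarts(
    problem: MateSelectionProblem,
    config: SAConfig,
    seed,
    k: int | None = None,
    n_jobs: int = 1,
) -> tuple[SAResult, list[SAResult]]:
    """Best solution over k independent restarts.

    Restart seeds are spawned deterministically from ``seed`` by a
    counter-based scheme, so the winner is independent of scheduling and of
    the degree of parallelism.  Aborted restarts are skipped; all aborting
    is an error.
    """
    k = k if k is not None else config.n_restarts
    if k < 1:
        raise ValueError("need at least one restart")
    seeds = np.random.SeedSequence(seed).spawn(k)

    def _run(ss):
        try:
            return anneal(problem, config, np.random.default_rng(ss))
        except RestartAborted:
            return None

    if n_jobs == 1:
        results = [_run(ss) for ss in seeds]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(_run)(ss) for ss in seeds)
    ok = [r for r in results if r is not None]
    if not ok:
        raise RestartAborted("all restarts aborted")
    best = min(ok, key=lambda r: (r.best_e,))
    return best, ok
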