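"""Selection and mating: ranking, random incomplete diallels, rule-based
inbreeding management, and solution statistics.

A mating design over a candidate set is the upper triangle plus diagonal of
a 0/1 matrix X: cell (i, j) with j >= i is one cross, the diagonal holds
selfings, reciprocals are excluded.  The conventional method selects the
top-ranked individuals and mates them at random with a fixed number of
mating slots per parent (a selfing consumes two of its parent's slots, so
that 2 * n_crosses = n_selected * slots_per_parent stays consistent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InfeasibleDesignError(RuntimeError):
    """No valid mating design exists (or was found) under the constraints."""


@dataclass
class CrossMatrix:
    """A mating design: candidate ids plus the set cells of the upper triangle.

    ``cells`` holds (i, j) index pairs into ``ids`` with j >= i; the diagonal
    marks selfings.
    """

    ids: np.ndarray                       # candidate ids, fixed order
    cells: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.cells = [(int(i), int(j)) for i, j in self.cells]

    @property
    def n_cross(self) -> int:
        return len(self.cells)

    @property
    def n_candidates(self) -> int:
        return self.ids.size

    def involved_indices(self) -> np.ndarray:
        """Indices of individuals appearing in at least one cross."""
        return np.unique([k for c in self.cells for k in c])

    def cross_counts(self) -> dict[int, int]:
        """Number of crosses each involved individual appears in (a selfing counts once)."""
        counts: dict[int, int] = {}
        for i, j in self.cells:
            counts[i] = counts.get(i, 0) + 1
            if j != i:
                counts[j] = counts.get(j, 0) + 1
        return counts

    def slot_counts(self) -> dict[int, int]:
        """Mating slots used per individual (a selfing uses two)."""
        counts: dict[int, int] = {}
        for i, j in self.cells:
            counts[i] = counts.get(i, 0) + 1
            counts[j] = counts.get(j, 0) + 1
        return counts

    def n_selfings(self) -> int:
        return sum(1 for i, j in self.cells if i == j)

    def dense(self) -> np.ndarray:
        X = np.zeros((self.n_candidates, self.n_candidates), dtype=np.int8)
        for i, j in self.cells:
            X[i, j] = 1
        return X

    def to_edge_list(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mother_id": [int(self.ids[i]) for i, _ in self.cells],
                "father_id": [int(self.ids[j]) for _, j in self.cells],
                "is_selfing": [i == j for i, j in self.cells],
            }
        )

    def validate(
        self,
        n_cross: int | None = None,
        n_selected: int | None = None,
        allow_selfing: bool = True,
    ) -> None:
        """Structural invariants shared by every mating method."""
        seen = set()
        for i, j in self.cells:
            if not (0 <= i <= j < self.n_candidates):
                raise InfeasibleDesignError(f"cell ({i},{j}) outside upper triangle")
            if (i, j) in seen:
                raise InfeasibleDesignError(f"cell ({i},{j}) set twice")
            if i == j and not allow_selfing:
                raise InfeasibleDesignError(f"selfing ({i},{i}) not allowed")
            seen.add((i, j))
        if n_cross is not None and self.n_cross != n_cross:
            raise InfeasibleDesignError(
                f"{self.n_cross} crosses set, expected {n_cross}"
            )
        if n_selected is not None and self.involved_indices().size != n_selected:
            raise InfeasibleDesignError(
                f"{self.involved_indices().size} individuals involved, expected {n_selected}"
            )


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


def rank_candidates(ebvs: pd.DataFrame, partner_mean_g: tuple[float, float]) -> pd.DataFrame:
    """Rank candidates by expected hybrid bunch production.

    score_i = (g_i(BN) + mean_partner(BN)) * (g_i(BW) + mean_partner(BW));
    descending, rank 1 is best, ties broken by ascending id for determinism.
    Returns the table sorted by rank with 'score' and 'rank' columns.
    """
    gp_bn, gp_bw = partner_mean_g
    tab = ebvs.copy()
    tab["score"] = (tab["g_bn"] + gp_bn) * (tab["g_bw"] + gp_bw)
    tab = tab.sort_values(
        ["score", "individual_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab


def partner_population_mean(ebvs: pd.DataFrame) -> tuple[float, float]:
    return float(ebvs["g_bn"].mean()), float(ebvs["g_bw"].mean())


# ---------------------------------------------------------------------------
# Random incomplete diallel with fixed parent degree
# ---------------------------------------------------------------------------


def _random_design_cells(
    n_parents: int,
    n_cross: int,
    slots_per_parent: int,
    allow_selfing: bool,
    rng: np.random.Generator,
    max_restarts: int = 10_000,
) -> list[tuple[int, int]]:
    """Uniform-ish random design by sequential cell sampling with restarts.

    Each step draws uniformly among the currently feasible cells (unused,
    both parents with free slots; a selfing needs two free slots in one
    parent).  Dead ends trigger a restart.
    """
    if 2 * n_cross != n_parents * slots_per_parent:
        raise InfeasibleDesignError(
            f"2*{n_cross} crosses != {n_parents} parents x {slots_per_parent} slots"
        )
    iu, ju = np.triu_indices(n_parents, k=0 if allow_selfing else 1)
    n_cells = iu.size
    for _ in range(max_restarts):
        slots = np.full(n_parents, slots_per_parent)
        used = np.zeros(n_cells, dtype=bool)
        cells: list[tuple[int, int]] = []
        ok = True
        for _ in range(n_cross):
            need = np.where(iu == ju, 2, 1)  # a selfing takes 2 of one parent's slots
            feasible = ~used & (slots[iu] >= need) & (slots[ju] >= need)
            idx = np.flatnonzero(feasible)
            if idx.size == 0:
                ok = False
                break
            pick = int(rng.choice(idx))
            used[pick] = True
            i, j = int(iu[pick]), int(ju[pick])
            slots[i] -= 1
            slots[j] -= 1
            cells.append((i, j))
        if ok and np.all(slots == 0):
            return cells
    raise InfeasibleDesignError(
        f"no feasible design after {max_restarts} restarts"
    )


def mix_design_cells(
    cells: list[tuple[int, int]],
    allow_selfing: bool,
    rng: np.random.Generator,
    n_steps: int = 200,
) -> list[tuple[int, int]]:
    """Degree-preserving swap chain, uniform over valid designs at stationarity.

    The sequential construction above conditions on reaching a complete
    design, which distorts cell marginals (it over-represents selfings);
    mixing with symmetric degree-preserving 2-cell swaps removes that bias.
    Moves: for two cells sharing no parent, rewire to one of the two
    alternative pairings; for (i,j),(i,l), exchange with the selfing pattern
    (i,i),(j,l) and back.  Proposals are symmetric, so accepting every move
    whose new cells are unused yields the uniform distribution on the
    chain's component (rare all-selfing configurations are isolated).
    """
    current = set(cells)
    cells_list = list(current)
    n_cross = len(cells_list)
    for _ in range(n_steps):
        a, b = rng.choice(n_cross, size=2, replace=False)
        (i, j), (k, l) = cells_list[a], cells_list[b]
        shared = {i, j} & {k, l}
        if len(shared) == 0:
            # 4 distinct parents: one of the two alternative pairings;
            # a selfing (s,s) with a disjoint cross (p,q) rewires to
            # (s,p),(s,q) under either coin outcome (the reverse of the
            # selfing-creating move below)
            if rng.integers(2):
                new_a, new_b = (min(i, k), max(i, k)), (min(j, l), max(j, l))
            else:
                new_a, new_b = (min(i, l), max(i, l)), (min(j, k), max(j, k))
        elif len(shared) == 1 and i != j and k != l:
            # (s,o1),(s,o2) -> (s,s),(o1,o2): the selfing-creating move
            if not allow_selfing:
                continue
            s = shared.pop()
            o1 = j if i == s else i
            o2 = l if k == s else k
            new_a, new_b = (s, s), (min(o1, o2), max(o1, o2))
        else:
            # (s,s),(s,o) has no degree-preserving alternative
            continue
        if new_a == new_b:
            continue
        if (new_a in current and new_a not in (cells_list[a], cells_list[b])) or (
            new_b in current and new_b not in (cells_list[a], cells_list[b])
        ):
            continue
        if not allow_selfing and (new_a[0] == new_a[1] or new_b[0] == new_b[1]):
            continue
        current.discard(cells_list[a])
        current.discard(cells_list[b])
        current.add(new_a)
        current.add(new_b)
        cells_list[a], cells_list[b] = new_a, new_b
    return cells_list


def conventional_mating(
    ranked_ids,
    n_select: int = 16,
    n_cross: int = 32,
    crosses_per_parent: int = 4,
    allow_selfing: bool = True,
    rng: np.random.Generator | None = None,
    uniform: bool = False,
) -> CrossMatrix:
    """Truncation selection plus random mating (the conventional method).

    The top ``n_select`` of ``ranked_ids`` are each given
    ``crosses_per_parent`` mating slots and paired at random into
    ``n_cross`` distinct crosses of the incomplete diallel, selfing
    authorized (consuming two slots) and reciprocals excluded.  The default
    sequential construction slightly over-represents selfings relative to
    the uniform distribution over valid designs (end-of-process slot
    depletion forces some selfings); ``uniform=True`` follows it with a
    degree-preserving swap chain that converges to the uniform law.
    """
    rng = np.random.default_rng(rng)
    ranked_ids = np.asarray(ranked_ids)
    if ranked_ids.size < n_select:
        raise InfeasibleDesignError(
            f"{ranked_ids.size} candidates for {n_select} selections"
        )
    selected = ranked_ids[:n_select]
    cells = _random_design_cells(
        n_select, n_cross, crosses_per_parent, allow_selfing, rng
    )
    if uniform:
        cells = mix_design_cells(cells, allow_selfing, rng)
    X = CrossMatrix(selected, cells)
    X.validate(n_cross=n_cross, n_selected=n_select, allow_selfing=allow_selfing)
    return X


METHODS = (
    "conventional",
    "NoSelf",
    "FS_T1",
    "FS_T3",
    "FS_T1_NoSelf",
    "FS_T3_NoSelf",
)


def full_sib_families(pedigree, ids) -> dict[int, tuple[int, int]]:
    """Family key per individual: the unordered parent pair."""
    fam = {}
    for i in ids:
        m, f = pedigree.parents(int(i))
        fam[int(i)] = (min(m, f), max(m, f))
    return fam


def constrained_mating(
    ranked_ids,
    families: dict[int, tuple[int, int]],
    method: str,
    n_select: int = 16,
    n_cross: int = 32,
    crosses_per_parent: int = 4,
    rng: np.random.Generator | None = None,
) -> CrossMatrix:
    """Simple inbreeding-management variants of the conventional method.

    Selection walks down the ranking, skipping candidates whose full-sib
    family quota (1 for FS_T1, 3 for FS_T3) is exhausted; the *NoSelf
    variants forbid the diagonal during random mating.
    """
    if method not in METHODS or method == "conventional":
        raise ValueError(f"unknown management method {method!r}")
    quota = {"FS_T1": 1, "FS_T3": 3, "FS_T1_NoSelf": 1, "FS_T3_NoSelf": 3}.get(method)
    no_self = method.endswith("NoSelf")
    rng = np.random.default_rng(rng)
    selected: list[int] = []
    per_family: dict[tuple[int, int], int] = {}
    for cand in np.asarray(ranked_ids):
        if len(selected) == n_select:
            break
        if quota is not None:
            key = families[int(cand)]
            if per_family.get(key, 0) >= quota:
                continue
            per_family[key] = per_family.get(key, 0) + 1
        selected.append(int(cand))
    if len(selected) < n_select:
        exhausted = {k: v for k, v in per_family.items()}
        raise InfeasibleDesignError(
            f"only {len(selected)} eligible candidates for {n_select} slots; "
            f"family quotas at cap: {exhausted}"
        )
    cells = _random_design_cells(
        n_select, n_cross, crosses_per_parent, not no_self, rng
    )
    X = CrossMatrix(np.asarray(selected), cells)
    X.validate(n_cross=n_cross, n_selected=n_select, allow_selfing=not no_self)
    return X


# ---------------------------------------------------------------------------
# Solution statistics
# ---------------------------------------------------------------------------


@dataclass
class SolutionStats:
    pct_selfing: float
    ranks_selected: list[int]
    max_rank: int
    min_rank: int
    crosses_per_individual: list[int]
    max_fullsibs_per_family: float
    corr_rank_vs_ncross: float
    mean_rank_selfed: float
    mean_parent_pair_kinship: float

    def as_dict(self) -> dict:
        d = {
            "pct_selfing": self.pct_selfing,
            "max_rank": self.max_rank,
            "min_rank": self.min_rank,
            "max_fullsibs_per_family": self.max_fullsibs_per_family,
            "corr_rank_vs_ncross": self.corr_rank_vs_ncross,
            "mean_rank_selfed": self.mean_rank_selfed,
            "mean_parent_pair_kinship": self.mean_parent_pair_kinship,
        }
        return d


def solution_stats(
    X: CrossMatrix,
    ranked_ids,
    families: dict[int, tuple[int, int]] | None = None,
    kinship=None,
) -> SolutionStats:
    """Breeding characteristics of a selection-and-mating solution.

    Ranks are positions (1-based) in ``ranked_ids``; the rank/cross-count
    correlation is Pearson over the selected individuals (missing when
    fewer than three are selected or either variable is constant).
    """
    rank_of = {int(v): k + 1 for k, v in enumerate(np.asarray(ranked_ids))}
    involved = X.involved_indices()
    sel_ids = [int(X.ids[k]) for k in involved]
    ranks = [rank_of[i] for i in sel_ids]
    counts = X.cross_counts()
    ncross = [counts[k] for k in involved]
    if len(ranks) >= 3 and np.std(ranks) > 0 and np.std(ncross) > 0:
        corr = float(np.corrcoef(ranks, ncross)[0, 1])
    else:
        corr = float("nan")
    selfed_ranks = [rank_of[int(X.ids[i])] for i, j in X.cells if i == j]
    mean_rank_selfed = float(np.mean(selfed_ranks)) if selfed_ranks else float("nan")
    if families is not None:
        fam_counts: dict[tuple[int, int], int] = {}
        for i in sel_ids:
            fam_counts[families[i]] = fam_counts.get(families[i], 0) + 1
        max_fs = float(max(fam_counts.values()))
    else:
        max_fs = float("nan")
    if kinship is not None:
        from .inbreeding import progeny_inbreeding_of_design

        mean_kin = progeny_inbreeding_of_design(X.cells, kinship, ids=X.ids)
    else:
        mean_kin = float("nan")
    return SolutionStats(
        pct_selfing=100.0 * X.n_selfings() / X.n_cross,
        ranks_selected=sorted(ranks),
        max_rank=int(max(ranks)),
        min_rank=int(min(ranks)),
        crosses_per_individual=sorted(ncross, reverse=True),
        max_fullsibs_per_family=max_fs,
        corr_rank_vs_ncross=corr,
        mean_rank_selfed=mean_rank_selfed,
        mean_parent_pair_kinship=float(mean_kin),
    )
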