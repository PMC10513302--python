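"""Deterministic synthetic inputs for tests and for the standalone optimizer.

Everything here is synthetic and generated at run time from a seed: small
hand-checkable pedigrees, enumerable mate-selection instances, and a
family-structured instance that emulates a single La Me generation (EBVs
with heritable full-sib family structure and a matching pedigree-derived
kinship matrix) for exercising the annealer outside the full simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annealing import MateSelectionProblem, SAConfig, ThresholdSpec, compute_threshold, deli_design_stats
from .evaluation import RelationshipMatrix, make_ebv_table
from .genome import Pedigree
from .inbreeding import PedigreeKinship
from .mating import conventional_mating, partner_population_mean, rank_candidates


def make_fixture(kind: str, rng, out_dir=None):
    """Dispatch on fixture kind; optionally write delimited files to ``out_dir``."""
    rng = np.random.default_rng(rng)
    maker = {
        "tiny_pedigree": tiny_pedigree,
        "tiny_sa_instance": lambda r: tiny_sa_instance(r),
        "ebv_table": lambda r: synthetic_ebv_table(20, r),
        "kinship_matrix": lambda r: synthetic_kinship(20, r),
        "ms_instance": lambda r: ms_instance(rng=r),
    }
    if kind not in maker:
        raise ValueError(f"unknown fixture kind {kind!r}")
    obj = maker[kind](rng) if kind != "tiny_pedigree" else tiny_pedigree()
    if out_dir is not None:
        _write(kind, obj, out_dir)
    return obj


def _write(kind, obj, out_dir) -> None:
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "tiny_pedigree":
        obj.to_frame().to_csv(out / "pedigree.csv", index=False)
    elif kind == "ebv_table":
        obj.to_csv(out / "ebvs.csv", index=False)
    elif kind == "kinship_matrix":
        obj.to_frame().to_csv(out / "kinship.csv")
    elif kind in ("tiny_sa_instance", "ms_instance"):
        obj.lame_ebvs.to_csv(out / "lame_ebvs.csv", index=False)
        obj.deli_ebvs.to_csv(out / "deli_ebvs.csv", index=False)
        obj.kinship.to_frame().to_csv(out / "kinship.csv")


def tiny_pedigree() -> Pedigree:
    """Three-generation pedigree with hand-checkable inbreeding.

    Founders 1-4; 5 = 1x2, 6 = 1x2 (full sibs), 7 = 3x4, 8 = 5x6
    (full-sib mating, F = 0.25), 9 = 5x5 (selfing, F = 0.5), 10 = 5x7
    (unrelated parents, F = 0).
    """
    ped = Pedigree.from_records(
        [
            (1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0),
            (5, 1, 2), (6, 1, 2), (7, 3, 4),
            (8, 5, 6), (9, 5, 5), (10, 5, 7),
        ]
    )
    return ped


def synthetic_ebv_table(n: int, rng, mu=(9.9, 5.0), sd=(0.9, 0.5), corr=-0.7) -> pd.DataFrame:
    """EBV table with negatively correlated BN/BW values on the half-scale."""
    cov = np.array(
        [[sd[0] ** 2, corr * sd[0] * sd[1]], [corr * sd[0] * sd[1], sd[1] ** 2]]
    )
    g = rng.multivariate_normal(mu, cov, size=n)
    return make_ebv_table(np.arange(1, n + 1), g[:, 0], g[:, 1], "synthetic")


def synthetic_kinship(n: int, rng, n_families: int = 5) -> RelationshipMatrix:
    """Block kinship: full-sib families (f = 0.25), unrelated across, f_ii = 0.5."""
    fam = rng.integers(n_families, size=n)
    f = np.where(fam[:, None] == fam[None, :], 0.25, 0.0)
    np.fill_diagonal(f, 0.5)
    return RelationshipMatrix(np.arange(1, n + 1), f, "synthetic_kinship")


@dataclass
class SAInstanceFixture:
    """A ready-to-anneal instance plus everything needed to inspect it."""

    problem: MateSelectionProblem
    lame_ebvs: pd.DataFrame
    deli_ebvs: pd.DataFrame
    kinship: RelationshipMatrix      # over all candidates
    ranked_ids: np.ndarray           # all candidates, best first
    config: SAConfig
    threshold: ThresholdSpec | None
    families: dict | None = None


def tiny_sa_instance(rng, bound: float = 0.16) -> SAInstanceFixture:
    """Enumerable instance: 6 candidates in 2 full-sib families, 4 crosses.

    21 upper-triangle cells give C(21, 4) = 5985 designs before the kinship
    constraint; the bound keeps the feasible set in the low thousands so the
    global optimum can be found by exhaustive enumeration.
    """
    n = 6
    lame = synthetic_ebv_table(n, rng)
    fam = np.repeat([0, 1], 3)
    f = np.where(fam[:, None] == fam[None, :], 0.25, 0.0)
    np.fill_diagonal(f, 0.5)
    kin = RelationshipMatrix(lame["individual_id"].to_numpy(), f, "synthetic_kinship")
    deli = synthetic_ebv_table(8, rng, mu=(4.6, 10.3), sd=(0.5, 0.9))
    cfg = SAConfig(
        n_presel=n, n1=40, n2=40, n_m=20, n_cross=4, n_select_init=3,
        nr_schedule=((3, 2),), nr_final=1, n_restarts=32,
    )
    ranked = rank_candidates(lame, partner_population_mean(deli))
    ranked_ids = ranked["individual_id"].to_numpy()
    deli_ranked = rank_candidates(deli, partner_population_mean(lame))
    deli_design = conventional_mating(
        deli_ranked["individual_id"].to_numpy(), 4, 4, 2, True, rng
    )
    da, db, dab = deli_design_stats(deli_design, deli)
    etab = lame.set_index("individual_id")
    problem = MateSelectionProblem(
        ids=ranked_ids,
        g_bn=etab.loc[ranked_ids, "g_bn"].to_numpy(),
        g_bw=etab.loc[ranked_ids, "g_bw"].to_numpy(),
        kinship=kin.submatrix(ranked_ids).values,
        deli_mean_a=da,
        deli_mean_b=db,
        deli_mean_ab=dab,
        bound=bound,
        n_cross=4,
    )
    return SAInstanceFixture(
        problem=problem, lame_ebvs=lame, deli_ebvs=deli, kinship=kin,
        ranked_ids=ranked_ids, config=cfg, threshold=None,
    )


def ms_instance(
    n_candidates: int = 120,
    n_families: int = 32,
    n_base_parents: int = 24,
    n_presel: int = 50,
    c_delta_f: float = 0.25,
    n_select: int = 16,
    n_cross: int = 32,
    rng=None,
) -> SAInstanceFixture:
    """Family-structured single-generation mate-selection instance.

    Emulates a La Me candidate cohort: ``n_families`` full-sib families from
    pairs of a limited base-parent pool (creating full- and half-sib
    structure), EBVs = midparent family value + within-family deviation with
    a negative BN/BW correlation, kinship from the pedigree, and the
    adaptive threshold computed exactly as in a simulation cycle.  The
    within-family deviation is half the family spread, reflecting the
    strong family structure and low within-family variation of these
    highly inbred breeding populations.
    """
    rng = np.random.default_rng(rng)
    ped = Pedigree()
    base = [ped.add_founder() for _ in range(n_base_parents)]
    base_g = {}
    cov = np.array([[0.8**2, -0.7 * 0.8 * 0.45], [-0.7 * 0.8 * 0.45, 0.45**2]])
    for b in base:
        base_g[b] = rng.multivariate_normal([9.9, 5.0], cov)
    fam_parents = []
    for _ in range(n_families):
        m, f = rng.choice(base, size=2, replace=False)
        fam_parents.append((int(m), int(f)))
    sizes = np.full(n_families, n_candidates // n_families)
    sizes[: n_candidates - sizes.sum()] += 1
    cand_ids, g_bn, g_bw, fam_of = [], [], [], {}
    for (m, f), size in zip(fam_parents, sizes):
        mid = 0.5 * (base_g[m] + base_g[f])
        for _ in range(size):
            i = ped.add_offspring(m, f)
            dev = rng.multivariate_normal([0.0, 0.0], cov / 4.0)
            cand_ids.append(i)
            g_bn.append(mid[0] + dev[0])
            g_bw.append(mid[1] + dev[1])
            fam_of[i] = (min(m, f), max(m, f))
    lame = make_ebv_table(cand_ids, g_bn, g_bw, "synthetic")
    deli = synthetic_ebv_table(n_select, rng, mu=(4.6, 10.3), sd=(0.5, 0.9))
    kin = PedigreeKinship(ped).matrix(cand_ids)
    ranked = rank_candidates(lame, partner_population_mean(deli))
    ranked_ids = ranked["individual_id"].to_numpy()
    deli_ranked = rank_candidates(deli, partner_population_mean(lame))
    deli_design = conventional_mating(
        deli_ranked["individual_id"].to_numpy(), n_select, n_cross, 4, True, rng
    )
    da, db, dab = deli_design_stats(deli_design, deli)
    f_n = float(
        np.mean([PedigreeKinship(ped).kinship(*ped.parents(int(i))) for i in cand_ids])
    )
    threshold = compute_threshold(
        np.asarray(cand_ids), kin, ranked_ids, f_n, c_delta_f, rng,
        n_select, n_cross, 4,
    )
    presel = ranked_ids[:n_presel]
    etab = lame.set_index("individual_id")
    problem = MateSelectionProblem(
        ids=presel,
        g_bn=etab.loc[presel, "g_bn"].to_numpy(),
        g_bw=etab.loc[presel, "g_bw"].to_numpy(),
        kinship=kin.submatrix(presel).values,
        deli_mean_a=da,
        deli_mean_b=db,
        deli_mean_ab=dab,
        bound=threshold.bound,
        n_cross=n_cross,
    )
    cfg = SAConfig(n_presel=n_presel, n1=80, n2=50, n_m=30, n_cross=n_cross, n_select_init=n_select)
    return SAInstanceFixture(
        problem=problem, lame_ebvs=lame, deli_ebvs=deli, kinship=kin,
        ranked_ids=ranked_ids, config=cfg, threshold=threshold, families=fam_of,
    )
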