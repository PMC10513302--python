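"""Breeding-scheme orchestration: RRS and RRGS over replicates.

A scenario is a breeding scheme (phenotypic RRS or genomic RRGS), a number
of selection candidates per population, a selection-and-mating method for
the La Me population (the Deli side always uses the conventional method)
and, for mate selection, the inbreeding-threshold coefficient c_dF.

Cycle structure
---------------
RRS: every cycle runs a hybrid progeny test of the candidates (19 years
per cycle); parents are evaluated by pedigree BLUP.  RRGS: progeny tests
run only in the configured cycles (by default the first and third); those
cycles last 19 years, the others 6; all candidates are evaluated by GBLUP
trained on the most recent progeny test.  Four RRS cycles therefore span
76 years and four RRGS cycles 50.

Initial populations
-------------------
Both populations descend from a common finite ancestral population (which
creates LD and divergence-free shared variation); the Deli history is a
4-founder bottleneck expanded over eight generations, the La Me history a
24-founder bottleneck expanded over two, both with mass selection.  The
trait scale is anchored at generation 0 to realistic bunch-number /
bunch-weight means with mirrored profiles, so hybrid heterosis for FFB
emerges from the multiplicative trait alone.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import genome as gn
from . import traits as tr
from . import evaluation as ev
from . import inbreeding as ib
from . import mating as mt
from . import annealing as sa


MS_METHODS = ("MS_0", "MS_25", "MS_50")
ALL_METHODS = mt.METHODS + MS_METHODS


def c_delta_f_of(method: str) -> float:
    return {"MS_0": 0.0, "MS_25": 0.25, "MS_50": 0.5}[method]


@dataclass
class SchemeConfig:
    """Scenario configuration (defaults: desk-scale preset)."""

    scheme: str = "RRGS"             # "RRS" or "RRGS"
    n_candidates: int = 60
    n_selected: int = 8
    n_crosses: int = 16
    crosses_per_parent: int = 4
    n_cycles: int = 2
    gs_pt_cycles: tuple[int, ...] = (1, 3)
    cycle_years_pt: int = 19
    cycle_years_no_pt: int = 6
    # progeny test
    pt_parents: int = 60
    pt_mean_mates: float = 2.1
    pt_progeny_per_cross: int = 10
    # genome / markers
    n_chromosomes: int = 16
    chrom_length_cm: float = 100.0
    n_loci: int = 1200
    n_markers: int = 500
    n_qtl_per_trait: int = 200
    pleiotropy_frac: float = 0.7
    pleiotropy_corr: float = -0.9
    maf_min: float = 0.1
    ld_target_cm: float = 6.0
    ancestral_generations: int | None = None
    # trait anchoring (Deli high-BW/low-BN, La Me the mirror image)
    mean_targets: dict = field(
        default_factory=lambda: {"Deli": (9.22, 20.52), "LaMe": (19.73, 10.07)}
    )
    h2_targets: dict = field(
        default_factory=lambda: {"Deli": (0.54, 0.55), "LaMe": (0.48, 0.47)}
    )
    var_a_target: tuple[float, float] = (2.445, 0.315)
    # mate selection
    sa_config: sa.SAConfig | None = None
    sa_restarts: int = 8
    sa_n_jobs: int = 1
    n_hybrid_ref: int = 200

    def __post_init__(self) -> None:
        if self.scheme not in ("RRS", "RRGS"):
            raise gn.ConfigurationError(f"unknown scheme {self.scheme!r}")
        if self.n_selected * self.crosses_per_parent != 2 * self.n_crosses:
            raise gn.ConfigurationError(
                "need n_selected * crosses_per_parent == 2 * n_crosses"
            )

    def has_progeny_test(self, cycle: int) -> bool:
        return self.scheme == "RRS" or cycle in self.gs_pt_cycles

    def cycle_years(self, cycle: int) -> int:
        return self.cycle_years_pt if self.has_progeny_test(cycle) else self.cycle_years_no_pt

    def total_years(self) -> int:
        return sum(self.cycle_years(c) for c in range(1, self.n_cycles + 1))

    @classmethod
    def desk(cls, **overrides) -> "SchemeConfig":
        """Scaled-down preset: all ratios of the full design preserved."""
        return cls(**overrides)

    @classmethod
    def full_scale(cls, **overrides) -> "SchemeConfig":
        """Full-scale preset (slow; for cluster-style runs)."""
        base = dict(
            n_candidates=120,
            n_selected=16,
            n_crosses=32,
            n_cycles=4,
            pt_parents=120,
            pt_progeny_per_cross=20,
            n_loci=16000,
            n_markers=2250,
            n_qtl_per_trait=800,
            sa_restarts=96,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# Simulation state
# ---------------------------------------------------------------------------


@dataclass
class SimState:
    gmap: gn.GenomeMap
    model: tr.TraitModel
    pedigree: gn.Pedigree
    pops: dict                      # label -> Population (current candidates)
    snp_panel: np.ndarray           # neutral loci polymorphic in initial La Me
    qtl_bn_panel: np.ndarray
    qtl_bw_panel: np.ndarray
    marker_panel: np.ndarray        # neutral loci used for G
    base_freqs: dict                # label -> allele freqs at generation 0
    generation: int = 0
    training: pd.DataFrame | None = None   # most recent progeny test
    training_parents: dict = field(default_factory=lambda: {"Deli": [], "LaMe": []})
    genotype_store: dict = field(default_factory=dict)  # id -> marker dosages

    def clone(self) -> "SimState":
        return copy.deepcopy(self)

    def checksum(self) -> int:
        """Order-sensitive digest of the candidate genotypes (for pairing checks)."""
        import zlib

        h = 0
        for label in sorted(self.pops):
            pop = self.pops[label]
            h = zlib.crc32(pop.ids.tobytes(), h)
            h = zlib.crc32(np.ascontiguousarray(pop.haplotypes).tobytes(), h)
        return h

    def store_genotypes(self, pop: gn.Population) -> None:
        dos = pop.dosages()[:, self.marker_panel]
        for k, i in enumerate(pop.ids):
            self.genotype_store[int(i)] = dos[k]


def initial_state(cfg: SchemeConfig, rng: np.random.Generator) -> SimState:
    """Generate generation-0 Deli and La Me candidate populations."""
    gmap = gn.build_genome_map(
        cfg.n_chromosomes, cfg.chrom_length_cm, cfg.n_loci, 0, rng=rng
    )
    anc_n = max(
        gn.ancestral_size_for_ld(cfg.ld_target_cm),
        gn.DELI_BURN_IN.n_founders + gn.LAME_BURN_IN.n_founders,
    )
    anc_gens = (
        cfg.ancestral_generations if cfg.ancestral_generations is not None else anc_n
    )
    # QTL architecture is defined in the shared ancestral gene pool before
    # drift and the population bottlenecks, so by generation 0 the QTL
    # frequency spectrum has drifted like any other locus (fixation at QTLs
    # included) rather than being conditioned on present-day polymorphism
    anc_base = gn.initial_ancestral_population(gmap, anc_n, rng)
    model = tr.sample_qtl_effects(
        gmap,
        anc_base,
        cfg.n_qtl_per_trait,
        cfg.pleiotropy_frac,
        cfg.pleiotropy_corr,
        cfg.maf_min,
        rng,
    )
    anc = gn.drift(anc_base.haplotypes, gmap, anc_gens, rng)
    pedigree = gn.Pedigree()
    deli_founders = gn.sample_founders(anc, gn.DELI_BURN_IN.n_founders, pedigree, rng, "Deli")
    lame_founders = gn.sample_founders(anc, gn.LAME_BURN_IN.n_founders, pedigree, rng, "LaMe")
    # provisional scale for burn-in mass selection (phenotypes need variances)
    for label, founders in (("Deli", deli_founders), ("LaMe", lame_founders)):
        model.mu[label] = (0.0, 0.0)
        model.h2[label] = cfg.h2_targets[label]
        model.var_a[label] = (
            max(model.tbv(founders, "bn").var(), 1e-9),
            max(model.tbv(founders, "bw").var(), 1e-9),
        )
    deli = gn.run_burn_in(
        gn.DELI_BURN_IN.scaled(cfg.n_candidates),
        deli_founders,
        gmap,
        pedigree,
        rng,
        trait_model=model,
    )
    lame = gn.run_burn_in(
        gn.LAME_BURN_IN.scaled(cfg.n_candidates),
        lame_founders,
        gmap,
        pedigree,
        rng,
        trait_model=model,
    )
    pops = {"Deli": deli, "LaMe": lame}
    model.anchor(pops, cfg.mean_targets, cfg.h2_targets, cfg.var_a_target)
    neutral = gmap.neutral_indices
    # SNP panel: neutral loci polymorphic in the initial La Me population,
    # frozen here and reused for all generations.  QTL homozygosity is
    # measured over ALL QTL loci of the trait: fixation at QTLs is the
    # signal of interest and is not censored by a polymorphism filter.
    snp_panel = ib.polymorphic_panel(lame, neutral)
    qtl_bn_panel = gmap.qtl_indices("bn")
    qtl_bw_panel = gmap.qtl_indices("bw")
    pooled0 = gn.Population(
        "gen0",
        np.concatenate([deli.ids, lame.ids]),
        np.concatenate([deli.haplotypes, lame.haplotypes]),
    )
    p_pool = pooled0.allele_freqs()
    marker_pool = neutral[(p_pool[neutral] > 0) & (p_pool[neutral] < 1)]
    n_mark = min(cfg.n_markers, marker_pool.size)
    marker_panel = np.sort(rng.choice(marker_pool, size=n_mark, replace=False))
    state = SimState(
        gmap=gmap,
        model=model,
        pedigree=pedigree,
        pops=pops,
        snp_panel=snp_panel,
        qtl_bn_panel=qtl_bn_panel,
        qtl_bw_panel=qtl_bw_panel,
        marker_panel=marker_panel,
        base_freqs={
            "Deli": deli.allele_freqs()[marker_panel],
            "LaMe": lame.allele_freqs()[marker_panel],
        },
    )
    state.store_genotypes(deli)
    state.store_genotypes(lame)
    return state


# ---------------------------------------------------------------------------
# Progeny tests and evaluation
# ---------------------------------------------------------------------------


def run_progeny_test(
    state: SimState, cfg: SchemeConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Incomplete factorial hybrid progeny test of the current candidates.

    ``pt_parents`` parents per population are mated across populations with
    ``pt_mean_mates`` mates on average (every parent gets at least one) and
    ``pt_progeny_per_cross`` hybrids per cross are simulated and phenotyped.
    """
    deli = state.pops["Deli"]
    lame = state.pops["LaMe"]
    n_par = min(cfg.pt_parents, deli.size, lame.size)
    d_rows = np.arange(n_par)
    l_rows = np.arange(n_par)
    n_crosses = int(round(n_par * cfg.pt_mean_mates))
    pairs: set[tuple[int, int]] = set()
    perm = rng.permutation(l_rows)
    for k in range(n_par):  # coverage: every parent in at least one cross
        pairs.add((int(d_rows[k]), int(perm[k])))
    cap = n_par * n_par
    while len(pairs) < min(n_crosses, cap):
        pairs.add((int(rng.integers(n_par)), int(rng.integers(n_par))))
    pair_list = sorted(pairs)
    n_off = cfg.pt_progeny_per_cross
    n_hyb = len(pair_list) * n_off
    haplos = np.empty((n_hyb, 2, state.gmap.n_loci), dtype=np.int8)
    parent_a = np.empty(n_hyb, dtype=np.int64)
    parent_b = np.empty(n_hyb, dtype=np.int64)
    k = 0
    for dr, lr in pair_list:
        for _ in range(n_off):
            haplos[k, 0] = gn.meiosis(deli.haplotypes[dr], state.gmap, rng)
            haplos[k, 1] = gn.meiosis(lame.haplotypes[lr], state.gmap, rng)
            parent_a[k] = deli.ids[dr]
            parent_b[k] = lame.ids[lr]
            k += 1
    hybrids = gn.Population("Hybrid", np.arange(n_hyb), haplos, state.generation)
    phen = state.model.phenotypes(hybrids, rng, label="Hybrid")
    phen["parent_a"] = parent_a
    phen["parent_b"] = parent_b
    return phen


def evaluate_candidates(
    state: SimState, cfg: SchemeConfig, rng: np.random.Generator
) -> dict:
    """(G)EBV tables for the current candidates of both populations.

    RRS: pedigree BLUP of the progeny-tested parents on the numerator
    relationship matrix.  RRGS: GBLUP on VanRaden G matrices spanning the
    training parents and the current (possibly untested) candidates.
    Returns {"Deli": table, "LaMe": table, "fits": fits, "G": optional}.
    """
    vc = ev.components_from_model(state.model, "Deli", "LaMe")
    if state.training is None:
        raise RuntimeError("no progeny test available for evaluation")
    if cfg.scheme == "RRS":
        K = {
            label: ev.build_A(state.pedigree, ids=state.pops[label].ids)
            for label in ("Deli", "LaMe")
        }
        tab_a, tab_b, fits = ev.fit_progeny_test_blup(
            state.training, K["Deli"], K["LaMe"], vc
        )
        return {"Deli": tab_a, "LaMe": tab_b, "fits": fits, "G": None}
    G = {}
    for label in ("Deli", "LaMe"):
        cand_ids = [int(i) for i in state.pops[label].ids]
        train_ids = [i for i in state.training_parents[label] if i not in set(cand_ids)]
        ids = train_ids + cand_ids
        dosages = np.stack([state.genotype_store[i] for i in ids])
        G[label] = ev.build_G(ids, dosages, state.base_freqs[label])
    tab_a, tab_b, fits = ev.fit_gblup(state.training, G["Deli"], G["LaMe"], vc)
    tab_a = tab_a[tab_a["individual_id"].isin(state.pops["Deli"].ids)].reset_index(drop=True)
    tab_b = tab_b[tab_b["individual_id"].isin(state.pops["LaMe"].ids)].reset_index(drop=True)
    return {"Deli": tab_a, "LaMe": tab_b, "fits": fits, "G": G}


# ---------------------------------------------------------------------------
# Selection and mating dispatch
# ---------------------------------------------------------------------------


def candidate_kinship(state: SimState, cfg: SchemeConfig, label: str, G=None):
    """Coancestry matrix of the current candidates on the scheme's basis."""
    ids = state.pops[label].ids
    if cfg.scheme == "RRS":
        return ib.PedigreeKinship(state.pedigree).matrix(ids)
    return ib.kinship_matrix_from_G(G[label].submatrix(ids))


def candidate_mean_inbreeding(state: SimState, cfg: SchemeConfig, label: str, G=None) -> float:
    """F(n): mean genealogical F (RRS) or mean diag(G) - 1 (RRGS)."""
    ids = state.pops[label].ids
    if cfg.scheme == "RRS":
        return float(ib.genealogical_inbreeding(state.pedigree, ids).mean())
    return float(G[label].submatrix(ids).diagonal().mean() - 1.0)


def select_and_mate(
    state: SimState,
    cfg: SchemeConfig,
    method: str,
    ebvs: dict,
    rng: np.random.Generator,
) -> dict:
    """Apply the configured method in La Me and the conventional method in Deli.

    Returns the two designs, the La Me ranking and (for MS) the threshold
    and annealing result.
    """
    ranked = {}
    for label, other in (("Deli", "LaMe"), ("LaMe", "Deli")):
        ranked[label] = mt.rank_candidates(
            ebvs[label], mt.partner_population_mean(ebvs[other])
        )
    deli_design = mt.conventional_mating(
        ranked["Deli"]["individual_id"].to_numpy(),
        cfg.n_selected,
        cfg.n_crosses,
        cfg.crosses_per_parent,
        True,
        rng,
    )
    lame_ranked_ids = ranked["LaMe"]["individual_id"].to_numpy()
    out = {"deli_design": deli_design, "ranked": ranked, "threshold": None, "sa_result": None}
    if method == "conventional":
        out["lame_design"] = mt.conventional_mating(
            lame_ranked_ids, cfg.n_selected, cfg.n_crosses, cfg.crosses_per_parent, True, rng
        )
    elif method in mt.METHODS:
        fams = mt.full_sib_families(state.pedigree, lame_ranked_ids)
        out["lame_design"] = mt.constrained_mating(
            lame_ranked_ids, fams, method, cfg.n_selected, cfg.n_crosses,
            cfg.crosses_per_parent, rng,
        )
    elif method in MS_METHODS:
        G = ebvs.get("G")
        kin_all = candidate_kinship(state, cfg, "LaMe", G)
        f_n = candidate_mean_inbreeding(state, cfg, "LaMe", G)
        threshold = sa.compute_threshold(
            state.pops["LaMe"].ids,
            kin_all,
            lame_ranked_ids,
            f_n,
            c_delta_f_of(method),
            rng,
            cfg.n_selected,
            cfg.n_crosses,
            cfg.crosses_per_parent,
        )
        sa_cfg = cfg.sa_config or sa.SAConfig.preset_120()
        sa_cfg = replace(
            sa_cfg,
            n_cross=cfg.n_crosses,
            n_select_init=cfg.n_selected,
            n_presel=min(sa_cfg.n_presel, len(lame_ranked_ids)),
        )
        presel_ids = lame_ranked_ids[: sa_cfg.n_presel]
        etab = ebvs["LaMe"].set_index("individual_id")
        da, db, dab = sa.deli_design_stats(deli_design, ebvs["Deli"])
        problem = sa.MateSelectionProblem(
            ids=presel_ids,
            g_bn=etab.loc[presel_ids, "g_bn"].to_numpy(),
            g_bw=etab.loc[presel_ids, "g_bw"].to_numpy(),
            kinship=kin_all.submatrix(presel_ids).values,
            deli_mean_a=da,
            deli_mean_b=db,
            deli_mean_ab=dab,
            bound=threshold.bound,
            n_cross=cfg.n_crosses,
        )
        seed = int(rng.integers(2**31 - 1))
        best, _ = sa.parallel_restarts(
            problem, sa_cfg, seed, k=cfg.sa_restarts, n_jobs=cfg.sa_n_jobs
        )
        out["lame_design"] = best.cross_matrix(problem)
        out["threshold"] = threshold
        out["sa_result"] = best
    else:
        raise ValueError(f"unknown method {method!r}")
    out["kinship_lame"] = (
        candidate_kinship(state, cfg, "LaMe", ebvs.get("G"))
        if method not in MS_METHODS
        else kin_all
    )
    return out


def advance_generation(
    state: SimState,
    cfg: SchemeConfig,
    designs: dict,
    rng: np.random.Generator,
) -> None:
    """Produce the next candidate cohorts from the two mating designs.

    Progeny are allocated to crosses as evenly as possible (floor/ceil of
    candidates per cross).
    """
    for label, key in (("Deli", "deli_design"), ("LaMe", "lame_design")):
        design: mt.CrossMatrix = designs[key]
        pop = state.pops[label]
        counts = _balanced_allocation(cfg.n_candidates, design.n_cross)
        pairs = []
        for (ci, cj), c in zip(design.cells, counts):
            mrow = pop.index_of(int(design.ids[ci]))
            frow = pop.index_of(int(design.ids[cj]))
            pairs.extend([(mrow, frow)] * c)
        state.pops[label] = gn.make_offspring_population(
            pairs, pop, state.gmap, state.pedigree, rng,
            generation=state.generation + 1, label=label,
        )
    state.generation += 1
    if cfg.scheme == "RRGS":
        for label in ("Deli", "LaMe"):
            state.store_genotypes(state.pops[label])


def _balanced_allocation(total: int, n_bins: int) -> np.ndarray:
    base = total // n_bins
    out = np.full(n_bins, base, dtype=int)
    out[: total - base * n_bins] += 1
    return out


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------


def hybrid_reference_ffb(state: SimState, cfg: SchemeConfig, rng: np.random.Generator) -> float:
    """Mean genetic FFB of random Deli x La Me hybrids of the current candidates."""
    deli = state.pops["Deli"]
    lame = state.pops["LaMe"]
    n = cfg.n_hybrid_ref
    haplos = np.empty((n, 2, state.gmap.n_loci), dtype=np.int8)
    for k in range(n):
        dr = int(rng.integers(deli.size))
        lr = int(rng.integers(lame.size))
        haplos[k, 0] = gn.meiosis(deli.haplotypes[dr], state.gmap, rng)
        haplos[k, 1] = gn.meiosis(lame.haplotypes[lr], state.gmap, rng)
    hybrids = gn.Population("Hybrid", np.arange(n), haplos)
    _, _, ffb = state.model.genetic_values(hybrids, label="Hybrid")
    return float(ffb.mean())


def genetic_progress(ffb_end: float, ffb_start: float) -> float:
    """100 x (FFB_end - FFB_start) / FFB_start."""
    if ffb_start == 0:
        raise ValueError("reference FFB is zero")
    return 100.0 * (ffb_end - ffb_start) / ffb_start


def measure_generation(
    state: SimState, cfg: SchemeConfig, rng: np.random.Generator
) -> dict:
    rep = ib.population_inbreeding(
        state.pops["LaMe"], state.pedigree,
        state.snp_panel, state.qtl_bn_panel, state.qtl_bw_panel,
    )
    row = rep.as_dict()
    row["ffb_hybrid"] = hybrid_reference_ffb(state, cfg, rng)
    return row


# ---------------------------------------------------------------------------
# Scheme and scenario runners
# ---------------------------------------------------------------------------


def run_scheme(
    state: SimState,
    cfg: SchemeConfig,
    method: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Run all cycles of one scheme on (and mutating) ``state``.

    Returns one row per generation 0..n_cycles with inbreeding aggregates,
    the hybrid FFB reference, elapsed years and (for generations produced
    by a recorded design) the solution statistics of the La Me design.
    """
    rows = []
    row0 = measure_generation(state, cfg, rng)
    row0.update({"generation": 0, "years": 0})
    rows.append(row0)
    years = 0
    for cycle in range(1, cfg.n_cycles + 1):
        if cfg.has_progeny_test(cycle):
            state.training = run_progeny_test(state, cfg, rng)
            state.training_parents = {
                "Deli": sorted(set(int(i) for i in state.training["parent_a"])),
                "LaMe": sorted(set(int(i) for i in state.training["parent_b"])),
            }
        ebvs = evaluate_candidates(state, cfg, rng)
        designs = select_and_mate(state, cfg, method, ebvs, rng)
        fams = mt.full_sib_families(
            state.pedigree, designs["ranked"]["LaMe"]["individual_id"].to_numpy()
        )
        stats = mt.solution_stats(
            designs["lame_design"],
            designs["ranked"]["LaMe"]["individual_id"].to_numpy(),
            families=fams,
            kinship=designs["kinship_lame"],
        )
        advance_generation(state, cfg, designs, rng)
        years += cfg.cycle_years(cycle)
        row = measure_generation(state, cfg, rng)
        row.update({"generation": cycle, "years": years})
        row.update(stats.as_dict())
        rows.append(row)
    out = pd.DataFrame(rows)
    out.insert(0, "method", method)
    out.insert(0, "scheme", cfg.scheme)
    return out


@dataclass
class RunResult:
    """Tidy per-generation results of a scenario grid run."""

    generations: pd.DataFrame

    def progress_summary(self) -> pd.DataFrame:
        """Genetic progress (total and annual %) per replicate x scheme x method."""
        rows = []
        gb = self.generations.groupby(["replicate", "scheme", "method"], sort=False)
        for (rep, scheme, method), grp in gb:
            grp = grp.sort_values("generation")
            f0 = grp.iloc[0]["ffb_hybrid"]
            fe = grp.iloc[-1]["ffb_hybrid"]
            yrs = grp.iloc[-1]["years"]
            pct = genetic_progress(fe, f0)
            rows.append(
                {
                    "replicate": rep,
                    "scheme": scheme,
                    "method": method,
                    "progress_pct": pct,
                    "years": yrs,
                    "annual_progress_pct": pct / yrs if yrs else float("nan"),
                    "final_F_snp": grp.iloc[-1]["F_snp"],
                    "final_F_pedigree": grp.iloc[-1]["F_pedigree"],
                    "delta_F_snp": grp.iloc[-1]["F_snp"] - grp.iloc[0]["F_snp"],
                    "delta_F_pedigree": grp.iloc[-1]["F_pedigree"]
                    - grp.iloc[0]["F_pedigree"],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.generations.to_csv(path, index=False)


def run_scenario(
    cfg: SchemeConfig,
    methods,
    n_replicates: int,
    master_seed: int,
) -> RunResult:
    """Replicated scenario run with paired initial populations.

    Each replicate generates one set of initial populations; every method
    starts from a clone of that exact state, so method comparisons within a
    replicate are paired.  Failures of individual method runs are recorded
    and excluded.
    """
    frames = []
    failures = []
    root = np.random.SeedSequence(master_seed)
    rep_seeds = root.spawn(n_replicates)
    for rep, rep_ss in enumerate(rep_seeds):
        init_ss, *method_ss = rep_ss.spawn(1 + len(methods))
        state0 = initial_state(cfg, np.random.default_rng(init_ss))
        for method, mss in zip(methods, method_ss):
            state = state0.clone()
            try:
                df = run_scheme(state, cfg, method, np.random.default_rng(mss))
            except Exception as exc:  # noqa: BLE001 - per-replicate isolation
                failures.append((rep, method, repr(exc)))
                continue
            df.insert(0, "replicate", rep)
            frames.append(df)
    if not frames:
        raise RuntimeError(f"all runs failed: {failures}")
    result = RunResult(pd.concat(frames, ignore_index=True))
    result.failures = failures
    return result
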