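"""Genome simulation: maps, haplotypes, meiosis, crossing and founder histories.

The simulator is forward-in-time and individual-based.  Loci are biallelic
(0/1), placed on a genetic map in centimorgans, and there is no mutation:
every allele segregating in any generation is present in the founders.
Linkage disequilibrium in the founders is created mechanistically, by
simulating a finite random-mating ancestral population (drift + linkage)
and sampling founders from it, mimicking the historical bottlenecks at the
origin of the two breeding populations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

# Locus classes
NEUTRAL = 0
QTL_BN = 1
QTL_BW = 2
QTL_PLEIO = 3

_QTL_CLASSES = (QTL_BN, QTL_BW, QTL_PLEIO)

UNKNOWN = 0  # parent id meaning "founder / unknown"


class ConfigurationError(ValueError):
    """Raised when a map or scheme configuration is internally inconsistent."""


@dataclass
class GenomeMap:
    """Genetic map: chromosome assignment, cM positions and locus classes.

    Positions are strictly increasing within each chromosome.  ``locus_class``
    starts out ``NEUTRAL`` everywhere unless QTLs were requested at build
    time; :func:`palmbreed.traits.sample_qtl_effects` may re-assign QTL
    classes subject to a founder minor-allele-frequency filter.
    """

    chrom: np.ndarray          # (L,) int, chromosome index per locus
    pos_cm: np.ndarray         # (L,) float, position within chromosome
    locus_class: np.ndarray    # (L,) int8
    chrom_lengths: np.ndarray  # (n_chrom,) float, cM

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos_cm = np.asarray(self.pos_cm, dtype=np.float64)
        self.locus_class = np.asarray(self.locus_class, dtype=np.int8)
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=np.float64)
        for c in range(self.n_chromosomes):
            p = self.pos_cm[self.chrom == c]
            if p.size and np.any(np.diff(p) <= 0):
                raise ConfigurationError(
                    f"locus positions not strictly increasing on chromosome {c}"
                )

    @property
    def n_loci(self) -> int:
        return self.chrom.size

    @property
    def n_chromosomes(self) -> int:
        return self.chrom_lengths.size

    def chrom_indices(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.chrom == c)

    def qtl_indices(self, trait: str) -> np.ndarray:
        """Indices of loci affecting ``trait`` ('bn' or 'bw'), pleiotropic included."""
        if trait == "bn":
            mask = (self.locus_class == QTL_BN) | (self.locus_class == QTL_PLEIO)
        elif trait == "bw":
            mask = (self.locus_class == QTL_BW) | (self.locus_class == QTL_PLEIO)
        else:
            raise ValueError(f"unknown trait {trait!r}")
        return np.flatnonzero(mask)

    @property
    def neutral_indices(self) -> np.ndarray:
        return np.flatnonzero(self.locus_class == NEUTRAL)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "locus_id": np.arange(self.n_loci),
                "cM": self.pos_cm,
                "class": self.locus_class,
            }
        )


def build_genome_map(
    n_chromosomes: int = 16,
    chrom_length_cm: float = 100.0,
    n_loci: int = 2000,
    n_qtl_per_trait: int = 0,
    pleiotropy_frac: float = 0.7,
    rng: np.random.Generator | None = None,
) -> GenomeMap:
    """Build a genome map with uniformly placed loci and optional QTL classes.

    With ``n_qtl_per_trait = q`` and pleiotropy fraction ``w``, ``round(w*q)``
    loci are pleiotropic and ``q - round(w*q)`` loci are private to each trait,
    so each trait is controlled by exactly ``q`` loci.
    """
    rng = np.random.default_rng(rng)
    if n_chromosomes < 1 or chrom_length_cm <= 0 or n_loci < 1:
        raise ConfigurationError("need n_chromosomes >= 1, length > 0, n_loci >= 1")
    n_pleio = int(round(pleiotropy_frac * n_qtl_per_trait))
    n_private = n_qtl_per_trait - n_pleio
    n_qtl_loci = n_pleio + 2 * n_private
    if n_qtl_loci > n_loci:
        raise ConfigurationError(
            f"{n_qtl_loci} QTL loci requested but map has only {n_loci} loci"
        )
    # spread loci over chromosomes as evenly as possible
    per_chrom = np.full(n_chromosomes, n_loci // n_chromosomes, dtype=int)
    per_chrom[: n_loci % n_chromosomes] += 1
    chrom = np.repeat(np.arange(n_chromosomes), per_chrom)
    pos = np.concatenate(
        [np.sort(rng.uniform(0.0, chrom_length_cm, size=k)) for k in per_chrom]
    )
    # enforce strict increase in the (measure-zero) event of ties
    for c in range(n_chromosomes):
        idx = np.flatnonzero(chrom == c)
        p = pos[idx]
        dup = np.flatnonzero(np.diff(p) <= 0)
        while dup.size:
            p[dup + 1] = np.nextafter(p[dup], np.inf)
            dup = np.flatnonzero(np.diff(p) <= 0)
        pos[idx] = p
    locus_class = np.zeros(n_loci, dtype=np.int8)
    if n_qtl_loci:
        chosen = rng.choice(n_loci, size=n_qtl_loci, replace=False)
        locus_class[chosen[:n_pleio]] = QTL_PLEIO
        locus_class[chosen[n_pleio : n_pleio + n_private]] = QTL_BN
        locus_class[chosen[n_pleio + n_private :]] = QTL_BW
    return GenomeMap(chrom, pos, locus_class, np.full(n_chromosomes, chrom_length_cm))


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


class Pedigree:
    """Ordered pedigree records (id, mother, father); 0 means unknown.

    Parents must be recorded before their offspring; the structure is acyclic
    by construction.  Used both for genealogical inbreeding and for the
    numerator relationship matrix.
    """

    def __init__(self) -> None:
        self._order: list[int] = []
        self._parents: dict[int, tuple[int, int]] = {}
        self._next_id = itertools.count(1)

    def new_id(self) -> int:
        return next(self._next_id)

    def add(self, ind_id: int, mother: int, father: int) -> None:
        if ind_id in self._parents:
            raise ValueError(f"duplicate pedigree id {ind_id}")
        for p in (mother, father):
            if p != UNKNOWN and p not in self._parents:
                raise ValueError(f"parent {p} of {ind_id} not in pedigree")
        self._order.append(ind_id)
        self._parents[ind_id] = (mother, father)

    def add_founder(self) -> int:
        i = self.new_id()
        self.add(i, UNKNOWN, UNKNOWN)
        return i

    def add_offspring(self, mother: int, father: int) -> int:
        i = self.new_id()
        self.add(i, mother, father)
        return i

    def parents(self, ind_id: int) -> tuple[int, int]:
        return self._parents[ind_id]

    def __contains__(self, ind_id: int) -> bool:
        return ind_id in self._parents

    def __len__(self) -> int:
        return len(self._order)

    @property
    def ids(self) -> list[int]:
        return list(self._order)

    def is_topologically_ordered(self) -> bool:
        seen: set[int] = set()
        for i in self._order:
            m, f = self._parents[i]
            if (m != UNKNOWN and m not in seen) or (f != UNKNOWN and f not in seen):
                return False
            seen.add(i)
        return True

    def depth(self, ind_id: int) -> int:
        """Number of ancestral generations behind ``ind_id`` (founder = 0)."""
        m, f = self._parents[ind_id]
        if m == UNKNOWN and f == UNKNOWN:
            return 0
        return 1 + max(
            self.depth(m) if m != UNKNOWN else -1,
            self.depth(f) if f != UNKNOWN else -1,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": self._order,
                "mother": [self._parents[i][0] for i in self._order],
                "father": [self._parents[i][1] for i in self._order],
            }
        )

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from an iterable of (id, mother, father) triples."""
        ped = cls()
        mx = 0
        for i, m, f in records:
            ped.add(int(i), int(m), int(f))
            mx = max(mx, int(i))
        ped._next_id = itertools.count(mx + 1)
        return ped


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------


@dataclass
class Population:
    """A cohort of diploid individuals of one breeding population.

    ``haplotypes`` has shape (n, 2, L) with 0/1 alleles; ``ids`` index into
    the shared :class:`Pedigree`.
    """

    label: str                 # "Deli", "LaMe", "Hybrid", ...
    ids: np.ndarray            # (n,) int64
    haplotypes: np.ndarray     # (n, 2, L) int8
    generation: int = 0

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)

    @property
    def size(self) -> int:
        return self.ids.size

    def dosages(self) -> np.ndarray:
        """(n, L) allele-1 dosage matrix (0/1/2)."""
        return self.haplotypes.sum(axis=1, dtype=np.int16)

    def allele_freqs(self) -> np.ndarray:
        return self.dosages().mean(axis=0) / 2.0

    def index_of(self, ind_id: int) -> int:
        pos = np.flatnonzero(self.ids == ind_id)
        if pos.size == 0:
            raise KeyError(f"id {ind_id} not in population {self.label}")
        return int(pos[0])

    def subset(self, idx) -> "Population":
        return Population(self.label, self.ids[idx], self.haplotypes[idx], self.generation)

    def copy(self) -> "Population":
        return Population(self.label, self.ids.copy(), self.haplotypes.copy(), self.generation)


# ---------------------------------------------------------------------------
# Meiosis and crossing
# ---------------------------------------------------------------------------


def meiosis(parent_haplos: np.ndarray, gmap: GenomeMap, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a (2, L) parent under Haldane's model.

    Crossover counts per chromosome are Poisson(length/100) with uniform
    positions and no interference; the starting strand is chosen at random
    per chromosome.
    """
    gamete = np.empty(gmap.n_loci, dtype=np.int8)
    for c in range(gmap.n_chromosomes):
        idx = gmap.chrom_indices(c)
        if idx.size == 0:
            continue
        length = gmap.chrom_lengths[c]
        n_co = rng.poisson(length / 100.0)
        start = rng.integers(2)
        if n_co == 0:
            gamete[idx] = parent_haplos[start, idx]
            continue
        xo = np.sort(rng.uniform(0.0, length, size=n_co))
        phase = (start + np.searchsorted(xo, gmap.pos_cm[idx], side="right")) % 2
        gamete[idx] = parent_haplos[phase, idx]
    return gamete


def make_gametes(
    pop: Population,
    parent_rows: np.ndarray,
    gmap: GenomeMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stack of gametes, one per entry of ``parent_rows`` (row indices)."""
    out = np.empty((len(parent_rows), gmap.n_loci), dtype=np.int8)
    for k, r in enumerate(parent_rows):
        out[k] = meiosis(pop.haplotypes[r], gmap, rng)
    return out


def cross(
    mother_haplos: np.ndarray,
    father_haplos: np.ndarray,
    gmap: GenomeMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring (2, L) haplotypes from independent meioses of both parents.

    Selfing is simply ``mother is father``.
    """
    return np.stack(
        [meiosis(mother_haplos, gmap, rng), meiosis(father_haplos, gmap, rng)]
    )


def make_offspring_population(
    pairs: list[tuple[int, int]],
    parents: Population,
    gmap: GenomeMap,
    pedigree: Pedigree,
    rng: np.random.Generator,
    generation: int,
    label: str | None = None,
) -> Population:
    """Create one offspring per (mother_row, father_row) pair, recording pedigree."""
    n = len(pairs)
    haplos = np.empty((n, 2, gmap.n_loci), dtype=np.int8)
    ids = np.empty(n, dtype=np.int64)
    for k, (mrow, frow) in enumerate(pairs):
        haplos[k] = cross(parents.haplotypes[mrow], parents.haplotypes[frow], gmap, rng)
        ids[k] = pedigree.add_offspring(int(parents.ids[mrow]), int(parents.ids[frow]))
    return Population(label or parents.label, ids, haplos, generation)


# ---------------------------------------------------------------------------
# Ancestral population and founders
# ---------------------------------------------------------------------------


def initial_ancestral_population(
    gmap: GenomeMap,
    n_individuals: int,
    rng: np.random.Generator,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> Population:
    """Linkage-equilibrium base population with Uniform(freq_range) frequencies."""
    p0 = rng.uniform(*freq_range, size=gmap.n_loci)
    haplos = (rng.random((n_individuals, 2, gmap.n_loci)) < p0).astype(np.int8)
    return Population("ancestral", np.zeros(n_individuals, dtype=np.int64), haplos)


def drift(
    haplotypes: np.ndarray,
    gmap: GenomeMap,
    n_generations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random mating at constant size for ``n_generations``; returns haplotypes."""
    n_individuals = haplotypes.shape[0]
    pop = Population("ancestral", np.zeros(n_individuals, dtype=np.int64), haplotypes)
    for _ in range(n_generations):
        mothers = rng.integers(n_individuals, size=n_individuals)
        fathers = rng.integers(n_individuals, size=n_individuals)
        nxt = np.empty_like(pop.haplotypes)
        for k in range(n_individuals):
            nxt[k, 0] = meiosis(pop.haplotypes[mothers[k]], gmap, rng)
            nxt[k, 1] = meiosis(pop.haplotypes[fathers[k]], gmap, rng)
        pop = Population("ancestral", pop.ids, nxt)
    return pop.haplotypes


def simulate_ancestral(
    gmap: GenomeMap,
    n_individuals: int,
    n_generations: int,
    rng: np.random.Generator,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> np.ndarray:
    """Random-mating ancestral population; returns final (n, 2, L) haplotypes.

    Initial allele frequencies are drawn Uniform(freq_range) per locus and
    alleles are in linkage equilibrium; drift through ``n_generations`` of
    random mating in a population of constant size builds up LD between
    linked loci.
    """
    base = initial_ancestral_population(gmap, n_individuals, rng, freq_range)
    return drift(base.haplotypes, gmap, n_generations, rng)


def ancestral_size_for_ld(ld_target_cm: float) -> int:
    """Ancestral population size whose equilibrium LD decays to r2=0.1 near the target.

    Uses the Sved/Hill-Robertson expectation E(r2) ~ 1/(1 + 4Nc): r2 = 0.1 at
    c = 9/(4N) recombination fraction, i.e. at roughly 900/(4N) cM for small
    distances, giving N ~ 225/d for a target distance of d cM.
    """
    return max(4, int(round(225.0 / ld_target_cm)))


def simulate_base_haplotypes(
    gmap: GenomeMap,
    n_founders: int,
    ld_target_cm: float,
    rng: np.random.Generator,
    pedigree: Pedigree | None = None,
    n_generations: int | None = None,
    label: str = "founders",
) -> Population:
    """Founder sample from an ancestral population sized for an LD target.

    Best-effort: the LD decay distance is tuned through the ancestral
    population size; locus density limits how finely it can be resolved.
    """
    if n_founders < 2:
        raise ConfigurationError("need at least two founders")
    n_anc = ancestral_size_for_ld(ld_target_cm)
    gens = n_generations if n_generations is not None else n_anc
    haplos = simulate_ancestral(gmap, max(n_anc, n_founders), gens, rng)
    rows = rng.choice(haplos.shape[0], size=n_founders, replace=False)
    ped = pedigree if pedigree is not None else Pedigree()
    ids = np.array([ped.add_founder() for _ in range(n_founders)], dtype=np.int64)
    return Population(label, ids, haplos[rows], generation=0)


def sample_founders(
    ancestral_haplos: np.ndarray,
    n_founders: int,
    pedigree: Pedigree,
    rng: np.random.Generator,
    label: str,
) -> Population:
    """Draw founders (without replacement) from stored ancestral haplotypes."""
    rows = rng.choice(ancestral_haplos.shape[0], size=n_founders, replace=False)
    ids = np.array([pedigree.add_founder() for _ in range(n_founders)], dtype=np.int64)
    return Population(label, ids, ancestral_haplos[rows], generation=0)


# ---------------------------------------------------------------------------
# Burn-in founder histories
# ---------------------------------------------------------------------------


@dataclass
class BurnInSpec:
    """Founder history of one breeding population.

    ``generation_sizes`` are the cohort sizes after the founders;
    ``selection_from`` is the first post-founder generation index (1-based)
    whose parents are chosen by mass selection; ``selfing_last`` marks how
    many final generations allow selfing; ``index_weights`` (w_bn, w_bw)
    define the mass-selection index on standardized trait phenotypes,
    creating the divergent trait profiles of the two populations.
    """

    n_founders: int
    generation_sizes: tuple[int, ...]
    selection_from: int = 1
    selfing_last: int = 0
    selection_fraction: float = 0.5
    index_weights: tuple[float, float] = (0.5, 0.5)

    def scaled(self, final_size: int) -> "BurnInSpec":
        sizes = self.generation_sizes[:-1] + (final_size,)
        return replace(self, generation_sizes=sizes)


DELI_BURN_IN = BurnInSpec(
    n_founders=4,
    generation_sizes=(25, 75, 75, 75, 75, 75, 75, 100),
    selection_from=2,
    selfing_last=2,
    index_weights=(0.1, 0.9),  # Deli: high bunch weight, low bunch number
)
LAME_BURN_IN = BurnInSpec(
    n_founders=24,
    generation_sizes=(70, 100),
    selection_from=1,
    selfing_last=0,
    index_weights=(0.9, 0.1),  # La Me: high bunch number, low bunch weight
)


def run_burn_in(
    spec: BurnInSpec,
    founders: Population,
    gmap: GenomeMap,
    pedigree: Pedigree,
    rng: np.random.Generator,
    trait_model=None,
    mass_selection: bool = True,
) -> Population:
    """Expand founders through the historical bottleneck generations.

    Each generation the parent pool is either all current individuals or,
    under mass selection, the top ``selection_fraction`` on a weighted index
    of standardized BN/BW phenotypes (a stand-in for mass selection on bunch
    production with population-specific emphasis).  Mating is random among
    the pool; in the last ``selfing_last`` generations parent pairs are drawn
    with replacement so selfings can occur.
    """
    if founders.size != spec.n_founders:
        raise ConfigurationError(
            f"burn-in expects {spec.n_founders} founders, got {founders.size}"
        )
    current = founders
    n_gens = len(spec.generation_sizes)
    for g, size in enumerate(spec.generation_sizes, start=1):
        pool = np.arange(current.size)
        if mass_selection and trait_model is not None and g >= spec.selection_from:
            score = _mass_selection_index(current, trait_model, spec.index_weights, rng)
            k = max(2, int(round(spec.selection_fraction * current.size)))
            pool = np.argsort(-score, kind="stable")[:k]
        allow_selfing = g > n_gens - spec.selfing_last
        pairs = []
        for _ in range(size):
            if allow_selfing:
                m, f = rng.choice(pool, size=2, replace=True)
            else:
                m, f = rng.choice(pool, size=2, replace=False)
            pairs.append((int(m), int(f)))
        current = make_offspring_population(
            pairs, current, gmap, pedigree, rng, generation=g, label=founders.label
        )
    return current


def _mass_selection_index(pop, trait_model, weights, rng) -> np.ndarray:
    """Weighted index of standardized BN/BW phenotypes for burn-in selection."""
    ph = trait_model.phenotypes(pop, rng)
    z_bn = _standardize(ph["bn_pheno"].to_numpy())
    z_bw = _standardize(ph["bw_pheno"].to_numpy())
    w_bn, w_bw = weights
    return w_bn * z_bn + w_bw * z_bw


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


# ---------------------------------------------------------------------------
# LD summaries
# ---------------------------------------------------------------------------


def adjacent_r2(pop: Population, gmap: GenomeMap, loci: np.ndarray | None = None):
    """r2 and cM distance for all adjacent locus pairs within chromosomes.

    Monomorphic loci yield undefined r2 and are dropped.
    Returns (distances, r2) arrays.
    """
    dos = pop.dosages().astype(float)
    loci = np.arange(gmap.n_loci) if loci is None else np.asarray(loci)
    dists, r2s = [], []
    for c in range(gmap.n_chromosomes):
        idx = loci[gmap.chrom[loci] == c]
        poly = idx[(dos[:, idx].std(axis=0) > 0)]
        if poly.size < 2:
            continue
        x = dos[:, poly]
        corr = np.corrcoef(x, rowvar=False)
        r = np.diag(corr, k=1) ** 2
        d = np.diff(gmap.pos_cm[poly])
        dists.append(d)
        r2s.append(r)
    if not dists:
        return np.array([]), np.array([])
    return np.concatenate(dists), np.concatenate(r2s)


def genotype_matrix_export(pop: Population, path) -> None:
    """Delimited text dosage matrix (individuals x loci)."""
    import pandas as pd

    pd.DataFrame(
        pop.dosages(), index=pop.ids, columns=[f"L{k}" for k in range(pop.haplotypes.shape[2])]
    ).to_csv(path)


def vcf_export(pop: Population, gmap: GenomeMap, path) -> None:
    """Minimal diploid VCF export; positions are cM x 1e5 bp, 1-based."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in range(gmap.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1}>\n")
        cols = "\t".join(str(i) for i in pop.ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for l in range(gmap.n_loci):
            pos = int(round(gmap.pos_cm[l] * 1e5)) + 1
            gts = "\t".join(
                f"{pop.haplotypes[k, 0, l]}|{pop.haplotypes[k, 1, l]}"
                for k in range(pop.size)
            )
            fh.write(f"chr{gmap.chrom[l] + 1}\t{pos}\tL{l}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
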