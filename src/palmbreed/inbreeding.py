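"""Inbreeding and coancestry measures.

Three views of inbreeding are tracked in the parental populations:

* genealogical: F_i = kinship(mother_i, father_i) computed recursively from
  the pedigree, founders taken as unrelated and non-inbred;
* SNP-based: fraction of homozygous loci on a fixed reference panel (the
  neutral SNPs polymorphic in the initial population, frozen at generation
  0), which mixes identity-by-descent with identity-by-state and therefore
  sits well above the genealogical value;
* QTL-based: the same homozygosity fraction at trait QTLs, which selection
  pushes above the neutral-SNP value.

Coancestry between prospective mates is pedigree kinship (f_ij = A_ij / 2)
in the phenotypic scheme and genomic coancestry (G_ij / 2) in the genomic
scheme, so progeny inbreeding is measured on the same basis as the breeding
values used for selection.  With the G_ij / 2 convention, the mean progeny
inbreeding of a mating design is directly comparable with the candidate
mean genomic inbreeding mean(G_ii) - 1 used in the adaptive threshold:

    scale conversions used throughout
    ---------------------------------
    pedigree:  f_ij = A_ij / 2,  f_ii = (1 + F_i) / 2,  F_progeny = f_parents
    genomic:   f_ij = G_ij / 2,  F_i = G_ii - 1
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import UNKNOWN, Pedigree, Population
from .evaluation import RelationshipMatrix


class PedigreeKinship:
    """Memoized recursive kinship on a pedigree (founders unrelated)."""

    def __init__(self, pedigree: Pedigree):
        self.ped = pedigree
        self._memo: dict[tuple[int, int], float] = {}
        self._order = {i: k for k, i in enumerate(pedigree.ids)}

    def kinship(self, a: int, b: int) -> float:
        """Coefficient of kinship f_ab; f_aa = (1 + F_a) / 2."""
        if a == UNKNOWN or b == UNKNOWN:
            return 0.0
        key = (a, b) if self._order[a] <= self._order[b] else (b, a)
        if key in self._memo:
            return self._memo[key]
        a, b = key
        if a == b:
            m, f = self.ped.parents(a)
            val = 0.5 * (1.0 + self.kinship(m, f))
        else:
            # b is the younger of the pair; recurse through its parents
            m, f = self.ped.parents(b)
            val = 0.5 * (self.kinship(a, m) + self.kinship(a, f))
        self._memo[key] = val
        return val

    def inbreeding(self, ind_id: int) -> float:
        m, f = self.ped.parents(ind_id)
        return self.kinship(m, f)

    def matrix(self, ids) -> RelationshipMatrix:
        """Kinship matrix f_ij over the given ids (pedigree mode)."""
        ids = np.asarray(ids, dtype=np.int64)
        n = ids.size
        out = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                out[i, j] = out[j, i] = self.kinship(int(ids[i]), int(ids[j]))
        return RelationshipMatrix(ids, out, "pedigree_kinship")


def genealogical_inbreeding(pedigree: Pedigree, ids=None) -> pd.Series:
    """Pedigree inbreeding coefficient per individual (founders = 0)."""
    calc = PedigreeKinship(pedigree)
    ids = pedigree.ids if ids is None else list(ids)
    return pd.Series([calc.inbreeding(int(i)) for i in ids], index=ids, dtype=float)


def snp_inbreeding(pop: Population, panel: np.ndarray) -> np.ndarray:
    """Per-individual fraction of homozygous loci on the reference panel.

    The panel is frozen at generation 0 (loci polymorphic in the initial
    population) and reused for all later generations.
    """
    panel = np.asarray(panel)
    if panel.size == 0:
        raise ValueError("empty reference panel")
    sub = pop.haplotypes[:, :, panel]
    return (sub[:, 0, :] == sub[:, 1, :]).mean(axis=1)


def polymorphic_panel(pop: Population, loci: np.ndarray) -> np.ndarray:
    """Subset of ``loci`` polymorphic in ``pop`` (the generation-0 freeze)."""
    p = pop.allele_freqs()[loci]
    return np.asarray(loci)[(p > 0) & (p < 1)]


def genomic_coancestry(i: int, j: int, G: RelationshipMatrix) -> float:
    """Genomic coancestry f_ij = G_ij / 2 (self-coancestry = G_ii / 2)."""
    return G.loc(i, j) / 2.0


def kinship_matrix_from_G(G: RelationshipMatrix) -> RelationshipMatrix:
    """Coancestry matrix f = G / 2 on the same id index."""
    return RelationshipMatrix(G.ids, G.values / 2.0, "genomic_kinship")


def progeny_inbreeding_of_design(cells, f: RelationshipMatrix | np.ndarray, ids=None) -> float:
    """Mean inbreeding of the progenies of a mating design.

    ``cells`` are (i, j) index pairs (j >= i) into ``ids``/the kinship
    matrix; the value is (1/n_cross) * sum of f_ij over the crosses, the
    expected inbreeding of a progeny cohort with one family per cross.
    """
    if isinstance(f, RelationshipMatrix):
        if ids is None:
            ids = f.ids
        vals = f.values
        index = {int(v): k for k, v in enumerate(f.ids)}
        rows = [index[int(i)] for i in ids]
        vals = vals[np.ix_(rows, rows)]
    else:
        vals = np.asarray(f)
    cells = list(cells)
    if not cells:
        raise ValueError("empty design")
    if max(max(c) for c in cells) >= vals.shape[0]:
        raise ValueError("cell index outside kinship matrix")
    return float(np.mean([vals[i, j] for i, j in cells]))


@dataclass
class InbreedingReport:
    """Population-level inbreeding aggregates for one generation."""

    f_pedigree: float
    f_snp: float
    f_qtl_bn: float
    f_qtl_bw: float

    def as_dict(self) -> dict:
        return {
            "F_pedigree": self.f_pedigree,
            "F_snp": self.f_snp,
            "F_qtl_bn": self.f_qtl_bn,
            "F_qtl_bw": self.f_qtl_bw,
        }


def population_inbreeding(
    pop: Population,
    pedigree: Pedigree,
    snp_panel: np.ndarray,
    qtl_bn_panel: np.ndarray,
    qtl_bw_panel: np.ndarray,
) -> InbreedingReport:
    """All inbreeding measures averaged over a population."""
    f_ped = genealogical_inbreeding(pedigree, pop.ids).mean()
    return InbreedingReport(
        f_pedigree=float(f_ped),
        f_snp=float(snp_inbreeding(pop, snp_panel).mean()),
        f_qtl_bn=float(snp_inbreeding(pop, qtl_bn_panel).mean()),
        f_qtl_bw=float(snp_inbreeding(pop, qtl_bw_panel).mean()),
    )
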