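"""Breeding-value estimation for hybrid performance.

Parents are evaluated for their general combining ability (GCA) in hybrid
crosses with the other population.  The mixed model per trait is

    y = 1*mu + Z_D u_D + Z_L u_L + e,
    u_D ~ N(0, K_D sigma2_D), u_L ~ N(0, K_L sigma2_L),

where y are hybrid phenotypes from a progeny test, Z_* link each hybrid to
its parent in each population, and K is the pedigree numerator relationship
matrix A (phenotypic scheme) or the VanRaden genomic relationship matrix G
(genomic scheme).  Variance components are taken as the simulated truth
(sigma2_GCA = sigma2_a / 4 per population), not re-estimated.

Estimated breeding values are reported on an absolute half-scale,
``g_i = mu_hat / 2 + u_hat_i``, so that the sum of a Deli and a La Me
parental mean term reconstructs the expected hybrid trait value and
products of g's in the multiplicative yield formulas stay positive and
rank-meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import UNKNOWN, Pedigree, Population

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------


@dataclass
class RelationshipMatrix:
    """Symmetric PSD additive relationship matrix with an id index."""

    ids: np.ndarray
    values: np.ndarray
    kind: str  # "pedigree" or "genomic"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self._index = {int(i): k for k, i in enumerate(self.ids)}

    def loc(self, i: int, j: int) -> float:
        return float(self.values[self._index[int(i)], self._index[int(j)]])

    def submatrix(self, ids) -> "RelationshipMatrix":
        rows = [self._index[int(i)] for i in ids]
        return RelationshipMatrix(
            np.asarray(ids), self.values[np.ix_(rows, rows)], self.kind
        )

    def diagonal(self, ids=None) -> np.ndarray:
        if ids is None:
            return np.diag(self.values).copy()
        return np.array([self.loc(i, i) for i in ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def build_A(pedigree: Pedigree, ids=None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``A_ii = 1 + F_i`` with F the pedigree inbreeding coefficient.  When
    ``ids`` is given the matrix is computed over the whole pedigree and
    sliced to those individuals (ancestors are needed for correctness).
    """
    if not pedigree.is_topologically_ordered():
        raise ValueError("pedigree is not topologically ordered")
    order = pedigree.ids
    idx = {i: k for k, i in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for k, i in enumerate(order):
        m, f = pedigree.parents(i)
        km = idx[m] if m != UNKNOWN else None
        kf = idx[f] if f != UNKNOWN else None
        row = np.zeros(k)
        if km is not None:
            row += 0.5 * A[km, :k]
        if kf is not None:
            row += 0.5 * A[kf, :k]
        A[k, :k] = row
        A[:k, k] = row
        if km is not None and kf is not None:
            A[k, k] = 1.0 + 0.5 * A[km, kf]
        else:
            A[k, k] = 1.0
    rel = RelationshipMatrix(np.asarray(order), A, "pedigree")
    return rel.submatrix(np.asarray(ids)) if ids is not None else rel


def build_G(
    ids,
    dosages: np.ndarray,
    base_freqs: np.ndarray,
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix.

    ``G = Z Z' / (2 sum p_k (1 - p_k))`` with ``Z`` the dosage matrix centered
    by twice the base-population allele frequencies.  ``base_freqs`` must be
    the frequencies of the declared base (founder) population, not of the
    genotyped sample.
    """
    dosages = np.asarray(dosages, dtype=np.float64)
    p = np.asarray(base_freqs, dtype=np.float64)
    if dosages.shape[1] != p.size:
        raise ValueError("dosage and frequency dimensions differ")
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("fewer than 2 polymorphic markers in the base population")
    Z = dosages[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = Z @ Z.T / denom
    return RelationshipMatrix(np.asarray(ids), G, "genomic")


# ---------------------------------------------------------------------------
# EBV tables and the hybrid-value formula
# ---------------------------------------------------------------------------


def make_ebv_table(ids, g_bn, g_bw, source: str) -> pd.DataFrame:
    tab = pd.DataFrame(
        {
            "individual_id": np.asarray(ids, dtype=np.int64),
            "g_bn": np.asarray(g_bn, dtype=float),
            "g_bw": np.asarray(g_bw, dtype=float),
            "source": source,
        }
    )
    if not np.isfinite(tab[["g_bn", "g_bw"]].to_numpy()).all():
        raise ValueError("non-finite estimated breeding values")
    return tab


def expected_hybrid_ffb(gd_i, gd_j, glm_i, glm_j) -> float:
    """Expected hybrid FFB of the cross (Deli i x j) x (La Me i x j).

    Each argument is a (g_BN, g_BW) pair on the absolute half-scale.  The
    value is the product of the summed parental mean terms per trait:

        [0.5(gDi+gDj)(BN) + 0.5(gLMi+gLMj)(BN)] *
        [0.5(gDi+gDj)(BW) + 0.5(gLMi+gLMj)(BW)]
    """
    bn = 0.5 * (gd_i[0] + gd_j[0]) + 0.5 * (glm_i[0] + glm_j[0])
    bw = 0.5 * (gd_i[1] + gd_j[1]) + 0.5 * (glm_i[1] + glm_j[1])
    return float(bn * bw)


# ---------------------------------------------------------------------------
# Mixed-model solver
# ---------------------------------------------------------------------------


@dataclass
class BlupFit:
    """Solution of one univariate two-GCA mixed model."""

    mu_hat: float
    u_pop_a: pd.Series  # indexed by individual id
    u_pop_b: pd.Series
    residual_norm: float


def _solve_gca_mme(
    y: np.ndarray,
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    K_a: RelationshipMatrix,
    K_b: RelationshipMatrix,
    lambda_a: float,
    lambda_b: float,
) -> BlupFit:
    """Henderson's mixed-model equations for y = mu + u_a + u_b + e."""
    ids_a, ids_b = K_a.ids, K_b.ids
    pos_a = {int(i): k for k, i in enumerate(ids_a)}
    pos_b = {int(i): k for k, i in enumerate(ids_b)}
    n = y.size
    na, nb = ids_a.size, ids_b.size
    Za = np.zeros((n, na))
    Zb = np.zeros((n, nb))
    Za[np.arange(n), [pos_a[int(p)] for p in parent_a]] = 1.0
    Zb[np.arange(n), [pos_b[int(p)] for p in parent_b]] = 1.0
    W = np.hstack([np.ones((n, 1)), Za, Zb])
    Kinv_a = _safe_inverse(K_a.values, "K_a")
    Kinv_b = _safe_inverse(K_b.values, "K_b")
    C = W.T @ W
    C[1 : 1 + na, 1 : 1 + na] += lambda_a * Kinv_a
    C[1 + na :, 1 + na :] += lambda_b * Kinv_b
    rhs = W.T @ y
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(C)
        raise np.linalg.LinAlgError(
            f"singular mixed-model equations (condition number {cond:.3g})"
        ) from exc
    resid = float(np.linalg.norm(C @ sol - rhs))
    return BlupFit(
        mu_hat=float(sol[0]),
        u_pop_a=pd.Series(sol[1 : 1 + na], index=ids_a),
        u_pop_b=pd.Series(sol[1 + na :], index=ids_b),
        residual_norm=resid,
    )


def _safe_inverse(K: np.ndarray, name: str) -> np.ndarray:
    try:
        np.linalg.cholesky(K)
        return np.linalg.inv(K)
    except np.linalg.LinAlgError:
        logger.info("%s not positive definite; adding 1e-6 ridge to diagonal", name)
        return np.linalg.inv(K + 1e-6 * np.eye(K.shape[0]))


@dataclass
class VarianceComponents:
    """True simulated components used for BLUP/GBLUP (per trait)."""

    gca_a: float   # GCA variance, population A (= sigma2_a / 4)
    gca_b: float
    residual: float

    @property
    def lambda_a(self) -> float:
        return self.residual / self.gca_a

    @property
    def lambda_b(self) -> float:
        return self.residual / self.gca_b


def components_from_model(model, label_a: str, label_b: str) -> dict:
    """Per-trait variance components from the simulated truth.

    GCA variance per population is a quarter of its additive variance; the
    model residual pools the environmental variance of hybrids with the
    within-cross segregation variance (a quarter of each parental additive
    variance).
    """
    out = {}
    ve = model.env_var("Hybrid")
    for k, trait in enumerate(("bn", "bw")):
        va_a = model.var_a[label_a][k]
        va_b = model.var_a[label_b][k]
        out[trait] = VarianceComponents(
            gca_a=va_a / 4.0,
            gca_b=va_b / 4.0,
            residual=ve[k] + va_a / 4.0 + va_b / 4.0,
        )
    return out


def fit_progeny_test_blup(
    hybrid_phenos: pd.DataFrame,
    K_a: RelationshipMatrix,
    K_b: RelationshipMatrix,
    var_components: dict,
    source: str = "pedigree_blup",
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Parental (G)EBVs from a hybrid progeny test, one mixed model per trait.

    ``hybrid_phenos`` needs columns parent_a, parent_b, bn_pheno, bw_pheno.
    Every individual carried by ``K_a``/``K_b`` receives an EBV, including
    unphenotyped candidates connected through relationships (this is what
    makes the same solver serve pedigree BLUP and GBLUP).  Returns the two
    EBV tables (population A, population B) and the per-trait fits.
    """
    fits = {}
    g_a, g_b = {}, {}
    for trait in ("bn", "bw"):
        vc = var_components[trait]
        fit = _solve_gca_mme(
            hybrid_phenos[f"{trait}_pheno"].to_numpy(dtype=float),
            hybrid_phenos["parent_a"].to_numpy(),
            hybrid_phenos["parent_b"].to_numpy(),
            K_a,
            K_b,
            vc.lambda_a,
            vc.lambda_b,
        )
        fits[trait] = fit
        g_a[trait] = fit.mu_hat / 2.0 + fit.u_pop_a
        g_b[trait] = fit.mu_hat / 2.0 + fit.u_pop_b
    tab_a = make_ebv_table(K_a.ids, g_a["bn"].to_numpy(), g_a["bw"].to_numpy(), source)
    tab_b = make_ebv_table(K_b.ids, g_b["bn"].to_numpy(), g_b["bw"].to_numpy(), source)
    return tab_a, tab_b, fits


def fit_gblup(
    training_phenos: pd.DataFrame,
    G_a: RelationshipMatrix,
    G_b: RelationshipMatrix,
    var_components: dict,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """GBLUP: the GCA mixed model with genomic relationship matrices.

    ``G_a``/``G_b`` must carry both the training parents and the selection
    candidates; candidates without records get GEBVs through the genomic
    relationships.
    """
    return fit_progeny_test_blup(
        training_phenos, G_a, G_b, var_components, source="gblup"
    )
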