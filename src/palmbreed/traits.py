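"""Quantitative-genetic trait model for the multiplicative hybrid trait.

Bunch number (BN) and bunch weight (BW) are purely additive traits; fresh
fruit bunch yield is their product, FFB = BN x BW.  Heterosis for FFB then
emerges without any dominance, from crossing populations with complementary
trait profiles (one high-BN/low-BW, the other the reverse): the hybrid mean
product of near-equal components exceeds the midparent mean of two
unbalanced products.

QTL effects are normal deviates; a configurable fraction of QTLs is
pleiotropic with negatively correlated BN/BW effect pairs, which generates
the negative genetic correlation between the traits.  Environmental noise
is normal with variance derived from the heritability:
``sigma_e^2 = sigma_a^2 * (1 - h2) / h2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genome
from .genome import GenomeMap, Population


def env_variance(var_a: float, h2: float) -> float:
    """Residual variance implied by additive variance and heritability."""
    if not 0 < h2 <= 1:
        raise ValueError("heritability must be in (0, 1]")
    return var_a * (1.0 - h2) / h2


@dataclass
class TraitModel:
    """Additive two-trait model with per-population means and heritabilities.

    ``eff_bn``/``eff_bw`` are per-locus additive effects (zero outside the
    matching QTL class).  ``mu`` maps a population label to its (BN, BW)
    trait means on the absolute scale; ``h2`` and ``var_a`` likewise map
    labels to per-trait values, from which residual variances follow.
    """

    eff_bn: np.ndarray
    eff_bw: np.ndarray
    pleiotropy_corr: float = 0.0
    mu: dict = field(default_factory=dict)        # label -> (mu_bn, mu_bw)
    h2: dict = field(default_factory=dict)        # label -> (h2_bn, h2_bw)
    var_a: dict = field(default_factory=dict)     # label -> (va_bn, va_bw)

    def env_var(self, label: str) -> tuple[float, float]:
        h2_bn, h2_bw = self.h2[label]
        va_bn, va_bw = self.var_a[label]
        return env_variance(va_bn, h2_bn), env_variance(va_bw, h2_bw)

    # -- genetic values ----------------------------------------------------

    def tbv(self, pop_or_dosages, trait: str) -> np.ndarray:
        """Genotypic contribution: dosage . effects (no population mean)."""
        dos = (
            pop_or_dosages.dosages()
            if isinstance(pop_or_dosages, Population)
            else np.asarray(pop_or_dosages)
        )
        eff = self.eff_bn if trait == "bn" else self.eff_bw
        return dos.astype(float) @ eff

    def genetic_values(self, pop: Population, label: str | None = None):
        """Absolute-scale genetic values (mu + tbv) for BN, BW and FFB."""
        label = label or pop.label
        mu_bn, mu_bw = self.mu[label]
        bn = mu_bn + self.tbv(pop, "bn")
        bw = mu_bw + self.tbv(pop, "bw")
        return bn, bw, bn * bw

    def phenotypes(self, pop: Population, rng: np.random.Generator, label: str | None = None) -> pd.DataFrame:
        """Phenotype records: pheno = mu + tbv + N(0, sigma_e^2); FFB = BN x BW."""
        label = label or pop.label
        mu_bn, mu_bw = self.mu.get(label, (0.0, 0.0))
        ve_bn, ve_bw = self.env_var(label) if label in self.h2 else (0.0, 0.0)
        tbv_bn = self.tbv(pop, "bn")
        tbv_bw = self.tbv(pop, "bw")
        bn = mu_bn + tbv_bn + rng.normal(0.0, np.sqrt(ve_bn), size=pop.size)
        bw = mu_bw + tbv_bw + rng.normal(0.0, np.sqrt(ve_bw), size=pop.size)
        return pd.DataFrame(
            {
                "individual_id": pop.ids,
                "bn_pheno": bn,
                "bw_pheno": bw,
                "ffb_pheno": bn * bw,
                "bn_tbv": tbv_bn,
                "bw_tbv": tbv_bw,
            }
        )

    def anchor(
        self,
        populations: dict[str, Population],
        mean_targets: dict[str, tuple[float, float]],
        h2_targets: dict[str, tuple[float, float]],
        var_a_target: tuple[float, float] | None = None,
    ) -> None:
        """Anchor the absolute scale on the generation-0 populations.

        Rescales the effect vectors so the across-population mean realized
        additive variance matches ``var_a_target`` per trait (when given),
        then sets each population's mean so its absolute genetic mean equals
        the target, and stores realized additive variances and target
        heritabilities (from which residual variances derive).  A "Hybrid"
        entry is added with midparent means and averaged parameters.
        """
        if var_a_target is not None:
            for trait, target in zip(("bn", "bw"), var_a_target):
                realized = np.mean(
                    [self.tbv(p, trait).var() for p in populations.values()]
                )
                if realized > 0:
                    scale = np.sqrt(target / realized)
                    if trait == "bn":
                        self.eff_bn = self.eff_bn * scale
                    else:
                        self.eff_bw = self.eff_bw * scale
        for label, pop in populations.items():
            t_bn, t_bw = mean_targets[label]
            self.mu[label] = (
                t_bn - self.tbv(pop, "bn").mean(),
                t_bw - self.tbv(pop, "bw").mean(),
            )
            self.h2[label] = h2_targets[label]
            self.var_a[label] = (
                max(self.tbv(pop, "bn").var(), 1e-12),
                max(self.tbv(pop, "bw").var(), 1e-12),
            )
        labels = list(populations)
        self.mu["Hybrid"] = tuple(
            np.mean([self.mu[l][k] for l in labels]) for k in range(2)
        )
        self.h2["Hybrid"] = tuple(
            np.mean([self.h2[l][k] for l in labels]) for k in range(2)
        )
        self.var_a["Hybrid"] = tuple(
            np.mean([self.var_a[l][k] for l in labels]) for k in range(2)
        )


def sample_qtl_effects(
    gmap: GenomeMap,
    founders: Population,
    n_qtl_per_trait: int,
    pleiotropy_frac: float = 0.7,
    pleiotropy_corr: float = -0.9,
    maf_min: float = 0.1,
    rng: np.random.Generator | None = None,
    effect_sd: float = 1.0,
) -> TraitModel:
    """Sample QTL positions and normal effects; updates ``gmap.locus_class``.

    QTL loci are drawn without replacement from loci segregating in the
    founders with minor allele frequency above ``maf_min``.  Pleiotropic
    QTLs get a bivariate-normal (BN, BW) effect pair with correlation
    ``pleiotropy_corr`` (negative by default, generating the antagonism
    between bunch number and bunch weight); private QTLs affect one trait.
    """
    rng = np.random.default_rng(rng)
    p = founders.allele_freqs()
    maf = np.minimum(p, 1.0 - p)
    eligible = np.flatnonzero(maf > maf_min)
    n_pleio = int(round(pleiotropy_frac * n_qtl_per_trait))
    n_private = n_qtl_per_trait - n_pleio
    need = n_pleio + 2 * n_private
    if eligible.size < need:
        raise ValueError(
            f"need {need} loci with MAF > {maf_min}, only {eligible.size} eligible"
        )
    chosen = rng.choice(eligible, size=need, replace=False)
    pleio = chosen[:n_pleio]
    only_bn = chosen[n_pleio : n_pleio + n_private]
    only_bw = chosen[n_pleio + n_private :]

    gmap.locus_class[:] = genome.NEUTRAL
    gmap.locus_class[pleio] = genome.QTL_PLEIO
    gmap.locus_class[only_bn] = genome.QTL_BN
    gmap.locus_class[only_bw] = genome.QTL_BW

    eff_bn = np.zeros(gmap.n_loci)
    eff_bw = np.zeros(gmap.n_loci)
    eff_bn[only_bn] = rng.normal(0.0, effect_sd, size=n_private)
    eff_bw[only_bw] = rng.normal(0.0, effect_sd, size=n_private)
    if n_pleio:
        cov = np.array([[1.0, pleiotropy_corr], [pleiotropy_corr, 1.0]]) * effect_sd**2
        pair = rng.multivariate_normal([0.0, 0.0], cov, size=n_pleio)
        eff_bn[pleio] = pair[:, 0]
        eff_bw[pleio] = pair[:, 1]
    return TraitModel(eff_bn, eff_bw, pleiotropy_corr=pleiotropy_corr)


def true_breeding_value(ind_haplos: np.ndarray, model: TraitModel, trait: str) -> float:
    """Sum over loci of allele dosage times effect, for one (2, L) individual."""
    dos = np.asarray(ind_haplos).sum(axis=0)
    return float(model.tbv(dos[None, :], trait)[0])


def genetic_correlation(model: TraitModel, pop: Population) -> float:
    """Pearson correlation of BN and BW true breeding values within a population."""
    a = model.tbv(pop, "bn")
    b = model.tbv(pop, "bw")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Population summary statistics
# ---------------------------------------------------------------------------


class UndefinedStatisticError(ValueError):
    """A summary statistic is undefined for the given input (e.g. no polymorphism)."""


def hudson_fst(pop_a: Population, pop_b: Population, loci: np.ndarray) -> float:
    """Hudson's Fst, ratio of averages over the given loci.

    Per locus: N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D = p1(1-p2) + p2(1-p1); Fst = sum(N)/sum(D) over loci with D > 0.
    """
    p1 = pop_a.allele_freqs()[loci]
    p2 = pop_b.allele_freqs()[loci]
    n1 = 2 * pop_a.size
    n2 = 2 * pop_b.size
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    if not np.any(ok):
        raise UndefinedStatisticError("all loci monomorphic in both populations")
    return float(num[ok].sum() / den[ok].sum())


def ld_decay_distance(
    pop: Population,
    gmap: GenomeMap,
    r2_threshold: float = 0.1,
    loci: np.ndarray | None = None,
) -> float:
    """Distance (cM) at which adjacent-pair r2 decays to the threshold.

    Fits a decreasing isotonic curve of r2 against distance (pool-adjacent-
    violators on the sorted pairs) and reports the first crossing of the
    threshold, linearly interpolated.  NaN if the fitted curve never crosses.
    """
    d, r2 = genome.adjacent_r2(pop, gmap, loci)
    if d.size < 2:
        raise UndefinedStatisticError("not enough polymorphic adjacent pairs")
    order = np.argsort(d)
    d, r2 = d[order], r2[order]
    fit = _isotonic_decreasing(r2)
    below = np.flatnonzero(fit <= r2_threshold)
    if below.size == 0:
        return float("nan")
    j = below[0]
    if j == 0:
        return float(d[0])
    x0, x1 = d[j - 1], d[j]
    y0, y1 = fit[j - 1], fit[j]
    if y0 == y1:
        return float(x1)
    return float(x0 + (y0 - r2_threshold) * (x1 - x0) / (y0 - y1))


def _isotonic_decreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators fit, non-increasing."""
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(increasing=False)
    return iso.fit_transform(np.arange(y.size), y)


def heterosis_percent(ffb_parent_a: float, ffb_parent_b: float, ffb_hybrid: float) -> float:
    midparent = 0.5 * (ffb_parent_a + ffb_parent_b)
    if midparent == 0:
        raise UndefinedStatisticError("midparent FFB is zero")
    return 100.0 * (ffb_hybrid - midparent) / midparent


def population_summaries(
    pop_a: Population,
    pop_b: Population,
    hybrids: Population | None,
    model: TraitModel,
    gmap: GenomeMap,
) -> pd.DataFrame:
    """One-row summary: Fst, LD decay, mean FFB per population, heterosis, r(BN,BW)."""
    if pop_a.size == 0 or pop_b.size == 0:
        raise ValueError("populations must be non-empty")
    neutral = gmap.neutral_indices
    _, _, ffb_a = model.genetic_values(pop_a)
    _, _, ffb_b = model.genetic_values(pop_b)
    row = {
        "fst": hudson_fst(pop_a, pop_b, neutral),
        f"ld_cm_{pop_a.label}": ld_decay_distance(pop_a, gmap, loci=neutral),
        f"ld_cm_{pop_b.label}": ld_decay_distance(pop_b, gmap, loci=neutral),
        f"ffb_{pop_a.label}": ffb_a.mean(),
        f"ffb_{pop_b.label}": ffb_b.mean(),
        f"r_bn_bw_{pop_a.label}": genetic_correlation(model, pop_a),
        f"r_bn_bw_{pop_b.label}": genetic_correlation(model, pop_b),
    }
    if hybrids is not None and hybrids.size:
        _, _, ffb_h = model.genetic_values(hybrids, label="Hybrid")
        row["ffb_hybrid"] = ffb_h.mean()
        row["heterosis_pct"] = heterosis_percent(
            ffb_a.mean(), ffb_b.mean(), ffb_h.mean()
        )
    return pd.DataFrame([row])
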