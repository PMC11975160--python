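"""Two-trait additive architecture, true breeding values and phenotypes.

Both traits (health, h2 = 0.1; production, h2 = 0.3) are controlled by
one shared set of QTL drawn from the marker panel.  Per-QTL effect pairs
come from a bivariate normal whose effect-level correlation is calibrated
so that the *realized* correlation of true breeding values in the founder
population hits the target (default -0.1) exactly; an affine rescaling
then anchors the founder TBV mean and genetic variance to 100 and 10 per
trait.  Residuals are independent across traits and individuals with
variance ``10 * (1 - h2) / h2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .genome import ConfigurationError, Individual

__all__ = ["TraitParams", "TraitArchitecture", "sample_architecture",
           "true_bv", "assign_tbv", "draw_phenotypes"]


@dataclass(frozen=True)
class TraitParams:
    """Target genetic parameters of the two-trait breeding goal."""

    n_qtl: int = 1000
    target_mean: float = 100.0
    target_genetic_variance: float = 10.0
    h2: tuple = (0.1, 0.3)
    r_g: float = -0.1

    @property
    def gsd(self) -> float:
        return float(np.sqrt(self.target_genetic_variance))

    @property
    def residual_variance(self) -> np.ndarray:
        h2 = np.asarray(self.h2)
        return self.target_genetic_variance * (1.0 - h2) / h2

    @property
    def G0(self) -> np.ndarray:
        """True 2x2 additive covariance matrix."""
        v = self.target_genetic_variance
        c = self.r_g * v
        return np.array([[v, c], [c, v]])

    @property
    def R0(self) -> np.ndarray:
        return np.diag(self.residual_variance)


@dataclass
class TraitArchitecture:
    """Realized QTL architecture with per-trait affine scaling.

    ``effects`` are the unscaled allele-substitution effects; the TBV of
    an individual with QTL allele counts ``c`` on trait t is
    ``intercept[t] + slope[t] * sum_q c_q * effects[q, t]``.
    """

    params: TraitParams
    qtl_indices: np.ndarray
    effects: np.ndarray          # (n_qtl, 2)
    slope: np.ndarray            # (2,)
    intercept: np.ndarray        # (2,)
    effect_correlation: float = field(default=np.nan)

    @property
    def scaled_effects(self) -> np.ndarray:
        return self.effects * self.slope[None, :]

    def to_table(self):
        """Plain text-table representation (trait, marker, effect)."""
        import pandas as pd
        rows = []
        for t in range(2):
            rows.append(pd.DataFrame({
                "trait": t,
                "marker_index": self.qtl_indices,
                "effect": self.effects[:, t],
                "slope": self.slope[t],
                "intercept": self.intercept[t],
            }))
        return pd.concat(rows, ignore_index=True)


def _tbv_raw(dosage_qtl: np.ndarray, effects: np.ndarray) -> np.ndarray:
    return dosage_qtl.astype(np.float64) @ effects


def sample_architecture(genome, population, founder_ids: Sequence,
                        params: TraitParams = TraitParams(),
                        rng: Optional[np.random.Generator] = None,
                        seed: Optional[int] = None) -> TraitArchitecture:
    """Draw QTL and calibrate effects on the founder population.

    The effect-level correlation rho is found by root-bracketing on the
    closed-form realized founder-TBV correlation of
    ``u1 = a, u2 = rho*a + sqrt(1-rho^2)*b`` (a, b independent standard
    normal effect vectors), so the realized genetic correlation matches
    the target to numerical precision.  Scaling makes the founder TBV
    mean and (population) variance exactly 100 and 10 per trait.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    m = genome.n_markers
    if params.n_qtl > m:
        raise ConfigurationError("more QTL requested than markers available")
    qtl = np.sort(rng.choice(m, size=params.n_qtl, replace=False))
    founder_ids = np.asarray(founder_ids)
    M = population.genotype_dosage(founder_ids)[:, qtl].astype(np.float64)

    a = rng.standard_normal(params.n_qtl)
    b = rng.standard_normal(params.n_qtl)
    x = M @ a
    y = M @ b
    x = x - x.mean()
    y = y - y.mean()
    sxx, syy, sxy = x @ x, y @ y, x @ y
    if sxx <= 0 or syy <= 0:
        raise ConfigurationError(
            "founder TBVs have zero variance; population is monomorphic "
            "at the sampled QTL")

    def realized(rho):
        lam = np.sqrt(max(0.0, 1.0 - rho * rho))
        num = rho * sxx + lam * sxy
        den = np.sqrt(sxx * (rho * rho * sxx + 2 * rho * lam * sxy
                             + lam * lam * syy))
        return num / den - params.r_g

    rho = brentq(realized, -1.0 + 1e-12, 1.0 - 1e-12, xtol=1e-12)
    lam = np.sqrt(1.0 - rho * rho)
    effects = np.column_stack([a, rho * a + lam * b])

    raw = _tbv_raw(M, effects)
    var = raw.var(axis=0)
    if np.any(var <= 0):
        raise ConfigurationError("zero-variance trait after effect draw")
    slope = np.sqrt(params.target_genetic_variance / var)
    intercept = params.target_mean - slope * raw.mean(axis=0)
    return TraitArchitecture(params, qtl, effects, slope, intercept,
                             effect_correlation=float(rho))


def true_bv(individual: Individual, arch: TraitArchitecture) -> np.ndarray:
    """TBV of one individual: pure function of its QTL genotype."""
    dosage = (individual.haplotypes[0] + individual.haplotypes[1])
    dq = dosage[arch.qtl_indices].astype(np.float64)
    return arch.intercept + dq @ arch.scaled_effects


def assign_tbv(population, ids, arch: TraitArchitecture) -> np.ndarray:
    """Compute and store TBVs for a cohort (vectorized)."""
    ids = np.asarray(ids)
    dq = population.genotype_dosage(ids)[:, arch.qtl_indices]
    tbv = arch.intercept[None, :] + _tbv_raw(dq, arch.scaled_effects)
    population.tbv[ids] = tbv
    return tbv


def draw_phenotypes(population, ids, arch: TraitArchitecture,
                    rng: np.random.Generator) -> np.ndarray:
    """Phenotype a cohort as own performance: TBV plus trait residual.

    Residuals are independent across traits and individuals.  An animal
    can be phenotyped only once.
    """
    ids = np.asarray(ids)
    if np.any(~np.isnan(population.phen[ids, 0])):
        raise ValueError("attempt to phenotype an already phenotyped animal")
    sd = np.sqrt(arch.params.residual_variance)
    e = rng.standard_normal((ids.size, 2)) * sd[None, :]
    phen = population.tbv[ids] + e
    population.phen[ids] = phen
    return phen
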