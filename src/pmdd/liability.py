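"""Liability-threshold models for relative pairs.

A binary diagnosis is modelled as a latent standard-normal liability
exceeding the threshold z = Phi^-1(1 - K) at lifetime prevalence K.  The
liability correlation of a relative pair with additive-genetic sharing s
and shared-environment sharing c is s*a2 + c*c2, so contrasting full
siblings (s = 1/2, c = 1) against first cousins (s = 1/8, c = 0)
identifies the ACE variance shares.  This module provides:

* tetrachoric correlations (root-finding against the exact bivariate
  normal orthant probability) with delta-method standard errors;
* ACE / AE variance-share estimation by weighted least squares on the
  kinship-class tetrachorics;
* genetic correlations between two traits, by WLS on cross-trait
  cross-person tetrachorics (non-exclusive traits) or by maximum
  likelihood on 3x3 pair cross-tables of mutually exclusive diagnoses
  (multinomial likelihood with 4-dimensional normal rectangle
  probabilities);
* family-clustered bootstrap confidence intervals, chi-square / LRT model
  comparison, and a paired bootstrap test for equality of two genetic
  correlations.

Mutually exclusive traits (psychotic vs non-psychotic MDD) never co-occur
within a person, so the within-person cross-trait correlation is not
estimable from comorbidity; it is parameterised structurally as
rg*sqrt(a2_1*a2_2) + re*sqrt(e2_1*e2_2) with re = 0 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, lsq_linear, minimize, minimize_scalar
from scipy.special import ndtr, ndtri
from scipy.stats import chi2

from ._bvn import bvn_cdf, bvn_pdf, bvn_sf
from ._mvn4 import mvn4_rect_multi
from .exceptions import ConfigError, DataError
from .registry import KINSHIP_A_SHARE, TraitSpec, pair_correlation_matrix

__all__ = [
    "TetrachoricResult",
    "PairCrossTable",
    "tetrachoric",
    "person_categories",
    "cross_table",
    "AceLiabilityModel",
    "GeneticCorrelationModel",
    "LiabilityFit",
    "bootstrap_fits",
    "percentile_ci",
    "compare_models",
    "rg_difference_test",
]

_C_SHARE = {"full_sib": 1.0, "half_sib": 0.0, "cousin": 0.0}


# --------------------------------------------------------------------------
# cross tables
# --------------------------------------------------------------------------

@dataclass
class PairCrossTable:
    """Counts of joint pair outcomes for one kinship class.

    ``counts`` is a symmetric k x k matrix over person-level categories in
    which each unordered pair contributes once (off-diagonal cells split
    evenly between (i,j) and (j,i)); the margins are therefore averaged
    over the two pair members and the total equals ``n_pairs``.
    """

    kinship: str
    traits: tuple[str, ...]
    counts: np.ndarray
    exclusive: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise DataError("cross table must be square")
        if (self.counts < 0).any():
            raise DataError("negative cell count")
        if not np.allclose(self.counts, self.counts.T):
            raise DataError("cross table must be symmetric after unordered aggregation")

    @property
    def n_pairs(self) -> float:
        return float(self.counts.sum())

    @property
    def a_share(self) -> float:
        return KINSHIP_A_SHARE[self.kinship]

    @classmethod
    def from_categories(cls, cat_a, cat_b, k: int, kinship: str,
                        traits: tuple[str, ...], exclusive: bool = False) -> "PairCrossTable":
        cat_a = np.asarray(cat_a, dtype=np.int64)
        cat_b = np.asarray(cat_b, dtype=np.int64)
        m = np.bincount(cat_a * k + cat_b, minlength=k * k).reshape(k, k).astype(float)
        return cls(kinship, traits, (m + m.T) / 2.0, exclusive=exclusive)

    def margin(self) -> np.ndarray:
        """Person-level category proportions (averaged over pair members)."""
        return self.counts.sum(axis=1) / self.n_pairs

    def unordered_counts(self) -> np.ndarray:
        """Counts over unordered category pairs: diagonal as-is, upper
        triangle doubled (both orderings pooled)."""
        u = np.triu(self.counts * 2.0, k=1)
        u[np.diag_indices_from(u)] = np.diag(self.counts)
        return u


def person_categories(pair_df: pd.DataFrame, traits: list[str],
                      exclusive: bool = False) -> tuple[np.ndarray, np.ndarray, int]:
    """Encode per-person categories from a ``simulate_pairs``-style frame.

    One trait: 0/1.  Two exclusive traits: 0 none, 1 first trait, 2 second.
    Two non-exclusive traits: 0 none, 1 first only, 2 second only, 3 both.
    """
    if len(traits) == 1:
        t = traits[0]
        return (pair_df[f"{t}_a"].to_numpy(np.int64),
                pair_df[f"{t}_b"].to_numpy(np.int64), 2)
    t1, t2 = traits
    a1 = pair_df[f"{t1}_a"].to_numpy(np.int64)
    a2 = pair_df[f"{t2}_a"].to_numpy(np.int64)
    b1 = pair_df[f"{t1}_b"].to_numpy(np.int64)
    b2 = pair_df[f"{t2}_b"].to_numpy(np.int64)
    if exclusive:
        if ((a1 & a2) | (b1 & b2)).any():
            raise DataError(f"traits {t1}/{t2} marked exclusive but co-occur")
        return a1 + 2 * a2, b1 + 2 * b2, 3
    return a1 + 2 * a2, b1 + 2 * b2, 4


def cross_table(pair_df: pd.DataFrame, traits: list[str], kinship: str,
                exclusive: bool = False) -> PairCrossTable:
    cat_a, cat_b, k = person_categories(pair_df, traits, exclusive)
    return PairCrossTable.from_categories(cat_a, cat_b, k, kinship,
                                          tuple(traits), exclusive)


# --------------------------------------------------------------------------
# tetrachoric correlation
# --------------------------------------------------------------------------

@dataclass
class TetrachoricResult:
    rho: float
    se: float
    z1: float
    z2: float
    n: float
    boundary: bool = False


def tetrachoric(table: np.ndarray, n: float | None = None,
                prevalence_constraint: tuple[float, float] | None = None,
                tol: float = 1e-10) -> TetrachoricResult:
    """Latent correlation from a 2x2 table of dichotomised indicators.

    Solves P(X > z1, Y > z2; rho) = p11 by bracketed root-finding, where
    the thresholds come from the table margins (or from
    ``prevalence_constraint`` when the population prevalences are known).
    The SE is the delta-method value sqrt(p11 (1-p11) / n) / phi2(z1, z2,
    rho), treating the thresholds as fixed.  A zero concordant or
    discordant cell gives the corresponding boundary estimate with
    ``boundary=True``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise DataError("tetrachoric needs a 2x2 table")
    total = t.sum()
    if total <= 0:
        raise DataError("empty 2x2 table")
    n = float(n if n is not None else total)
    p1 = t[1].sum() / total
    p2 = t[:, 1].sum() / total
    if min(p1, p2) <= 0 or max(p1, p2) >= 1:
        raise DataError("a margin of the 2x2 table is empty")
    if prevalence_constraint is not None:
        k1, k2 = prevalence_constraint
        z1, z2 = float(ndtri(1 - k1)), float(ndtri(1 - k2))
    else:
        z1, z2 = float(ndtri(1 - p1)), float(ndtri(1 - p2))
    p11 = t[1, 1] / total

    lo_lim = max(0.0, p1 + p2 - 1.0)  # P11 at rho = -1
    hi_lim = min(p1, p2)              # P11 at rho = +1
    if p11 <= lo_lim + 1e-300 and t[1, 1] == 0:
        return TetrachoricResult(-1.0, np.nan, z1, z2, n, boundary=True)
    if p11 >= hi_lim - 1e-300 and (t[0, 1] == 0 or t[1, 0] == 0):
        return TetrachoricResult(1.0, np.nan, z1, z2, n, boundary=True)

    f = lambda r: float(bvn_sf(z1, z2, r)) - p11
    lo, hi = -1.0 + 1e-12, 1.0 - 1e-12
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:  # p11 outside attainable range (rounding)
        rho = -1.0 if flo > 0 else 1.0
        return TetrachoricResult(rho, np.nan, z1, z2, n, boundary=True)
    rho = brentq(f, lo, hi, xtol=tol)
    dens = float(bvn_pdf(z1, z2, rho))
    se = float(np.sqrt(p11 * (1.0 - p11) / n) / dens) if dens > 0 else np.inf
    return TetrachoricResult(float(rho), se, z1, z2, n)


def _tetra_from_cross(tab: PairCrossTable, which: tuple[int, int] | None = None,
                      **kw) -> TetrachoricResult:
    """Tetrachoric of a 2-category cross table (or of a 2x2 collapsed from
    a larger one by indicator categories)."""
    c = tab.counts
    if which is not None:
        i, j = which
        m = np.zeros((2, 2))
        idx_i = np.arange(c.shape[0]) == i
        idx_j = np.arange(c.shape[1]) == j
        m[1, 1] = c[idx_i][:, idx_j].sum()
        m[1, 0] = c[idx_i][:, ~idx_j].sum()
        m[0, 1] = c[~idx_i][:, idx_j].sum()
        m[0, 0] = c[~idx_i][:, ~idx_j].sum()
    else:
        m = c
    return tetrachoric(m, n=tab.n_pairs, **kw)


# --------------------------------------------------------------------------
# results container
# --------------------------------------------------------------------------

@dataclass
class LiabilityFit:
    """Fitted liability model: variance shares and/or genetic correlation."""

    model: str                       # "ACE" | "AE"
    estimator: str                   # "WLS" | "ML"
    params: dict[str, float]
    se: dict[str, float] = field(default_factory=dict)
    rg: float | None = None
    fit_statistic: float | None = None
    df: int | None = None
    loglike: float | None = None
    n_params: int = 0
    boundary: bool = False
    boot_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    details: dict = field(default_factory=dict)

    @property
    def a2(self):
        return self.params.get("a2")

    @property
    def c2(self):
        return self.params.get("c2", 0.0)

    @property
    def e2(self):
        return self.params.get("e2")

    def summary(self) -> str:
        lines = [f"{self.model} liability model ({self.estimator})"]
        for k, v in self.params.items():
            ci = self.boot_ci.get(k)
            tail = f"  [boot 95% CI {ci[0]:.4f}, {ci[1]:.4f}]" if ci else ""
            se = f" (SE {self.se[k]:.4f})" if k in self.se else ""
            lines.append(f"  {k:>4} = {v:.4f}{se}{tail}")
        if self.rg is not None:
            ci = self.boot_ci.get("rg")
            tail = f"  [boot 95% CI {ci[0]:.4f}, {ci[1]:.4f}]" if ci else ""
            se = f" (SE {self.se['rg']:.4f})" if "rg" in self.se else ""
            lines.append(f"    rg = {self.rg:.4f}{se}{tail}")
        if self.fit_statistic is not None:
            lines.append(f"  fit statistic = {self.fit_statistic:.4f} on {self.df} df")
        if self.loglike is not None:
            lines.append(f"  log-likelihood = {self.loglike:.2f}")
        if self.boundary:
            lines.append("  note: a parameter is at its boundary")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model, "estimator": self.estimator,
            "params": self.params, "se": self.se, "rg": self.rg,
            "fit_statistic": self.fit_statistic, "df": self.df,
            "loglike": self.loglike, "boundary": self.boundary,
            "boot_ci": {k: list(v) for k, v in self.boot_ci.items()},
            "n_boot": self.n_boot,
        }


# --------------------------------------------------------------------------
# ACE / AE by weighted least squares
# --------------------------------------------------------------------------

class AceLiabilityModel:
    """Univariate ACE / AE variance decomposition from kinship-class
    tetrachoric correlations (the full-sibling vs cousin contrast).

    Parameters
    ----------
    tetrachorics : mapping kinship -> TetrachoricResult (or -> 2x2 count
        table, converted internally).  At least two kinship classes are
        needed for ACE.
    kappa : shared-environment sharing assumed for half siblings.
    """

    def __init__(self, tetrachorics: dict, kappa: float = 0.0):
        self.tetra: dict[str, TetrachoricResult] = {}
        for kin, val in tetrachorics.items():
            if kin not in KINSHIP_A_SHARE:
                raise ConfigError(f"unknown kinship {kin!r}")
            if isinstance(val, TetrachoricResult):
                self.tetra[kin] = val
            elif isinstance(val, PairCrossTable):
                self.tetra[kin] = _tetra_from_cross(val)
            else:
                self.tetra[kin] = tetrachoric(np.asarray(val))
        self.kappa = kappa

    @classmethod
    def from_tables(cls, tables: dict[str, PairCrossTable], **kw) -> "AceLiabilityModel":
        return cls(tables, **kw)

    def _rows(self):
        kin = sorted(self.tetra)
        r = np.array([self.tetra[k].rho for k in kin])
        se = np.array([self.tetra[k].se for k in kin])
        a_sh = np.array([KINSHIP_A_SHARE[k] for k in kin])
        c_sh = np.array([{"full_sib": 1.0, "half_sib": self.kappa, "cousin": 0.0}[k]
                         for k in kin])
        if np.any(~np.isfinite(se)):
            raise DataError("a tetrachoric at the boundary has no finite SE; "
                            "cannot weight")
        return kin, r, se, a_sh, c_sh

    def fit(self, model: str = "AE", weights: np.ndarray | None = None) -> LiabilityFit:
        if model not in ("AE", "ACE"):
            raise ConfigError("model must be 'AE' or 'ACE'")
        kin, r, se, a_sh, c_sh = self._rows()
        if model == "ACE" and len(kin) < 2:
            raise DataError("ACE needs at least two kinship classes")
        w = np.asarray(weights, dtype=float) if weights is not None else 1.0 / se**2
        sw = np.sqrt(w)
        if model == "AE":
            A = (a_sh * sw)[:, None]
        else:
            A = np.column_stack([a_sh * sw, c_sh * sw])
        b = r * sw
        sol = lsq_linear(A, b, bounds=(0.0, 1.0))
        x = sol.x
        boundary = bool(np.any(x < 1e-9) or np.any(x > 1 - 1e-9))
        if model == "ACE" and x.sum() > 1.0:
            cons = ({"type": "ineq", "fun": lambda p: 1.0 - p.sum()},)
            res = minimize(lambda p: np.sum((A @ p - b) ** 2), x / x.sum(),
                           bounds=[(0, 1)] * A.shape[1], constraints=cons,
                           method="SLSQP")
            x = res.x
            boundary = True
        resid = A @ x - b
        stat = float(resid @ resid)
        a2 = float(x[0])
        c2 = float(x[1]) if model == "ACE" else 0.0
        # delta-method SE of the WLS solution (unconstrained formula)
        try:
            cov = np.linalg.inv(A.T @ A)
            se_par = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se_par = np.full(A.shape[1], np.nan)
        params = {"a2": a2, "c2": c2, "e2": float(1.0 - a2 - c2)}
        ses = {"a2": float(se_par[0])}
        if model == "ACE":
            ses["c2"] = float(se_par[1])
        return LiabilityFit(
            model=model, estimator="WLS", params=params, se=ses,
            fit_statistic=stat, df=len(kin) - A.shape[1],
            n_params=A.shape[1], boundary=boundary,
            details={"kinships": kin, "tetrachorics": list(r),
                     "tetrachoric_se": list(se)},
        )


# --------------------------------------------------------------------------
# genetic correlation
# --------------------------------------------------------------------------

class GeneticCorrelationModel:
    """Genetic correlation between two liability traits from full-sibling
    and cousin pair cross-tables.

    Marginal variance shares are fixed from univariate fits (two-stage, the
    default) or estimated jointly.  For non-exclusive traits the default
    estimator is WLS on the cross-trait cross-person tetrachorics, whose
    structural value is a_share * rg * sqrt(a2_1 a2_2); for mutually
    exclusive traits the estimator is maximum likelihood on the 3x3 pair
    outcome tables, with rectangle probabilities of the 4-dimensional
    liability normal.

    Parameters
    ----------
    tables : mapping kinship -> PairCrossTable (3x3 for exclusive pairs,
        4x4 for non-exclusive ones; built by :func:`cross_table`).
    marginals : {trait name: dict(a2=..., c2=0.0)} from univariate fits.
    exclusive : whether the two traits are mutually exclusive.
    winner : for exclusive pairs, the trait recorded when both latent
        diagnoses fire (default: the first trait).
    re_within : within-person unique-environment cross-trait correlation
        (unidentifiable for exclusive pairs; structural assumption).
    """

    def __init__(self, tables: dict[str, PairCrossTable], marginals: dict,
                 exclusive: bool = False, winner: str | None = None,
                 re_within: float = 0.0, kappa: float = 0.0):
        if not tables:
            raise DataError("no cross tables")
        self.tables = dict(tables)
        first = next(iter(self.tables.values()))
        self.trait_names = list(first.traits)
        if len(self.trait_names) != 2:
            raise DataError("genetic correlation needs exactly two traits")
        self.marginals = marginals
        self.exclusive = exclusive
        self.winner = winner or self.trait_names[0]
        if self.winner not in self.trait_names:
            raise ConfigError(f"winner {self.winner!r} not among traits")
        self.re_within = re_within
        self.kappa = kappa
        self._k = 3 if exclusive else 4

        for t in self.trait_names:
            if t not in marginals or "a2" not in marginals[t]:
                raise ConfigError(f"marginal a2 for trait {t!r} missing")

        # person-level margins pooled over kinship classes
        tot = sum(tab.counts.sum() for tab in self.tables.values())
        self.margin = sum(tab.counts.sum(axis=1) for tab in self.tables.values()) / tot

    # -- shared structure --------------------------------------------------
    def _a2(self, t):
        return float(self.marginals[t]["a2"])

    def _c2(self, t):
        return float(self.marginals[t].get("c2", 0.0))

    def _corr(self, rg: float, kinship: str) -> np.ndarray:
        t1, t2 = self.trait_names
        specs = [
            TraitSpec(t1, self._a2(t1), self._c2(t1),
                      1 - self._a2(t1) - self._c2(t1), 0.5),
            TraitSpec(t2, self._a2(t2), self._c2(t2),
                      1 - self._a2(t2) - self._c2(t2), 0.5),
        ]
        return pair_correlation_matrix(
            specs, {(t1, t2): rg}, {(t1, t2): self.re_within},
            KINSHIP_A_SHARE[kinship],
            {"full_sib": 1.0, "half_sib": self.kappa, "cousin": 0.0}[kinship],
        )

    def _r_within(self, rg: float) -> float:
        t1, t2 = self.trait_names
        e1 = 1 - self._a2(t1) - self._c2(t1)
        e2 = 1 - self._a2(t2) - self._c2(t2)
        return (rg * np.sqrt(self._a2(t1) * self._a2(t2))
                + self.re_within * np.sqrt(e1 * e2))

    # -- thresholds --------------------------------------------------------
    def _thresholds(self, rg: float) -> tuple[float, float]:
        """Latent thresholds reproducing the observed person-level margins."""
        if not self.exclusive:
            t1_m = self.margin[1] + self.margin[3]
            t2_m = self.margin[2] + self.margin[3]
            return float(ndtri(1 - t1_m)), float(ndtri(1 - t2_m))
        # winner margin is observed directly; the other solves
        # P(l_w <= z_w, l_o > z_o; r_within) = observed margin
        iw = self.trait_names.index(self.winner)
        m_w = self.margin[1 + iw]
        m_o = self.margin[2 - iw]
        z_w = float(ndtri(1 - m_w))
        rw = float(np.clip(self._r_within(rg), -0.999, 0.999))

        def f(z_o):
            return float(ndtr(z_w) - bvn_cdf(z_w, z_o, rw)) - m_o

        z_o = brentq(f, -8.0, 8.0, xtol=1e-12)
        if iw == 0:
            return z_w, float(z_o)
        return float(z_o), z_w

    def _cells(self, z1: float, z2: float) -> list[tuple[float, float, float, float]]:
        """Per-person 2-D liability rectangles for each observed category."""
        inf = np.inf
        if not self.exclusive:
            return [
                (-inf, z1, -inf, z2),   # none
                (z1, inf, -inf, z2),    # trait1 only
                (-inf, z1, z2, inf),    # trait2 only
                (z1, inf, z2, inf),     # both
            ]
        if self.trait_names.index(self.winner) == 0:
            return [
                (-inf, z1, -inf, z2),   # none
                (z1, inf, -inf, inf),   # winner (trait1) fires
                (-inf, z1, z2, inf),    # trait2 fires, trait1 does not
            ]
        return [
            (-inf, z1, -inf, z2),
            (z1, inf, -inf, z2),        # trait1 fires, winner does not
            (-inf, inf, z2, inf),       # winner (trait2) fires
        ]

    def category_probabilities(self, rg: float, kinship: str) -> np.ndarray:
        """Ordered k x k pair-category probabilities under the model."""
        z1, z2 = self._thresholds(rg)
        cells = self._cells(z1, z2)
        corr = self._corr(rg, kinship)
        ev = np.linalg.eigvalsh(corr)
        if ev.min() < 1e-10:
            raise np.linalg.LinAlgError("implied correlation matrix not PD")
        k = self._k
        P = np.empty((k, k))
        for i, cell in enumerate(cells):
            P[i] = mvn4_rect_multi(cell, cells, corr)
        return P / P.sum()

    def loglike(self, rg: float) -> float:
        ll = 0.0
        for kin, tab in self.tables.items():
            try:
                P = self.category_probabilities(rg, kin)
            except np.linalg.LinAlgError:
                return -1e10  # reject non-PSD candidates
            Ps = (P + P.T) / 2.0
            ll += float(np.sum(tab.counts * np.log(np.maximum(Ps, 1e-300))))
        return ll

    # -- estimators --------------------------------------------------------
    def fit(self, method: str | None = None, lrt: bool = True,
            joint_marginals: bool = False) -> LiabilityFit:
        if method is None:
            method = "ml" if self.exclusive else "wls"
        if method == "wls":
            return self._fit_wls()
        if method == "ml":
            return self._fit_ml(lrt=lrt, joint_marginals=joint_marginals)
        raise ConfigError(f"unknown method {method!r}")

    def _fit_wls(self) -> LiabilityFit:
        if self.exclusive:
            raise ConfigError("WLS cross-trait estimator requires non-exclusive "
                              "traits; use method='ml'")
        t1, t2 = self.trait_names
        prod = np.sqrt(self._a2(t1) * self._a2(t2))
        if prod <= 0:
            raise DataError("zero marginal heritability; rg undefined")
        num = den = 0.0
        rows = {}
        for kin, tab in self.tables.items():
            # indicator: trait1 in one member (cats 1,3) x trait2 in the other
            c = tab.counts
            i1 = np.array([0, 1, 0, 1], bool)
            j2 = np.array([0, 0, 1, 1], bool)
            m = np.zeros((2, 2))
            m[1, 1] = c[i1][:, j2].sum()
            m[1, 0] = c[i1][:, ~j2].sum()
            m[0, 1] = c[~i1][:, j2].sum()
            m[0, 0] = c[~i1][:, ~j2].sum()
            tr = tetrachoric(m, n=tab.n_pairs)
            if not np.isfinite(tr.se):
                raise DataError(f"boundary cross-trait tetrachoric for {kin}")
            s = KINSHIP_A_SHARE[kin]
            w = 1.0 / tr.se**2
            num += w * s * tr.rho
            den += w * s**2
            rows[kin] = tr
        rg_raw = num / (den * prod)
        rg = float(np.clip(rg_raw, -1.0, 1.0))
        se_rg = float(1.0 / np.sqrt(den) / prod)
        stat = sum((1.0 / rows[k].se**2) * (rows[k].rho
                    - KINSHIP_A_SHARE[k] * rg * prod) ** 2 for k in rows)
        return LiabilityFit(
            model="AE" if all(self._c2(t) == 0 for t in self.trait_names) else "ACE",
            estimator="WLS",
            params={f"a2_{t}": self._a2(t) for t in self.trait_names},
            se={"rg": se_rg}, rg=rg, fit_statistic=float(stat),
            df=len(rows) - 1, n_params=1,
            boundary=bool(abs(rg_raw) > 1),
            details={"cross_tetrachorics": {k: (v.rho, v.se) for k, v in rows.items()}},
        )

    def _fit_ml(self, lrt: bool = True, joint_marginals: bool = False) -> LiabilityFit:
        if joint_marginals:
            return self._fit_ml_joint(lrt=lrt)
        res = minimize_scalar(lambda r: -self.loglike(r),
                              bounds=(-0.999, 0.999), method="bounded",
                              options={"xatol": 1e-5})
        rg = float(res.x)
        ll = -float(res.fun)
        # observed-information SE from the profile curvature
        h = 5e-3
        ll_p = self.loglike(min(rg + h, 0.999))
        ll_m = self.loglike(max(rg - h, -0.999))
        d2 = (ll_p - 2 * ll + ll_m) / h**2
        se = float(1.0 / np.sqrt(-d2)) if d2 < 0 else np.nan
        details = {}
        if lrt:
            for r0, name in ((0.0, "rg=0"), (0.999, "rg=1")):
                ll0 = self.loglike(r0)
                stat = max(0.0, 2.0 * (ll - ll0))
                details[f"lrt_{name}"] = {
                    "statistic": stat, "df": 1,
                    "p_value": float(chi2.sf(stat, 1)),
                }
        return LiabilityFit(
            model="AE" if all(self._c2(t) == 0 for t in self.trait_names) else "ACE",
            estimator="ML",
            params={f"a2_{t}": self._a2(t) for t in self.trait_names},
            se={"rg": se}, rg=rg, loglike=ll, n_params=1,
            boundary=bool(abs(rg) > 0.998),
            details=details,
        )

    def _fit_ml_joint(self, lrt: bool = True, n_starts: int = 3) -> LiabilityFit:
        """Joint ML over (rg, a2_1, a2_2) with logit-reparameterised bounds
        and multi-start to guard against local optima."""
        t1, t2 = self.trait_names
        base = dict(self.marginals)

        def unpack(x):
            return np.tanh(x[0]), 1 / (1 + np.exp(-x[1])), 1 / (1 + np.exp(-x[2]))

        def nll(x):
            rg, a1, a2_ = unpack(x)
            self.marginals = {t1: {"a2": a1}, t2: {"a2": a2_}}
            try:
                return -self.loglike(rg)
            finally:
                self.marginals = base

        starts = [np.array([np.arctanh(r0), 0.0, 0.0])
                  for r0 in (-0.3, 0.3, 0.7)][:n_starts]
        best = None
        for x0 in starts:
            r = minimize(nll, x0, method="Nelder-Mead",
                         options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
            if best is None or r.fun < best.fun:
                best = r
        rg, a1, a2_ = unpack(best.x)
        return LiabilityFit(
            model="AE", estimator="ML",
            params={f"a2_{t1}": float(a1), f"a2_{t2}": float(a2_)},
            rg=float(rg), loglike=-float(best.fun), n_params=3,
        )


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

def _family_count_matrices(pair_cats: pd.DataFrame, n_cat: int):
    """Per-family unordered-pair category count matrices, one per kinship."""
    fams = pair_cats["family_id"].unique()
    fam_index = pd.Series(np.arange(len(fams)), index=fams)
    out = {}
    k = n_cat
    for kin, sub in pair_cats.groupby("kinship"):
        i = np.minimum(sub["cat_a"], sub["cat_b"]).to_numpy(np.int64)
        j = np.maximum(sub["cat_a"], sub["cat_b"]).to_numpy(np.int64)
        cat = i * k + j
        rows = fam_index[sub["family_id"]].to_numpy()
        m = np.zeros((len(fams), k * k), dtype=np.float64)
        np.add.at(m, (rows, cat), 1.0)
        out[kin] = m
    return out, len(fams)


def _tables_from_unordered(vec: np.ndarray, k: int, kinship: str,
                           traits, exclusive) -> PairCrossTable:
    u = vec.reshape(k, k)
    sym = (u + u.T) / 2.0
    return PairCrossTable(kinship, tuple(traits), sym, exclusive=exclusive)


def bootstrap_fits(pair_cats: pd.DataFrame, n_cat: int, fit_fn,
                   n_boot: int = 1000, seed: int | None = None,
                   traits=("trait",), exclusive: bool = False) -> pd.DataFrame:
    """Family-clustered bootstrap of an arbitrary table-based fit.

    ``pair_cats`` has columns family_id, kinship, cat_a, cat_b; families
    are resampled with replacement jointly across kinship classes, the
    cross tables rebuilt, and ``fit_fn(tables) -> dict`` re-evaluated.
    Returns one row of parameter draws per replicate; reproducible given
    ``seed``.
    """
    mats, n_fam = _family_count_matrices(pair_cats, n_cat)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_fam, n_fam)
        tables = {}
        for kin, m in mats.items():
            vec = m[idx].sum(axis=0)
            tables[kin] = _tables_from_unordered(vec, n_cat, kin, traits, exclusive)
        try:
            rows.append(fit_fn(tables))
        except (DataError, np.linalg.LinAlgError):
            continue  # degenerate resample (e.g. empty margin)
    if not rows:
        raise DataError("all bootstrap replicates were degenerate")
    return pd.DataFrame(rows)


def percentile_ci(draws: pd.DataFrame, level: float = 0.95) -> dict[str, tuple[float, float]]:
    alpha = 100 * (1 - level) / 2
    return {c: (float(np.percentile(draws[c], alpha)),
                float(np.percentile(draws[c], 100 - alpha)))
            for c in draws.columns}


# --------------------------------------------------------------------------
# model comparison
# --------------------------------------------------------------------------

def compare_models(fit_full: LiabilityFit, fit_reduced: LiabilityFit,
                   boundary_mixture: bool = False) -> dict:
    """Chi-square (WLS) or likelihood-ratio (ML) comparison of nested fits.

    With a variance parameter on its boundary under the null (c2 = 0), the
    asymptotic reference is a 50:50 mixture of chi2(0) and chi2(df);
    ``boundary_mixture=True`` halves the tail p accordingly.
    """
    if fit_full.estimator != fit_reduced.estimator:
        raise ConfigError("cannot compare fits from different estimators")
    df = fit_full.n_params - fit_reduced.n_params
    if df <= 0:
        raise ConfigError("fit_full must have more parameters than fit_reduced")
    if fit_full.estimator == "ML":
        if fit_full.loglike is None or fit_reduced.loglike is None:
            raise DataError("ML comparison needs log-likelihoods")
        stat = 2.0 * (fit_full.loglike - fit_reduced.loglike)
    else:
        stat = (fit_reduced.fit_statistic or 0.0) - (fit_full.fit_statistic or 0.0)
    stat = max(0.0, float(stat))
    p = float(chi2.sf(stat, df))
    if boundary_mixture:
        p = 0.5 * p if stat > 0 else 1.0
    return {"statistic": stat, "df": df, "p_value": min(p, 1.0),
            "boundary_mixture": boundary_mixture}


def rg_difference_test(boot_rg1: np.ndarray, boot_rg2: np.ndarray) -> dict:
    """Two-sided test of rg1 = rg2 from paired bootstrap replicate draws."""
    d = np.asarray(boot_rg1, float) - np.asarray(boot_rg2, float)
    if d.size < 2:
        raise DataError("need at least two bootstrap replicates")
    n = d.size
    p_low = (np.sum(d <= 0) + 1) / (n + 1)
    p_high = (np.sum(d >= 0) + 1) / (n + 1)
    return {"diff": float(np.mean(d)), "p_value": float(min(1.0, 2 * min(p_low, p_high))),
            "n_replicates": int(n)}
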