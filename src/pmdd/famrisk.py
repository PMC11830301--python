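"""Familial aggregation and co-aggregation odds ratios.

For each kinship class, the odds of a relative carrying an outcome
diagnosis given the proband's exposure status are estimated with a logistic
model whose point estimates coincide with GEE under an independence working
correlation; standard errors are cluster-sandwich over extended families,
which accounts for the both-orderings expansion (each unordered pair enters
once with each member as proband) and for multiple pairs per family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .exceptions import CollinearityError, DataError, SeparationError
from .meta import fixed_effect_meta

__all__ = [
    "AssocEstimate",
    "pair_dataset",
    "fit_cluster_logit",
    "FamilialAggregation",
    "bonferroni",
]

_Z95 = 1.959963984540054


@dataclass
class AssocEstimate:
    """A log-odds-ratio with cluster-robust uncertainty."""

    label: str
    log_or: float
    robust_se: float
    n_pairs: int = 0
    n_clusters: int = 0
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    p_value: float = field(init=False)

    def __post_init__(self):
        self.or_ = float(np.exp(self.log_or))
        self.ci_low = float(np.exp(self.log_or - _Z95 * self.robust_se))
        self.ci_high = float(np.exp(self.log_or + _Z95 * self.robust_se))
        self.p_value = float(2.0 * norm.sf(abs(self.log_or) / self.robust_se))

    def to_dict(self) -> dict:
        return {
            "label": self.label, "log_or": self.log_or, "robust_se": self.robust_se,
            "or": self.or_, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value, "n_pairs": self.n_pairs,
            "n_clusters": self.n_clusters,
        }


def pair_dataset(pairs: pd.DataFrame, exposure: pd.Series, outcome: pd.Series,
                 persons: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format rows: relative outcome ~ proband exposure.

    Each unordered pair contributes both orderings, so each member appears
    once as proband and once as relative; the family id is carried along as
    the clustering unit.  ``exposure`` and ``outcome`` are boolean Series
    indexed by person id (they may be the same phenotype for aggregation or
    different ones for co-aggregation).  If ``persons`` is given, the
    relative's sex and birth year are attached as covariates.
    """
    if (pairs["person_a"] == pairs["person_b"]).any():
        raise DataError("self-pairing: person_a equals person_b in pair table")
    rows = []
    for proband, relative in (("person_a", "person_b"), ("person_b", "person_a")):
        df = pd.DataFrame({
            "proband_id": pairs[proband].to_numpy(),
            "relative_id": pairs[relative].to_numpy(),
            "family_id": pairs["family_id"].to_numpy(),
        })
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out["exposure"] = exposure.astype(float).reindex(out["proband_id"]).fillna(0.0).to_numpy()
    out["outcome"] = outcome.astype(float).reindex(out["relative_id"]).fillna(0.0).to_numpy()
    if persons is not None:
        p = persons.set_index("person_id")
        out["sex_male"] = (p["sex"].reindex(out["relative_id"]) == "M").to_numpy(dtype=float)
        out["birth_year"] = p["birth_year"].reindex(out["relative_id"]).to_numpy(dtype=float)
    return out


def _design(dataset: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, "exposure": dataset["exposure"].to_numpy()})
    for cov in covariates:
        v = dataset[cov].to_numpy(dtype=float)
        if cov == "birth_year":
            v = v - v.mean()  # centred linear term
        X[cov] = v
    return X


def fit_cluster_logit(dataset: pd.DataFrame, covariates=(), label: str = "exposure",
                      cluster: str = "family_id") -> AssocEstimate:
    """Logistic ML point estimates with family-cluster sandwich SEs.

    Equivalent to GEE with an independence working correlation.  No
    small-sample correction is applied to the sandwich, so with one
    independent pair per family the SE equals the classical Woolf /
    binomial-variance logistic SE.
    """
    y = dataset["outcome"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise DataError("outcome has a single class; cannot fit")
    X = _design(dataset, covariates)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise CollinearityError(f"singular design; collinear columns: {bad}")
    groups = dataset[cluster].to_numpy()
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(cov_type="cluster",
                        cov_kwds={"groups": groups, "use_correction": False})
    if np.abs(res.params["exposure"]) > 30 or not np.isfinite(res.bse["exposure"]):
        raise SeparationError(
            "apparent separation in logistic fit (|log OR| > 30); penalised "
            "likelihood methods are out of scope here"
        )
    return AssocEstimate(
        label=label,
        log_or=float(res.params["exposure"]),
        robust_se=float(res.bse["exposure"]),
        n_pairs=len(dataset) // 2,
        n_clusters=int(len(np.unique(groups))),
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    cols = list(X.columns)
    bad = []
    kept: list[str] = []
    for c in cols:
        trial = kept + [c]
        if np.linalg.matrix_rank(X[trial].to_numpy()) < len(trial):
            bad.append(c)
        else:
            kept.append(c)
    return bad


class FamilialAggregation:
    """Familial (co-)aggregation model over a relative-pair dataset.

    Parameters
    ----------
    dataset : long-format pair rows from :func:`pair_dataset`.
    covariates : column names adjusted for (relative's sex indicator and
        centred birth year by default when present).

    ``fit()`` returns an :class:`AssocEstimate` for the proband-exposure
    log-OR with family-cluster sandwich SE.
    """

    def __init__(self, dataset: pd.DataFrame, covariates=None, label: str = "exposure"):
        if covariates is None:
            covariates = [c for c in ("sex_male", "birth_year") if c in dataset.columns]
        self.dataset = dataset
        self.covariates = tuple(covariates)
        self.label = label

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame, exposure: pd.Series, outcome: pd.Series,
                   persons: pd.DataFrame | None = None, kinship: str | None = None,
                   covariates=None, label: str | None = None) -> "FamilialAggregation":
        if kinship is not None:
            pairs = pairs.loc[pairs["kinship"] == kinship]
            if pairs.empty:
                raise DataError(f"no pairs of kinship {kinship!r}")
        ds = pair_dataset(pairs, exposure, outcome, persons=persons)
        return cls(ds, covariates=covariates, label=label or (kinship or "exposure"))

    def fit(self) -> AssocEstimate:
        return fit_cluster_logit(self.dataset, covariates=self.covariates,
                                 label=self.label)


def bonferroni(results: list[AssocEstimate], alpha: float = 0.05) -> pd.DataFrame:
    """Flag estimates significant at the Bonferroni-adjusted threshold
    alpha / number of tests."""
    if not results:
        raise DataError("no results to correct")
    thr = alpha / len(results)
    rows = [r.to_dict() | {"bonferroni_threshold": thr,
                           "significant": r.p_value < thr}
            for r in results]
    return pd.DataFrame(rows)


def meta_estimates(estimates: list[AssocEstimate], label: str = "meta") -> AssocEstimate:
    """Fixed-effect pooling of cohort log-ORs."""
    m = fixed_effect_meta([e.log_or for e in estimates],
                          [e.robust_se for e in estimates])
    return AssocEstimate(label=label, log_or=m.estimate, robust_se=m.se,
                         n_pairs=sum(e.n_pairs for e in estimates),
                         n_clusters=sum(e.n_clusters for e in estimates))
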