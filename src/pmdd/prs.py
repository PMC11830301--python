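"""Case-case polygenic-score association: psychotic vs non-psychotic MDD.

Scores are standardized to SD units within the analysis sample; per-SD
odds ratios come from logistic regression adjusted for sex, age and (when
present) genetic principal components, in univariate (one score at a time)
or joint (all scores mutually adjusted) mode.  Cohort estimates pool by
fixed-effect inverse-variance meta-analysis on the log-OR scale.

Upstream score construction (GWAS weights, LD-aware rescaling, MAF/INFO and
MHC filters) is out of scope: scores arrive as columns of a table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import CollinearityError, ConfigError, DataError, SeparationError
from .famrisk import AssocEstimate
from .meta import fixed_effect_meta

__all__ = ["standardize", "PrsCaseCase", "fit_prs_models", "meta_fixed"]

_BD_GUARD = ({"bd", "bd1"}, {"bd", "bd2"}, {"bd", "bd1", "bd2"})


def standardize(scores: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Mean-0, SD-1 columns (sample SD, ddof=1). Idempotent; a constant
    column raises."""
    out = scores.copy()
    cols = list(columns) if columns is not None else [
        c for c in scores.columns if np.issubdtype(scores[c].dtype, np.number)]
    for c in cols:
        sd = out[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DataError(f"score column {c!r} has zero variance")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


class PrsCaseCase:
    """Polygenic-score model for the psychotic vs non-psychotic contrast.

    Parameters
    ----------
    data : one row per MDD case with score columns, a binary label column
        (1 = psychotic), and covariates.
    scores : score column names.
    label : label column (default "psychotic").
    covariates : adjusted-for columns; "sex" is coded as a male indicator,
        anything else enters linearly.
    """

    def __init__(self, data: pd.DataFrame, scores, label: str = "psychotic",
                 covariates=("sex", "age")):
        missing = [c for c in list(scores) + [label] + list(covariates)
                   if c not in data.columns]
        if missing:
            raise ConfigError(f"missing columns: {missing}")
        self.scores = list(scores)
        self.label = label
        self.covariates = list(covariates)
        bad = [g for g in _BD_GUARD if g <= set(self.scores)]
        if bad:
            raise CollinearityError(
                "bipolar-disorder score and its subtype scores cannot enter one "
                f"joint model: {sorted(bad[0])}")
        y = data[label].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            raise DataError("both case classes must be present")
        self.data = standardize(data, columns=self.scores)
        self.y = y

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, scores, **kw) -> "PrsCaseCase":
        return cls(data, scores, **kw)

    def _design(self, score_cols) -> pd.DataFrame:
        X = pd.DataFrame({"const": np.ones(len(self.data))})
        for c in score_cols:
            X[c] = self.data[c].to_numpy(dtype=float)
        for c in self.covariates:
            if c == "sex":
                X["sex_male"] = (self.data[c] == "M").to_numpy(dtype=float)
            else:
                v = self.data[c].to_numpy(dtype=float)
                X[c] = v - v.mean()
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            from .famrisk import _collinear_columns
            raise CollinearityError(
                f"singular design; collinear columns: {_collinear_columns(X)}")
        return X

    def _fit_one(self, score_cols) -> dict[str, AssocEstimate]:
        X = self._design(score_cols)
        model = sm.Logit(self.y, X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(disp=0, maxiter=200)
            except Exception as err:  # statsmodels raises on perfect separation
                raise SeparationError(f"logistic fit failed: {err}") from err
        if np.any(np.abs(res.params[score_cols]) > 30):
            raise SeparationError("apparent separation (|log OR| > 30)")
        out = {}
        for c in score_cols:
            out[c] = AssocEstimate(label=c, log_or=float(res.params[c]),
                                   robust_se=float(res.bse[c]),
                                   n_pairs=len(self.y))
        return out

    def fit(self, mode: str = "joint") -> dict[str, AssocEstimate]:
        """Per-SD odds ratios: 'univariate' fits one score at a time,
        'joint' includes all scores simultaneously."""
        if mode == "joint":
            return self._fit_one(self.scores)
        if mode == "univariate":
            out = {}
            for c in self.scores:
                out[c] = self._fit_one([c])[c]
            return out
        raise ConfigError(f"unknown mode {mode!r}")


def fit_prs_models(data: pd.DataFrame, scores, mode: str = "joint",
                   comparator: str = "all_nonpsychotic",
                   label: str = "psychotic", severity_col: str = "severe",
                   covariates=("sex", "age")) -> dict[str, AssocEstimate]:
    """Functional wrapper.  ``comparator='severe_nonpsychotic'`` restricts
    the non-psychotic class to rows flagged in ``severity_col``."""
    if comparator not in ("all_nonpsychotic", "severe_nonpsychotic"):
        raise ConfigError(f"unknown comparator {comparator!r}")
    d = data
    if comparator == "severe_nonpsychotic":
        if severity_col not in d.columns:
            raise ConfigError(f"severity column {severity_col!r} missing")
        keep = (d[label] == 1) | (d[severity_col] == 1)
        d = d.loc[keep]
    return PrsCaseCase(d, scores, label=label, covariates=covariates).fit(mode=mode)


def meta_fixed(estimates: list[AssocEstimate], label: str = "meta") -> AssocEstimate:
    """Fixed-effect pooling of per-cohort per-SD log-ORs."""
    if len(estimates) == 1:
        e = estimates[0]
        return AssocEstimate(label=label, log_or=e.log_or, robust_se=e.robust_se,
                             n_pairs=e.n_pairs, n_clusters=e.n_clusters)
    m = fixed_effect_meta([e.log_or for e in estimates],
                          [e.robust_se for e in estimates])
    return AssocEstimate(label=label, log_or=m.estimate, robust_se=m.se,
                         n_pairs=sum(e.n_pairs for e in estimates))
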