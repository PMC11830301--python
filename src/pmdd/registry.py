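"""Synthetic population-register generator.

Emulates the linkage of a national patient register with a multi-generation
register: pedigrees with full-sibling / half-sibling / first-cousin links,
binary psychiatric diagnoses generated from a multivariate liability-threshold
model with configurable additive-genetic (A), shared-environment (C) and
unique-environment (E) variance shares, cross-trait genetic correlations,
mutually exclusive diagnosis assignment, diagnosis and censoring ages, ECT /
antipsychotic treatment codes, and standardized polygenic scores.  Every
generating parameter is known, so each downstream estimator can be checked
against ground truth.

Liabilities are produced by Mendelian transmission of additive-genetic
values (child = mid-parent + independent segregation noise with variance
1/2), which yields the classical expected liability correlations exactly:
0.5*a2 + c2 for full siblings, 0.25*a2 + kappa*c2 for half siblings and
0.125*a2 for first cousins.

Alongside the full pedigree generator there are direct pair-level
generators (`simulate_pairs`, `simulate_aggregation_pairs`,
`simulate_prs_casecase`) that produce relative pairs or case-case cohorts
at a given kinship without building pedigrees; these are what the
calibration experiments use.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtri
from scipy.optimize import brentq

from .exceptions import ConfigError, DataError, NotPositiveDefiniteError

__all__ = [
    "TraitSpec",
    "PrsSpec",
    "GeneratorConfig",
    "Population",
    "simulate_population",
    "simulate_pairs",
    "simulate_aggregation_pairs",
    "simulate_prs_casecase",
    "KINSHIP_A_SHARE",
]

KINSHIP_A_SHARE = {"full_sib": 0.5, "half_sib": 0.25, "cousin": 0.125}


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass
class TraitSpec:
    """One binary diagnosis generated from a latent liability.

    a2, c2, e2 are the liability variance shares (must sum to 1);
    ``prevalence`` the lifetime probability, giving the liability threshold
    z = Phi^-1(1 - prevalence).  ``exclusive_with`` names a trait that can
    never co-occur with this one in a person; ``exclusivity_rule`` names the
    trait that wins when both latent diagnoses fire.
    """

    name: str
    a2: float
    c2: float
    e2: float
    prevalence: float
    icd10_codes: tuple[str, ...] = ()
    exclusive_with: str | None = None
    exclusivity_rule: str | None = None

    def __post_init__(self):
        for label, v in (("a2", self.a2), ("c2", self.c2), ("e2", self.e2)):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"trait {self.name}: {label}={v} outside [0, 1]")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-12:
            raise ConfigError(
                f"trait {self.name}: a2+c2+e2 = {self.a2 + self.c2 + self.e2} != 1"
            )
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"trait {self.name}: prevalence {self.prevalence} outside (0,1)")

    @property
    def threshold(self) -> float:
        return float(ndtri(1.0 - self.prevalence))


@dataclass
class PrsSpec:
    """A standardized polygenic score column with a per-SD log-OR for the
    psychotic vs non-psychotic case-case contrast."""

    name: str
    log_or: float


def _default_traits() -> list[TraitSpec]:
    return [
        TraitSpec("psychotic_mdd", 0.3017, 0.0, 0.6983, 0.002,
                  ("F32.3", "F33.3"), exclusive_with="nonpsychotic_mdd",
                  exclusivity_rule="psychotic_mdd"),
        TraitSpec("nonpsychotic_mdd", 0.40, 0.0, 0.60, 0.05,
                  ("F32.1", "F33.1", "F32.2", "F33.2", "F32.0", "F33.0"),
                  exclusive_with="psychotic_mdd", exclusivity_rule="psychotic_mdd"),
        TraitSpec("scz_sad", 0.70, 0.0, 0.30, 0.01, ("F20", "F25")),
        TraitSpec("bd", 0.60, 0.0, 0.40, 0.02, ("F31",)),
    ]


def _default_rg() -> dict[tuple[str, str], float]:
    return {
        ("psychotic_mdd", "nonpsychotic_mdd"): 0.82,
        ("psychotic_mdd", "scz_sad"): 0.67,
        ("psychotic_mdd", "bd"): 0.64,
        ("nonpsychotic_mdd", "scz_sad"): 0.46,
        ("nonpsychotic_mdd", "bd"): 0.70,
        ("scz_sad", "bd"): 0.53,
    }


def _default_prs() -> list[PrsSpec]:
    return [
        PrsSpec("scz", float(np.log(1.23))),
        PrsSpec("bd", float(np.log(1.22))),
        PrsSpec("bd1", float(np.log(1.26))),
        PrsSpec("bd2", float(np.log(0.97))),
        PrsSpec("mdd", float(np.log(0.87))),
    ]


def _default_conversion() -> dict:
    # P(diagnosis code group present after / before the first MDD diagnosis),
    # per MDD subtype; magnitudes follow the registry descriptives the
    # generator emulates (see docs/methods.md)
    return {
        "psychotic_mdd": {"scz_sad": (0.03, 0.159), "bd": (0.04, 0.174),
                          "other_psychotic": (0.05, 0.219)},
        "nonpsychotic_mdd": {"scz_sad": (0.01, 0.035), "bd": (0.015, 0.06),
                             "other_psychotic": (0.01, 0.05)},
    }


def _default_treatment() -> dict:
    return {
        "psychotic_mdd": {"N05A": 0.7386, "9218": 0.1465},
        "nonpsychotic_mdd": {"N05A": 0.2392, "9218": 0.0186},
    }


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic registry draw."""

    n_families: int = 1000
    offspring_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.20, 2: 0.45, 3: 0.25, 4: 0.10})
    traits: list[TraitSpec] = field(default_factory=_default_traits)
    rg: dict[tuple[str, str], float] = field(default_factory=_default_rg)
    re: dict[tuple[str, str], float] = field(default_factory=dict)
    prs_specs: list[PrsSpec] = field(default_factory=_default_prs)
    prs_correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("bd", "bd1"): 0.7, ("bd", "bd2"): 0.5})
    prs_default_correlation: float = 0.3
    birth_year_range: tuple[int, int] = (1958, 1993)
    followup_end: int = 2013
    seed: int = 0
    half_sib_kappa: float = 0.0   # shared-environment fraction for half sibs
    half_sib_prob: float = 0.15   # chance the first parent has a second sibship
    censor_prob: float = 0.04
    conversion: dict = field(default_factory=_default_conversion)
    treatment: dict = field(default_factory=_default_treatment)
    onset_age_range: tuple[float, float] = (18.0, 45.0)

    def __post_init__(self):
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        tot = sum(self.offspring_distribution.values())
        if abs(tot - 1.0) > 1e-9 or min(self.offspring_distribution.values()) < 0:
            raise ConfigError("offspring_distribution must be a probability distribution")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate trait names")
        for pair, r in {**self.rg, **self.re}.items():
            if not -1.0 <= r <= 1.0:
                raise ConfigError(f"correlation {pair} = {r} outside [-1, 1]")
        if not 0.0 <= self.half_sib_kappa <= 1.0:
            raise ConfigError("half_sib_kappa outside [0, 1]")

    # symmetric lookups -----------------------------------------------------
    def rg_of(self, t1: str, t2: str) -> float:
        if t1 == t2:
            return 1.0
        return self.rg.get((t1, t2), self.rg.get((t2, t1), 0.0))

    def re_of(self, t1: str, t2: str) -> float:
        if t1 == t2:
            return 1.0
        return self.re.get((t1, t2), self.re.get((t2, t1), 0.0))

    def rg_matrix(self) -> np.ndarray:
        names = [t.name for t in self.traits]
        m = np.array([[self.rg_of(a, b) for b in names] for a in names])
        _check_psd(m, names, context="genetic correlation matrix")
        return m

    def re_matrix(self) -> np.ndarray:
        names = [t.name for t in self.traits]
        m = np.array([[self.re_of(a, b) for b in names] for a in names])
        _check_psd(m, names, context="unique-environment correlation matrix")
        return m

    def truth(self) -> dict:
        """Generating parameters, JSON-serialisable."""
        return {
            "traits": [dataclasses.asdict(t) | {"threshold": t.threshold}
                       for t in self.traits],
            "rg": {f"{a}|{b}": v for (a, b), v in self.rg.items()},
            "re": {f"{a}|{b}": v for (a, b), v in self.re.items()},
            "prs": {p.name: {"log_or": p.log_or, "or": float(np.exp(p.log_or))}
                    for p in self.prs_specs},
            "half_sib_kappa": self.half_sib_kappa,
            "seed": self.seed,
            "n_families": self.n_families,
        }


def _check_psd(m: np.ndarray, names: list[str], context: str) -> None:
    ev = np.linalg.eigvalsh(m)
    if ev.min() < -1e-9:
        off = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if m[i, j] != 0.0:
                    off.append(f"{names[i]}~{names[j]}={m[i, j]:g}")
        raise NotPositiveDefiniteError(
            f"{context} is not positive semi-definite "
            f"(min eigenvalue {ev.min():.3g}); entries: {', '.join(off)}"
        )


# --------------------------------------------------------------------------
# full pedigree generator
# --------------------------------------------------------------------------

@dataclass
class Population:
    """Output tables of one synthetic registry draw."""

    persons: pd.DataFrame
    diagnoses: pd.DataFrame
    treatments: pd.DataFrame
    prs: pd.DataFrame
    truth: dict

    def write(self, outdir) -> dict[str, str]:
        """Write TSV tables plus truth.json; returns {name: path}."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("persons", "diagnoses", "treatments", "prs"):
            p = out / f"{name}.tsv"
            getattr(self, name).to_csv(p, sep="\t", index=False)
            paths[name] = str(p)
        tp = out / "truth.json"
        tp.write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        paths["truth"] = str(tp)
        return paths


def _sample_sibship_sizes(rng, dist: dict[int, float], n: int) -> np.ndarray:
    sizes = np.array(sorted(dist))
    probs = np.array([dist[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(sizes, size=n, p=probs)


def simulate_population(config: GeneratorConfig) -> Population:
    """Generate a population of extended families.

    Each family: one grandparent couple, their two full-sib children, who
    marry unrelated spouses and produce two sibships (first cousins of each
    other); with probability ``half_sib_prob`` the first of those children
    has a further sibship with a second spouse (half siblings of sibship 1).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    traits = config.traits
    T = len(traits)
    Rg = config.rg_matrix()
    Re = config.re_matrix()
    Lg = np.linalg.cholesky(Rg + 1e-12 * np.eye(T))
    Le = np.linalg.cholesky(Re + 1e-12 * np.eye(T))
    a = np.array([t.a2 for t in traits])
    c = np.array([t.c2 for t in traits])
    e = np.array([t.e2 for t in traits])
    sqa, sqc, sqe = np.sqrt(a), np.sqrt(c), np.sqrt(e)
    kappa = config.half_sib_kappa

    F = config.n_families
    s1 = _sample_sibship_sizes(rng, config.offspring_distribution, F)
    s2 = _sample_sibship_sizes(rng, config.offspring_distribution, F)
    has_hs = rng.random(F) < config.half_sib_prob
    s3 = np.where(has_hs, _sample_sibship_sizes(rng, config.offspring_distribution, F), 0)

    # ------- person bookkeeping (vectorised construction) ----------------
    # per family: gp_f, gp_m, p1, p2, sp1, sp2 (+ sp3 if half-sib branch)
    n_adults = 6 + has_hs.astype(int)
    n_off = s1 + s2 + s3
    n_per_fam = n_adults + n_off
    fam_first = np.concatenate([[0], np.cumsum(n_per_fam)[:-1]])
    n_total = int(n_per_fam.sum())

    family_id = np.repeat(np.arange(F), n_per_fam)
    person_id = np.arange(n_total)

    role = np.empty(n_total, dtype="U8")
    father = np.full(n_total, -1, dtype=np.int64)
    mother = np.full(n_total, -1, dtype=np.int64)
    sibship = np.full(n_total, -1, dtype=np.int64)  # global sibship index for C

    # genetic values (n_total, T)
    g = np.zeros((n_total, T))

    def founders_g(n):
        return rng.standard_normal((n, T)) @ Lg.T

    # assign adults
    idx_gpf = fam_first
    idx_gpm = fam_first + 1
    idx_p1 = fam_first + 2
    idx_p2 = fam_first + 3
    idx_sp1 = fam_first + 4
    idx_sp2 = fam_first + 5
    idx_sp3 = np.where(has_hs, fam_first + 6, -1)

    for idx, r in ((idx_gpf, "gp_f"), (idx_gpm, "gp_m"), (idx_p1, "parent"),
                   (idx_p2, "parent"), (idx_sp1, "spouse"), (idx_sp2, "spouse")):
        role[idx] = r
    role[idx_sp3[has_hs]] = "spouse"

    g[idx_gpf] = founders_g(F)
    g[idx_gpm] = founders_g(F)
    g[idx_sp1] = founders_g(F)
    g[idx_sp2] = founders_g(F)
    g[idx_sp3[has_hs]] = founders_g(int(has_hs.sum()))
    # parents: mid-grandparent + segregation
    seg = rng.standard_normal((2 * F, T)) @ Lg.T * np.sqrt(0.5)
    g[idx_p1] = 0.5 * (g[idx_gpf] + g[idx_gpm]) + seg[:F]
    g[idx_p2] = 0.5 * (g[idx_gpf] + g[idx_gpm]) + seg[F:]
    father[idx_p1] = idx_gpf
    mother[idx_p1] = idx_gpm
    father[idx_p2] = idx_gpf
    mother[idx_p2] = idx_gpm

    # offspring blocks
    off_rows = []
    sib_counter = 0
    # vectorised per sibship slot: build index arrays
    for which, sizes, fa_idx, mo_idx in (
        (1, s1, idx_p1, idx_sp1),
        (2, s2, idx_p2, idx_sp2),
        (3, s3, idx_p1, idx_sp3),
    ):
        n_k = int(sizes.sum())
        if n_k == 0:
            continue
        fam_of = np.repeat(np.arange(F), sizes)
        offset_within = np.concatenate([np.arange(k) for k in sizes if k > 0])
        prior = {1: np.zeros(F, dtype=int), 2: s1, 3: s1 + s2}[which]
        rows = fam_first[fam_of] + n_adults[fam_of] + prior[fam_of] + offset_within
        fa = fa_idx[fam_of]
        mo = mo_idx[fam_of]
        father[rows] = fa
        mother[rows] = mo
        role[rows] = "child"
        seg = rng.standard_normal((n_k, T)) @ Lg.T * np.sqrt(0.5)
        g[rows] = 0.5 * (g[fa] + g[mo]) + seg
        # sibship ids: one per (family, slot)
        sib_ids = sib_counter + fam_of  # unique per family within slot
        sibship[rows] = sib_ids + {1: 0, 2: F, 3: 2 * F}[which]
        off_rows.append(rows)
    sib_counter = 3 * F

    # shared environment: per-sibship component; sibships 1 and 3 share the
    # kappa fraction through their common parent p1
    n_sib = 3 * F
    c_unique = rng.standard_normal((n_sib, T))
    c_parent = rng.standard_normal((F, T))  # p1's contribution
    c_env_by_sib = np.array(c_unique)
    if kappa > 0:
        for slot in (0, 2):  # sibships of p1
            rows = slice(slot * F, (slot + 1) * F)
            c_env_by_sib[rows] = (np.sqrt(kappa) * c_parent
                                  + np.sqrt(1.0 - kappa) * c_unique[rows])
    c_env = np.zeros((n_total, T))
    m = sibship >= 0
    c_env[m] = c_env_by_sib[sibship[m]]
    c_env[~m] = rng.standard_normal(((~m).sum(), T))

    e_env = rng.standard_normal((n_total, T)) @ Le.T

    liab = g * sqa + c_env * sqc + e_env * sqe

    thresholds = np.array([t.threshold for t in traits])
    affected = liab > thresholds  # (n_total, T)

    # exclusivity
    name_to_i = {t.name: i for i, t in enumerate(traits)}
    for t in traits:
        if t.exclusive_with is not None:
            i, j = name_to_i[t.name], name_to_i[t.exclusive_with]
            winner = name_to_i[t.exclusivity_rule or t.name]
            loser = j if winner == i else i
            both = affected[:, i] & affected[:, j]
            affected[both, loser] = False

    # demographics --------------------------------------------------------
    by_lo, by_hi = config.birth_year_range
    sex = rng.choice(np.array(["F", "M"]), size=n_total)
    birth_year = np.empty(n_total, dtype=int)
    is_child = role == "child"
    birth_year[is_child] = rng.integers(by_lo, by_hi + 1, size=int(is_child.sum()))
    is_parent_gen = (role == "parent") | (role == "spouse")
    birth_year[is_parent_gen] = rng.integers(by_lo - 32, by_lo - 18, size=int(is_parent_gen.sum()))
    is_gp = (role == "gp_f") | (role == "gp_m")
    birth_year[is_gp] = rng.integers(by_lo - 62, by_lo - 40, size=int(is_gp.sum()))
    sex[idx_gpf] = "M"
    sex[idx_gpm] = "F"
    # the two within-family parents are recorded as fathers, spouses as mothers
    sex[idx_p1] = "M"
    sex[idx_p2] = "M"
    sex[idx_sp1] = "F"
    sex[idx_sp2] = "F"
    sex[idx_sp3[has_hs]] = "F"

    censor_age = np.full(n_total, np.nan)
    cens = rng.random(n_total) < config.censor_prob
    censor_age[cens] = rng.uniform(0.0, 60.0, size=int(cens.sum()))

    father_col = pd.Series(father, dtype="Int64").mask(pd.Series(father) < 0)
    mother_col = pd.Series(mother, dtype="Int64").mask(pd.Series(mother) < 0)
    persons = pd.DataFrame({
        "person_id": person_id,
        "family_id": family_id,
        "sex": sex,
        "birth_year": birth_year,
        "father_id": father_col,
        "mother_id": mother_col,
        "age_at_death_or_emigration": censor_age,
        "role": role,
    })

    # diagnoses -----------------------------------------------------------
    diagnoses = _emit_diagnoses(rng, config, persons, affected, name_to_i)

    # treatments ----------------------------------------------------------
    treatments = _emit_treatments(rng, config, affected, name_to_i)

    # PRS -----------------------------------------------------------------
    prs = _emit_prs(rng, config, affected, name_to_i)

    return Population(persons=persons, diagnoses=diagnoses, treatments=treatments,
                      prs=prs, truth=config.truth())


def _onset_age(rng, config, n, birth_years):
    lo, hi = config.onset_age_range
    max_age = np.maximum(config.followup_end - birth_years, lo + 1.0)
    return rng.uniform(lo, np.minimum(hi, max_age), size=n)


_OTHER_PSYCHOTIC_CODES = ("F22", "F23", "F28", "F29")
_CONVERSION_CODES = {"scz_sad": ("F20", "F25"), "bd": ("F31",),
                     "other_psychotic": _OTHER_PSYCHOTIC_CODES}


def _emit_diagnoses(rng, config, persons, affected, name_to_i) -> pd.DataFrame:
    rows_pid, rows_code, rows_age = [], [], []
    birth_year = persons["birth_year"].to_numpy()
    mdd_traits = [t for t in config.traits if t.name in config.conversion]
    is_mdd_case = np.zeros(len(persons), dtype=bool)
    for t in mdd_traits:
        is_mdd_case |= affected[:, name_to_i[t.name]]

    # MDD subtype index diagnoses
    for t in config.traits:
        idx = np.flatnonzero(affected[:, name_to_i[t.name]])
        if idx.size == 0 or not t.icd10_codes:
            continue
        if t.name in config.conversion:
            ages = _onset_age(rng, config, idx.size, birth_year[idx])
            codes = rng.choice(np.array(t.icd10_codes), size=idx.size)
            rows_pid.append(idx)
            rows_code.append(codes)
            rows_age.append(ages)
        else:
            # non-MDD disorder traits: emitted only for non-MDD persons; MDD
            # cases get their comorbid codes from the conversion mechanism
            keep = idx[~is_mdd_case[idx]]
            if keep.size:
                ages = _onset_age(rng, config, keep.size, birth_year[keep])
                codes = rng.choice(np.array(t.icd10_codes), size=keep.size)
                rows_pid.append(keep)
                rows_code.append(codes)
                rows_age.append(ages)

    # conversion diagnoses for MDD cases, timed before/after the index age
    index_age = np.full(len(persons), np.nan)
    for pid, age in zip(rows_pid, rows_age):
        # the loop above emits one index diagnosis per MDD case first
        index_age[pid] = np.where(np.isnan(index_age[pid]), age, np.fmin(index_age[pid], age))
    for t in mdd_traits:
        case_idx = np.flatnonzero(affected[:, name_to_i[t.name]])
        rules = config.conversion[t.name]
        for group, (p_before, p_after) in rules.items():
            codes = np.array(_CONVERSION_CODES[group])
            for prob, side in ((p_before, "before"), (p_after, "after")):
                hit = case_idx[rng.random(case_idx.size) < prob]
                if hit.size == 0:
                    continue
                base = index_age[hit]
                if side == "before":
                    ages = np.maximum(base - rng.uniform(0.5, 10.0, hit.size), 1.0)
                else:
                    ages = base + rng.uniform(0.5, 10.0, hit.size)
                rows_pid.append(hit)
                rows_code.append(rng.choice(codes, size=hit.size))
                rows_age.append(ages)

    if rows_pid:
        out = pd.DataFrame({
            "person_id": np.concatenate(rows_pid),
            "icd10": np.concatenate(rows_code),
            "age": np.round(np.concatenate(rows_age), 3),
        }).sort_values(["person_id", "age"], kind="mergesort").reset_index(drop=True)
    else:
        out = pd.DataFrame({"person_id": [], "icd10": [], "age": []})
    return out


def _emit_treatments(rng, config, affected, name_to_i) -> pd.DataFrame:
    rows_pid, rows_code = [], []
    for trait, rules in config.treatment.items():
        if trait not in name_to_i:
            continue
        idx = np.flatnonzero(affected[:, name_to_i[trait]])
        for code, p in rules.items():
            hit = idx[rng.random(idx.size) < p]
            rows_pid.append(hit)
            rows_code.append(np.full(hit.size, code))
    if rows_pid:
        pid = np.concatenate(rows_pid)
        out = pd.DataFrame({
            "person_id": pid,
            "code": np.concatenate(rows_code),
            "age": np.round(rng.uniform(18, 60, size=pid.size), 3),
        }).sort_values(["person_id", "code"], kind="mergesort").reset_index(drop=True)
    else:
        out = pd.DataFrame({"person_id": [], "code": [], "age": []})
    return out


def _prs_cov(config) -> tuple[list[str], np.ndarray]:
    names = [p.name for p in config.prs_specs]
    S = np.full((len(names), len(names)), config.prs_default_correlation)
    np.fill_diagonal(S, 1.0)
    for (a, b), r in config.prs_correlations.items():
        if a in names and b in names:
            i, j = names.index(a), names.index(b)
            S[i, j] = S[j, i] = r
    _check_psd(S, names, context="PRS correlation matrix")
    return names, S


def _emit_prs(rng, config, affected, name_to_i) -> pd.DataFrame:
    """Scores for MDD cases via the Gaussian-discriminant construction.

    With class-conditional score means differing by delta = S beta (common
    covariance S), a logistic refit of psychotic vs non-psychotic on the
    scores recovers approximately the per-SD log-ORs beta.
    """
    if not config.prs_specs:
        return pd.DataFrame({"person_id": []})
    names, S = _prs_cov(config)
    beta = np.array([p.log_or for p in config.prs_specs])
    psych = affected[:, name_to_i["psychotic_mdd"]] if "psychotic_mdd" in name_to_i \
        else np.zeros(affected.shape[0], bool)
    nonpsych = affected[:, name_to_i["nonpsychotic_mdd"]] if "nonpsychotic_mdd" in name_to_i \
        else np.zeros(affected.shape[0], bool)
    cases = np.flatnonzero(psych | nonpsych)
    if cases.size == 0:
        return pd.DataFrame({"person_id": []})
    L = np.linalg.cholesky(S + 1e-12 * np.eye(len(names)))
    scores = rng.standard_normal((cases.size, len(names))) @ L.T
    delta = S @ beta
    pi = psych[cases].mean()
    scores[psych[cases]] += delta * (1.0 - pi)
    scores[~psych[cases]] -= delta * pi
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    out = pd.DataFrame(scores, columns=names)
    out.insert(0, "person_id", cases)
    return out


# --------------------------------------------------------------------------
# direct pair-level generators
# --------------------------------------------------------------------------

def pair_correlation_matrix(traits: list[TraitSpec], rg, re, a_share: float,
                            c_share: float) -> np.ndarray:
    """Implied correlation matrix of (liab_t1_a, liab_t2_a, ..., _b) for a
    relative pair with additive sharing a_share and C sharing c_share.

    rg / re may be dicts keyed by trait-name pairs or full matrices.
    """
    T = len(traits)
    names = [t.name for t in traits]

    def look(d, i, j):
        if isinstance(d, np.ndarray):
            return d[i, j]
        if i == j:
            return 1.0
        a, b = names[i], names[j]
        return d.get((a, b), d.get((b, a), 0.0))

    # within-person: rg sqrt(a2 a2') + re sqrt(e2 e2'); cross-person:
    # a_share rg sqrt(a2 a2') + c_share sqrt(c2 c2') 1{same trait}
    # (cross-trait shared-environment correlation taken as 0)
    W = np.eye(T)
    C = np.zeros((T, T))
    for i in range(T):
        for j in range(T):
            ti, tj = traits[i], traits[j]
            ga = look(rg, i, j) * np.sqrt(ti.a2 * tj.a2)
            if i != j:
                W[i, j] = ga + look(re, i, j) * np.sqrt(ti.e2 * tj.e2)
            C[i, j] = a_share * ga + (c_share * np.sqrt(ti.c2 * tj.c2) if i == j else 0.0)
    full = np.block([[W, C], [C.T, W]])
    labels = [f"{n}_a" for n in names] + [f"{n}_b" for n in names]
    _check_psd(full, labels, context="implied pair liability correlation matrix")
    return full


def simulate_pairs(n_pairs: int, kinship: str, traits: list[TraitSpec],
                   rg=None, re=None, seed: int | None = None,
                   kappa: float = 0.0, chunk: int = 1 << 20) -> pd.DataFrame:
    """Draw relative pairs of one kinship class directly from the joint
    liability normal (vectorised, chunked).

    Returns a DataFrame with one uint8 column per trait and person:
    ``<trait>_a``, ``<trait>_b``; mutually exclusive assignment applied.
    """
    if kinship not in KINSHIP_A_SHARE:
        raise ConfigError(f"unknown kinship {kinship!r}")
    a_share = KINSHIP_A_SHARE[kinship]
    c_share = {"full_sib": 1.0, "half_sib": kappa, "cousin": 0.0}[kinship]
    rg = rg if rg is not None else {}
    re = re if re is not None else {}
    corr = pair_correlation_matrix(traits, rg, re, a_share, c_share)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    thr = np.array([t.threshold for t in traits])
    T = len(traits)

    rng = np.random.default_rng(seed)
    cols = {f"{t.name}_{s}": np.empty(n_pairs, dtype=np.uint8)
            for s in ("a", "b") for t in traits}
    done = 0
    while done < n_pairs:
        m = min(chunk, n_pairs - done)
        z = rng.standard_normal((m, 2 * T)) @ L.T
        aff = z > np.concatenate([thr, thr])
        aff = _apply_exclusivity_pairwise(aff, traits)
        for i, t in enumerate(traits):
            cols[f"{t.name}_a"][done:done + m] = aff[:, i]
            cols[f"{t.name}_b"][done:done + m] = aff[:, T + i]
        done += m
    df = pd.DataFrame(cols)
    df.attrs["kinship"] = kinship
    df.attrs["a_share"] = a_share
    df.attrs["c_share"] = c_share
    return df


def _apply_exclusivity_pairwise(aff: np.ndarray, traits: list[TraitSpec]) -> np.ndarray:
    T = len(traits)
    name_to_i = {t.name: i for i, t in enumerate(traits)}
    for t in traits:
        if t.exclusive_with is not None and t.exclusive_with in name_to_i:
            i, j = name_to_i[t.name], name_to_i[t.exclusive_with]
            winner = name_to_i.get(t.exclusivity_rule or t.name, i)
            loser = j if winner == i else i
            for off in (0, T):
                both = aff[:, off + i] & aff[:, off + j]
                aff[both, off + loser] = False
    return aff


def simulate_aggregation_pairs(n_pairs: int, prevalence: float, odds_ratio: float,
                               seed: int | None = None) -> pd.DataFrame:
    """Relative pairs from a direct odds-multiplier mechanism.

    One pair member ("proband") is affected with the baseline prevalence;
    the other member's odds of being affected are multiplied by
    ``odds_ratio`` when the proband is affected.  The joint 2x2 cross-product
    ratio equals ``odds_ratio`` exactly.  Each pair is its own family.
    """
    if not 0 < prevalence < 1:
        raise ConfigError("prevalence outside (0, 1)")
    if odds_ratio <= 0:
        raise ConfigError("odds_ratio must be > 0")
    rng = np.random.default_rng(seed)
    proband = rng.random(n_pairs) < prevalence
    p_rel = expit(logit(prevalence) + np.log(odds_ratio) * proband)
    relative = rng.random(n_pairs) < p_rel
    idx = np.arange(n_pairs)
    return pd.DataFrame({
        "person_a": 2 * idx,
        "person_b": 2 * idx + 1,
        "family_id": idx,
        "kinship": "full_sib",
        "affected_a": proband.astype(np.uint8),
        "affected_b": relative.astype(np.uint8),
    })


def simulate_prs_casecase(n_cases: int, specs: list[PrsSpec],
                          score_corr: float | np.ndarray = 0.0,
                          psychotic_fraction: float = 0.05,
                          sex_log_or: float = 0.2, age_log_or: float = 0.01,
                          seed: int | None = None, max_retries: int = 10) -> pd.DataFrame:
    """MDD cases with a psychotic / non-psychotic label drawn from a logistic
    model on standardized scores plus sex and age covariates.

    The logistic intercept is solved so the expected psychotic fraction
    matches ``psychotic_fraction``.  A large-sample refit recovers the
    generating per-SD ORs.
    """
    if n_cases < 2:
        raise ConfigError("n_cases must be >= 2")
    names = [s.name for s in specs]
    beta = np.array([s.log_or for s in specs])
    k = len(specs)
    if np.isscalar(score_corr):
        S = np.full((k, k), float(score_corr))
        np.fill_diagonal(S, 1.0)
    else:
        S = np.asarray(score_corr, dtype=float)
    _check_psd(S, names, context="PRS correlation matrix")
    L = np.linalg.cholesky(S + 1e-12 * np.eye(k))
    rng = np.random.default_rng(seed)

    for attempt in range(max_retries):
        scores = rng.standard_normal((n_cases, k)) @ L.T
        female = rng.random(n_cases) < 0.63
        age = rng.normal(55.0, 8.0, size=n_cases)
        eta = scores @ beta + sex_log_or * female + age_log_or * (age - 55.0)

        def frac(c):
            return expit(c + eta).mean() - psychotic_fraction

        c0 = brentq(frac, -30.0, 30.0, xtol=1e-10)
        label = rng.random(n_cases) < expit(c0 + eta)
        if 0 < label.sum() < n_cases:
            df = pd.DataFrame(scores, columns=names)
            df["sex"] = np.where(female, "F", "M")
            df["age"] = np.round(age, 3)
            df["psychotic"] = label.astype(np.uint8)
            df.insert(0, "person_id", np.arange(n_cases))
            return df
        warnings.warn("degenerate case-case draw (single class); regenerating")
    raise DataError(f"all {max_retries} case-case draws were single-class")
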