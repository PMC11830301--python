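"""Phenotype definition, eligibility filtering, relative-pair extraction and
cohort descriptives for registry-shaped data.

Phenotypes are defined from ICD-10 diagnosis codes by prefix matching on
dot-normalised strings ("F323" and "f32.3" both normalise to "F32.3").
The main definition labels any carrier of a psychotic-MDD code as psychotic
MDD and all other MDD-code carriers as non-psychotic MDD; the restrictive
definition additionally removes bipolar-disorder carriers from all MDD and
schizophrenia/schizoaffective carriers from psychotic MDD.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, DataError
from .registry import KINSHIP_A_SHARE

__all__ = [
    "CodeSet",
    "load_codesets",
    "normalize_code",
    "classify_mdd",
    "apply_eligibility",
    "extract_pairs",
    "conversion_table",
    "descriptives",
    "summarize_counts",
]

log = logging.getLogger(__name__)

_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")


def normalize_code(code: str) -> str:
    """Uppercase, dot-normalised ICD-10 code ('f323' -> 'F32.3')."""
    c = str(code).strip().upper().replace(".", "")
    if len(c) > 3:
        c = c[:3] + "." + c[3:]
    return c


@dataclass(frozen=True)
class CodeSet:
    """A named set of ICD code prefixes."""

    name: str
    icd10: tuple[str, ...]
    icd89: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.icd10:
            raise ConfigError(f"code set {self.name!r} is empty")
        norm = tuple(normalize_code(c) for c in self.icd10)
        object.__setattr__(self, "icd10", norm)
        for c in norm:
            if not _ICD10_RE.match(c):
                raise ConfigError(f"code set {self.name!r}: bad ICD-10 prefix {c!r}")

    def matches(self, codes: pd.Series) -> pd.Series:
        """Boolean mask of (already normalised) codes matching any prefix."""
        pat = "|".join(re.escape(p) for p in self.icd10)
        return codes.str.match(f"(?:{pat})")


def load_codesets(path=None) -> dict[str, CodeSet]:
    """Load code sets from YAML (defaults shipped with the package)."""
    if path is None:
        text = (importlib.resources.files("pmdd") / "data" / "codes.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: CodeSet(name, tuple(spec["icd10"]), tuple(spec.get("icd89", ())))
            for name, spec in raw.items()}


def _normalized_diagnoses(diagnoses: pd.DataFrame) -> pd.DataFrame:
    d = diagnoses.copy()
    d["icd10"] = d["icd10"].map(normalize_code)
    bad = d.loc[~d["icd10"].str.match(_ICD10_RE.pattern), "icd10"].unique()
    if len(bad):
        raise DataError(
            "unrecognised diagnosis codes (expected ICD-10 strings): "
            + ", ".join(map(repr, bad[:20]))
        )
    return d


def classify_mdd(diagnoses: pd.DataFrame, codesets: dict[str, CodeSet],
                 definition: str = "main",
                 psychotic_set: str = "psychotic_mdd") -> pd.Series:
    """Label every person appearing in the diagnosis table.

    Returns a Series indexed by person_id with values in
    {'none', 'non_psychotic_mdd', 'psychotic_mdd'} (mutually exclusive,
    exhaustive over diagnosed persons).
    """
    if definition not in ("main", "restrictive"):
        raise ConfigError(f"unknown definition {definition!r}")
    d = _normalized_diagnoses(diagnoses)
    mdd = codesets["mdd"]
    psy = codesets[psychotic_set]

    has = {}
    for name, cs in (("mdd", mdd), ("psy", psy),
                     ("bd", codesets["bd"]), ("scz", codesets["scz_sad"])):
        ids = d.loc[cs.matches(d["icd10"]), "person_id"]
        has[name] = set(ids)

    persons = d["person_id"].unique()
    labels = pd.Series("none", index=pd.Index(persons, name="person_id"), name="label")
    is_mdd = labels.index.isin(has["mdd"])
    is_psy = labels.index.isin(has["psy"])
    labels[is_mdd & ~is_psy] = "non_psychotic_mdd"
    labels[is_psy] = "psychotic_mdd"

    if definition == "restrictive":
        is_bd = labels.index.isin(has["bd"])
        is_scz = labels.index.isin(has["scz"])
        labels[is_bd] = "none"  # BD excluded from all MDD
        labels[(labels == "psychotic_mdd").to_numpy() & is_scz] = "none"
    return labels


def apply_eligibility(persons: pd.DataFrame, birth_window: tuple[int, int] | None = None,
                      min_followup_age: float = 20.0) -> pd.DataFrame:
    """Drop persons born outside the window or censored (death/emigration)
    before the minimum follow-up age; null censoring ages are retained."""
    n0 = len(persons)
    keep = pd.Series(True, index=persons.index)
    if birth_window is not None:
        lo, hi = birth_window
        keep &= persons["birth_year"].between(lo, hi)
    age = persons["age_at_death_or_emigration"]
    keep &= age.isna() | (age >= min_followup_age)
    out = persons.loc[keep].reset_index(drop=True)
    log.info("eligibility: kept %d of %d persons (%d removed)", len(out), n0, n0 - len(out))
    return out


def _check_acyclic(persons: pd.DataFrame) -> None:
    import networkx as nx

    g = nx.DiGraph()
    for col in ("father_id", "mother_id"):
        sub = persons[["person_id", col]].dropna()
        g.add_edges_from(zip(sub[col].astype(np.int64), sub["person_id"]))
    if g.number_of_edges() and not nx.is_directed_acyclic_graph(g):
        raise DataError("pedigree contains a cycle (a person is their own ancestor)")


def extract_pairs(persons: pd.DataFrame, max_birth_gap: int = 10,
                  half_sib_kappa: float = 0.0) -> pd.DataFrame:
    """Full-sib, half-sib and first-cousin pairs from parent links.

    Full sibs share both parents, half sibs exactly one known parent, and
    cousins have parents who are full sibs.  Sibling pairs (full and half)
    born more than ``max_birth_gap`` years apart are dropped; the gap filter
    is not applied to cousins.  Each unordered pair appears once
    (person_a < person_b).
    """
    _check_acyclic(persons)
    p = persons.set_index("person_id")
    ids = p.index.to_numpy()
    father = p["father_id"]
    mother = p["mother_id"]
    by = p["birth_year"]
    fam = p["family_id"] if "family_id" in p.columns else None

    def _pairs_within(groups: pd.core.groupby.SeriesGroupBy):
        out = []
        for _, members in groups:
            m = members.to_numpy()
            if len(m) > 1:
                i, j = np.triu_indices(len(m), k=1)
                out.append(np.column_stack([m[i], m[j]]))
        return np.concatenate(out) if out else np.empty((0, 2), dtype=np.int64)

    known = father.notna() & mother.notna()
    couples = pd.Series(
        list(zip(father[known].astype(np.int64), mother[known].astype(np.int64))),
        index=p.index[known],
    )
    sib_groups = couples.index.to_series().groupby(couples)
    fs = _pairs_within(sib_groups)

    # half sibs: share exactly one known parent
    rows = []
    for parent_col, other_col in ((father, mother), (mother, father)):
        sub = parent_col.dropna()
        groups = sub.index.to_series().groupby(sub.astype(np.int64))
        cand = _pairs_within(groups)
        for x, y in cand:
            ox, oy = other_col.get(x), other_col.get(y)
            if pd.isna(ox) or pd.isna(oy) or ox != oy:
                rows.append((min(x, y), max(x, y)))
    hs = np.array(sorted(set(rows)), dtype=np.int64).reshape(-1, 2)

    # cousins: parents are full sibs (and the pair is not itself sib/half-sib)
    fs_set = {frozenset(t) for t in fs}
    hs_set = {frozenset(t) for t in hs}
    children_of: dict[int, list[int]] = {}
    for child, (fa, mo) in couples.items():
        children_of.setdefault(fa, []).append(child)
        children_of.setdefault(mo, []).append(child)
    cz_rows = set()
    for x, y in fs:
        kids_x = {k for par in (x,) for k in children_of.get(par, [])}
        kids_y = {k for par in (y,) for k in children_of.get(par, [])}
        for kx in kids_x:
            for ky in kids_y:
                if kx == ky:
                    continue
                key = frozenset((kx, ky))
                if key in fs_set or key in hs_set:
                    continue
                cz_rows.add((min(kx, ky), max(kx, ky)))
    cz = np.array(sorted(cz_rows), dtype=np.int64).reshape(-1, 2)

    frames = []
    for arr, kin in ((fs, "full_sib"), (hs, "half_sib"), (cz, "cousin")):
        if len(arr) == 0:
            continue
        df = pd.DataFrame(arr, columns=["person_a", "person_b"])
        df["kinship"] = kin
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["person_a", "person_b", "kinship",
                                     "a_share", "c_share", "family_id"])
    pairs = pd.concat(frames, ignore_index=True)

    gap = (by.reindex(pairs["person_a"]).to_numpy()
           - by.reindex(pairs["person_b"]).to_numpy())
    sib_like = pairs["kinship"].isin(["full_sib", "half_sib"]).to_numpy()
    dropped = sib_like & (np.abs(gap) > max_birth_gap)
    n_drop = int(dropped.sum())
    if n_drop:
        log.info("pair extraction: dropped %d sibling pairs with birth gap > %d years",
                 n_drop, max_birth_gap)
    pairs = pairs.loc[~dropped].reset_index(drop=True)

    pairs["a_share"] = pairs["kinship"].map(KINSHIP_A_SHARE)
    pairs["c_share"] = pairs["kinship"].map(
        {"full_sib": 1.0, "half_sib": half_sib_kappa, "cousin": 0.0})
    if fam is not None:
        pairs["family_id"] = fam.reindex(pairs["person_a"]).to_numpy()
    else:
        pairs["family_id"] = _connected_families(pairs)
    return pairs


def _connected_families(pairs: pd.DataFrame) -> np.ndarray:
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(zip(pairs["person_a"], pairs["person_b"]))
    comp_of = {}
    for i, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            comp_of[node] = i
    return pairs["person_a"].map(comp_of).to_numpy()


def conversion_table(labels: pd.Series, diagnoses: pd.DataFrame,
                     codesets: dict[str, CodeSet],
                     groups: tuple[str, ...] = ("bd", "scz_sad", "other_psychotic"),
                     ties: str = "before") -> pd.DataFrame:
    """Proportions of MDD cases with each comorbid diagnosis group before vs
    after the first MDD diagnosis, by MDD subtype (groups overlap; a person
    can appear under both 'before' and 'after').

    A comorbid diagnosis at exactly the index age counts as 'before' when
    ``ties == 'before'`` (diagnostic-conversion reading), else as 'after'.
    """
    if ties not in ("before", "after"):
        raise ConfigError("ties must be 'before' or 'after'")
    d = _normalized_diagnoses(diagnoses)
    n_missing = int(d["age"].isna().sum())
    if n_missing:
        log.warning("conversion table: %d diagnosis rows without age excluded", n_missing)
        d = d.dropna(subset=["age"])
    mdd_mask = codesets["mdd"].matches(d["icd10"])
    index_age = d.loc[mdd_mask].groupby("person_id")["age"].min()

    rows = []
    for subtype in ("psychotic_mdd", "non_psychotic_mdd"):
        members = labels.index[labels == subtype]
        n = len(members)
        idx_age = index_age.reindex(members)
        for gname in groups:
            cs = codesets[gname]
            sub = d.loc[d["person_id"].isin(members) & cs.matches(d["icd10"])]
            ages = sub.groupby("person_id")["age"]
            first = ages.min().reindex(members)
            last = ages.max().reindex(members)
            if ties == "before":
                before = (first <= idx_age).fillna(False)
            else:
                before = (first < idx_age).fillna(False)
            after = (last > idx_age).fillna(False) if ties == "before" \
                else (last >= idx_age).fillna(False)
            rows.append({
                "subtype": subtype, "group": gname, "n": n,
                "n_before": int(before.sum()), "n_after": int(after.sum()),
                "prop_before": before.sum() / n if n else np.nan,
                "prop_after": after.sum() / n if n else np.nan,
            })
    return pd.DataFrame(rows)


def summarize_counts(n_total: int, n_female: int, n_mdd_icd10: int,
                     n_psychotic: int) -> dict:
    """Cohort summary percentages from raw counts (rounded to 2 decimals,
    matching register-table reporting style)."""
    pct = lambda num, den: round(100.0 * num / den, 2) if den else None
    return {
        "n_total": n_total,
        "n_female": n_female,
        "pct_female": pct(n_female, n_total),
        "n_mdd_icd10": n_mdd_icd10,
        "pct_mdd": pct(n_mdd_icd10, n_total),
        "n_psychotic_mdd": n_psychotic,
        "pct_psychotic_in_mdd": pct(n_psychotic, n_mdd_icd10),
        "pct_psychotic_in_population": pct(n_psychotic, n_total),
    }


def descriptives(persons: pd.DataFrame, labels: pd.Series) -> dict:
    """Table-style cohort summary: counts, % female, psychotic share of MDD,
    and population prevalence."""
    lab = labels.reindex(persons["person_id"]).fillna("none")
    n_mdd = int((lab != "none").sum())
    n_psy = int((lab == "psychotic_mdd").sum())
    return summarize_counts(
        n_total=len(persons),
        n_female=int((persons["sex"] == "F").sum()),
        n_mdd_icd10=n_mdd,
        n_psychotic=n_psy,
    )
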