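"""End-to-end orchestration: generate -> phenotype -> pairs -> familial
aggregation -> liability models -> PRS -> meta-analysis.

A run is fully specified by a :class:`RunConfig` (YAML-loadable) and a
seed; cohorts (register analogues) are generated with consecutive
sub-seeds and pooled by fixed-effect meta-analysis.  Every stage logs its
exclusion counts, and every file consumed or produced is checksummed into
``manifest.json``; re-running with the same config and seed reproduces
every output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import cohort as coh
from . import famrisk as fr
from . import liability as lia
from . import prs as prsmod
from .exceptions import ConfigError, DataError, PmddError
from .meta import fixed_effect_meta
from .registry import GeneratorConfig, TraitSpec, simulate_population

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger(__name__)


def _smoke_traits() -> list[TraitSpec]:
    # prevalences are boosted relative to the register setting so that a
    # small-family smoke run still contains concordant pairs in every cell
    return [
        TraitSpec("psychotic_mdd", 0.50, 0.0, 0.50, 0.03, ("F32.3", "F33.3"),
                  exclusive_with="nonpsychotic_mdd", exclusivity_rule="psychotic_mdd"),
        TraitSpec("nonpsychotic_mdd", 0.40, 0.0, 0.60, 0.15,
                  ("F32.1", "F33.1", "F32.0", "F33.0", "F32.2", "F33.2"),
                  exclusive_with="psychotic_mdd", exclusivity_rule="psychotic_mdd"),
        TraitSpec("scz_sad", 0.70, 0.0, 0.30, 0.05, ("F20", "F25")),
    ]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see README for a YAML example)."""

    seed: int
    n_families: int = 5000
    cohorts: tuple[str, ...] = ("cohort_a", "cohort_b")
    definition: str = "main"
    comparator: str = "all_nonpsychotic"
    kinships: tuple[str, ...] = ("full_sib", "cousin")
    n_boot: int = 200
    rg_boot: int = 0            # ML rg bootstrap replicates (0: curvature SE)
    max_birth_gap: int = 10
    traits: list[TraitSpec] = field(default_factory=_smoke_traits)
    rg: dict = field(default_factory=lambda: {
        ("psychotic_mdd", "nonpsychotic_mdd"): 0.82,
        ("psychotic_mdd", "scz_sad"): 0.67,
        ("nonpsychotic_mdd", "scz_sad"): 0.46,
    })
    codes_path: str | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.definition not in ("main", "restrictive"):
            raise ConfigError(f"unknown definition {self.definition!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "traits" in raw:
            raw["traits"] = [TraitSpec(**t) for t in raw["traits"]]
        if "rg" in raw:
            raw["rg"] = {tuple(k.split("|")): float(v) for k, v in raw["rg"].items()}
        for key in ("cohorts", "kinships"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as err:
            raise ConfigError(f"bad run config: {err}") from err


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self):
        self.stages: list[dict] = []

    def record(self, stage: str, inputs: list[pathlib.Path], outputs: list[pathlib.Path]):
        self.stages.append({
            "stage": stage,
            "inputs": {p.name: _sha256(p) for p in inputs},
            "outputs": {p.name: _sha256(p) for p in outputs},
        })

    def write(self, path: pathlib.Path):
        path.write_text(json.dumps({"stages": self.stages}, indent=2, sort_keys=True))


def _write_tsv(df: pd.DataFrame, path: pathlib.Path) -> pathlib.Path:
    df.to_csv(path, sep="\t", index=False)
    return path


def _labels_from(diagnoses, codesets, definition) -> pd.Series:
    return coh.classify_mdd(diagnoses, codesets, definition=definition)


def _pair_categories(pairs: pd.DataFrame, labels: pd.Series, traits: list[str],
                     kinships=None) -> tuple[pd.DataFrame, int]:
    """cat_a/cat_b columns for the liability stage from phenotype labels."""
    if kinships is not None:
        pairs = pairs.loc[pairs["kinship"].isin(kinships)].reset_index(drop=True)
    lab_a = labels.reindex(pairs["person_a"]).fillna("none").to_numpy()
    lab_b = labels.reindex(pairs["person_b"]).fillna("none").to_numpy()

    # generator trait names vs classifier label values
    label_of = {"nonpsychotic_mdd": "non_psychotic_mdd"}
    tlabels = [label_of.get(t, t) for t in traits]

    def enc(lab):
        if len(tlabels) == 1:
            return (lab == tlabels[0]).astype(np.int64)
        cat = np.zeros(len(lab), dtype=np.int64)
        cat[lab == tlabels[0]] = 1
        cat[lab == tlabels[1]] = 2
        return cat

    out = pairs[["family_id", "kinship"]].copy()
    out["cat_a"] = enc(lab_a)
    out["cat_b"] = enc(lab_b)
    return out, (2 if len(traits) == 1 else 3)


def _tables_by_kinship(pair_cats: pd.DataFrame, n_cat: int, traits,
                       exclusive: bool, kinships) -> dict[str, lia.PairCrossTable]:
    tables = {}
    for kin in kinships:
        sub = pair_cats.loc[pair_cats["kinship"] == kin]
        if sub.empty:
            raise DataError(f"no {kin} pairs for liability stage")
        tables[kin] = lia.PairCrossTable.from_categories(
            sub["cat_a"], sub["cat_b"], n_cat, kin, tuple(traits), exclusive)
    return tables


def _cohort_analysis(name: str, cfg: RunConfig, seed: int, outdir: pathlib.Path,
                     codesets, manifest: _Manifest) -> dict:
    cdir = outdir / name
    cdir.mkdir(parents=True, exist_ok=True)

    # --- simulate ---------------------------------------------------------
    gen = GeneratorConfig(n_families=cfg.n_families, traits=cfg.traits,
                          rg=dict(cfg.rg), seed=seed)
    pop = simulate_population(gen)
    paths = pop.write(cdir)
    manifest.record(f"{name}/simulate", [], [pathlib.Path(p) for p in paths.values()])

    # --- phenotype + eligibility -----------------------------------------
    labels = _labels_from(pop.diagnoses, codesets, cfg.definition)
    persons = coh.apply_eligibility(pop.persons, birth_window=gen.birth_year_range)
    lab_path = _write_tsv(labels.rename("label").reset_index(), cdir / "labels.tsv")
    manifest.record(f"{name}/phenotype",
                    [cdir / "diagnoses.tsv", cdir / "persons.tsv"], [lab_path])

    # --- pairs ------------------------------------------------------------
    # pedigree links come from the full multi-generation table; the pair
    # list is then restricted to eligible members of the study cohort
    pairs = coh.extract_pairs(pop.persons, max_birth_gap=cfg.max_birth_gap,
                              half_sib_kappa=gen.half_sib_kappa)
    eligible = set(persons["person_id"])
    pairs = pairs.loc[pairs["person_a"].isin(eligible)
                      & pairs["person_b"].isin(eligible)].reset_index(drop=True)
    pairs_path = _write_tsv(pairs, cdir / "pairs.tsv")
    manifest.record(f"{name}/pairs", [cdir / "persons.tsv"], [pairs_path])

    # --- descriptives + conversion ---------------------------------------
    desc = coh.descriptives(persons, labels)
    conv = coh.conversion_table(labels, pop.diagnoses, codesets)
    desc_path = cdir / "descriptives.json"
    desc_path.write_text(json.dumps(desc, indent=2, sort_keys=True))
    conv_path = _write_tsv(conv, cdir / "conversion.tsv")
    manifest.record(f"{name}/descriptives", [lab_path], [desc_path, conv_path])

    # --- familial aggregation --------------------------------------------
    psych = labels == "psychotic_mdd"
    famrisk_rows = []
    assoc = {}
    for kin in cfg.kinships:
        est = fr.FamilialAggregation.from_pairs(
            pairs, exposure=psych, outcome=psych, persons=persons,
            kinship=kin, label=f"aggregation_psychotic_{kin}").fit()
        famrisk_rows.append(est)
        assoc[f"aggregation_{kin}"] = est
    # co-aggregation with SCZ/SAD diagnoses
    d = pop.diagnoses.copy()
    d["icd10"] = d["icd10"].map(coh.normalize_code)
    scz_ids = set(d.loc[codesets["scz_sad"].matches(d["icd10"]), "person_id"])
    scz = pd.Series(True, index=pd.Index(sorted(scz_ids), name="person_id"))
    for kin in cfg.kinships:
        est = fr.FamilialAggregation.from_pairs(
            pairs, exposure=psych, outcome=scz, persons=persons,
            kinship=kin, label=f"coaggregation_scz_sad_{kin}").fit()
        famrisk_rows.append(est)
        assoc[f"coaggregation_scz_sad_{kin}"] = est
    fam_tbl = fr.bonferroni(famrisk_rows)
    fam_path = _write_tsv(fam_tbl, cdir / "famrisk.tsv")
    manifest.record(f"{name}/famrisk", [pairs_path, lab_path], [fam_path])

    # --- liability: h2 + exclusive rg ------------------------------------
    pc_uni, k_uni = _pair_categories(pairs, labels, ["psychotic_mdd"], cfg.kinships)
    tabs_uni = _tables_by_kinship(pc_uni, k_uni, ["psychotic_mdd"], False, cfg.kinships)
    h2_fit = lia.AceLiabilityModel(tabs_uni).fit("AE")
    ace_fit = lia.AceLiabilityModel(tabs_uni).fit("ACE")
    c_test = lia.compare_models(ace_fit, h2_fit, boundary_mixture=True)
    if cfg.n_boot > 0:
        draws = lia.bootstrap_fits(
            pc_uni, k_uni,
            lambda tabs: {"a2": lia.AceLiabilityModel(tabs).fit("AE").a2},
            n_boot=cfg.n_boot, seed=seed + 101, traits=("psychotic_mdd",))
        h2_fit.boot_ci = lia.percentile_ci(draws)
        h2_fit.n_boot = cfg.n_boot

    exc = ["psychotic_mdd", "nonpsychotic_mdd"]
    pc_exc, k_exc = _pair_categories(pairs, labels, exc, cfg.kinships)
    tabs_exc = _tables_by_kinship(pc_exc, k_exc, exc, True, cfg.kinships)
    # two-stage marginals: univariate AE fits per trait
    marginals = {}
    for t in exc:
        pc_t, k_t = _pair_categories(pairs, labels, [t], cfg.kinships)
        tabs_t = _tables_by_kinship(pc_t, k_t, [t], False, cfg.kinships)
        marginals[t] = {"a2": lia.AceLiabilityModel(tabs_t).fit("AE").a2}
    rg_model = lia.GeneticCorrelationModel(tabs_exc, marginals, exclusive=True,
                                           winner="psychotic_mdd")
    rg_fit = rg_model.fit()
    if cfg.rg_boot > 0:
        draws = lia.bootstrap_fits(
            pc_exc, k_exc,
            lambda tabs: {"rg": lia.GeneticCorrelationModel(
                tabs, marginals, exclusive=True,
                winner="psychotic_mdd").fit(lrt=False).rg},
            n_boot=cfg.rg_boot, seed=seed + 202, traits=tuple(exc), exclusive=True)
        rg_fit.boot_ci = lia.percentile_ci(draws)
        rg_fit.n_boot = cfg.rg_boot

    lia_path = cdir / "liability.json"
    lia_path.write_text(json.dumps({
        "h2_psychotic_AE": h2_fit.to_dict(),
        "h2_psychotic_ACE": ace_fit.to_dict(),
        "test_c_equals_0": c_test,
        "rg_psychotic_vs_nonpsychotic": rg_fit.to_dict(),
    }, indent=2, sort_keys=True))
    manifest.record(f"{name}/liability", [pairs_path, lab_path], [lia_path])

    # --- PRS --------------------------------------------------------------
    prs = pop.prs
    prs_res = {}
    if len(prs) > 50:
        df = prs.merge(persons[["person_id", "sex"]], on="person_id", how="inner")
        df["age"] = 2013.0 - persons.set_index("person_id")["birth_year"] \
            .reindex(df["person_id"]).to_numpy()
        df["psychotic"] = (labels.reindex(df["person_id"]) == "psychotic_mdd") \
            .to_numpy(dtype=np.uint8)
        score_cols = [c for c in prs.columns if c != "person_id"
                      and not ({c, "bd1", "bd2"} <= set(prs.columns) and c == "bd")]
        try:
            model = prsmod.PrsCaseCase(df, score_cols)
            prs_res = {k: v.to_dict() for k, v in model.fit(mode="joint").items()}
        except (DataError, PmddError) as err:
            log.warning("%s: PRS stage skipped: %s", name, err)
    prs_path = cdir / "prs_assoc.json"
    prs_path.write_text(json.dumps(prs_res, indent=2, sort_keys=True))
    manifest.record(f"{name}/prs", [cdir / "prs.tsv", lab_path], [prs_path])

    return {
        "descriptives": desc,
        "famrisk": {k: v.to_dict() for k, v in assoc.items()},
        "h2": h2_fit.to_dict(),
        "rg_exclusive": rg_fit.to_dict(),
        "prs": prs_res,
    }


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage for every cohort, meta-analyse, and write a report.

    Returns the consolidated report dict (also written to report.json)."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log", mode="w")
    logging.getLogger().addHandler(fh)
    try:
        manifest = _Manifest()
        codesets = coh.load_codesets(config.codes_path)
        cohorts = {}
        for i, name in enumerate(config.cohorts):
            log.info("=== cohort %s (seed %d) ===", name, config.seed + i)
            try:
                cohorts[name] = _cohort_analysis(name, config, config.seed + i,
                                                 out, codesets, manifest)
            except PmddError as err:
                raise type(err)(f"stage failure in cohort {name!r}: {err}") from err

        # meta-analysis across cohorts
        meta: dict = {}
        names = list(cohorts)
        for key in cohorts[names[0]]["famrisk"]:
            ests = [cohorts[n]["famrisk"][key] for n in names]
            m = fixed_effect_meta([e["log_or"] for e in ests],
                                  [e["robust_se"] for e in ests])
            meta[f"famrisk_{key}"] = {"or": float(np.exp(m.estimate)),
                                      "ci_low": float(np.exp(m.ci_low)),
                                      "ci_high": float(np.exp(m.ci_high)),
                                      "p_value": m.p_value}
        h2s = [cohorts[n]["h2"] for n in names]
        ses = [((c["boot_ci"]["a2"][1] - c["boot_ci"]["a2"][0]) / (2 * 1.96))
               if c["boot_ci"].get("a2") else c["se"]["a2"] for c in h2s]
        m = fixed_effect_meta([c["params"]["a2"] for c in h2s], ses)
        meta["h2_psychotic"] = {"estimate": m.estimate, "ci_low": m.ci_low,
                                "ci_high": m.ci_high}
        rgs = [cohorts[n]["rg_exclusive"] for n in names]
        m = fixed_effect_meta([c["rg"] for c in rgs], [c["se"]["rg"] for c in rgs])
        meta["rg_psychotic_nonpsychotic"] = {"estimate": m.estimate,
                                             "ci_low": m.ci_low, "ci_high": m.ci_high}

        report = {"config": {"seed": config.seed, "n_families": config.n_families,
                             "definition": config.definition,
                             "cohorts": list(config.cohorts)},
                  "cohorts": cohorts, "meta": meta}
        rpath = out / "report.json"
        rpath.write_text(json.dumps(report, indent=2, sort_keys=True))
        manifest.record("meta", [], [rpath])
        manifest.write(out / "manifest.json")
        return report
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()
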