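"""End-to-end reproducible runs: simulate/load -> summarize -> QTL scan
-> QMDR/GMDR search -> permutation -> report bundle.

A run is fully described by a :class:`RunConfig` (loadable from YAML);
the same config + seed reproduces the same bundle byte for byte.  Every
number written to the human-readable TSVs is also present in the
machine-readable ``results.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import (
    PhenotypeTable,
    read_ped_map,
    read_phenotypes_csv,
    write_ped_map,
    write_phenotypes_csv,
    align_cohort,
)
from .mdr import model_table, permutation_test, cross_validated_search
from .panel import default_panel
from .qtl import run_scan
from .simulate import Cohort, CohortConfig, simulate_cohort
from .summary import summarize_phenotypes

CASE_TRAITS = ("fev1", "fev1_pct_pred", "fvc", "fev1_fvc", "bode", "six_mwt", "mmrc")
LUNG_TRAITS = ("fev1", "fev1_pct_pred", "fvc", "fev1_fvc")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.  ``seed`` is mandatory: every
    stochastic stage derives its stream from it."""

    seed: int
    out_dir: str = "results"
    # either simulate ...
    simulate: dict | None = None  # keys: n_cases, n_controls, missing_rate
    # ... or load
    ped: str | None = None
    map: str | None = None
    pheno: str | None = None
    traits_cases: tuple[str, ...] = CASE_TRAITS
    traits_all: tuple[str, ...] = LUNG_TRAITS
    methods: tuple[str, ...] = ("qmdr", "gmdr")
    ks: tuple[int, ...] = (2, 3)
    folds: int = 10
    permutations: int = 1000
    subject_sets: tuple[str, ...] = ("cases", "all")
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set a seed")
        if self.simulate is None and not (self.ped and self.map and self.pheno):
            # default to simulating the study-sized cohort
            self.simulate = {}
        for path in (self.ped, self.map, self.pheno):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError(f"config {path}: missing required key 'seed'")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        for key in ("traits_cases", "traits_all", "methods", "ks", "subject_sets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_or_simulate(config: RunConfig) -> Cohort:
    if config.ped:
        geno = read_ped_map(config.ped, config.map)
        pheno = read_phenotypes_csv(config.pheno)
        align_cohort(geno, pheno)
        return Cohort(geno, pheno, seed=config.seed)
    sim = dict(config.simulate or {})
    cc = CohortConfig(
        panel=default_panel(),
        n_cases=int(sim.get("n_cases", 310)),
        n_controls=int(sim.get("n_controls", 203)),
        missing_rate=float(sim.get("missing_rate", 0.0)),
    )
    return simulate_cohort(cc, seed=config.seed)


def _interaction_stage(
    cohort: Cohort, config: RunConfig, subset: str, method: str, k: int
) -> dict:
    keep = (
        cohort.phenotypes.case_mask()
        if subset == "cases"
        else np.ones(cohort.n_subjects, dtype=bool)
    )
    traits = config.traits_cases if subset == "cases" else config.traits_all
    G = cohort.genotypes.calls[keep]
    ids = cohort.genotypes.snp_ids
    cov = cohort.phenotypes.covariate_frame().loc[keep]
    out: dict[str, dict] = {}
    for i, trait in enumerate(traits):
        y = cohort.phenotypes.trait(trait)[keep]
        # reproducible per-stage stream: spawn key from stage indices
        stage_seed = np.random.SeedSequence(
            entropy=config.seed,
            spawn_key=(
                list(config.subject_sets).index(subset),
                list(config.methods).index(method),
                k,
                i,
            ),
        )
        rng_seed = int(stage_seed.generate_state(1)[0] % (2**31))
        if config.permutations > 0:
            res = permutation_test(
                G, y, cov, method=method, k=k, B=config.permutations,
                n_folds=config.folds, seed=rng_seed, snp_ids=ids,
            )
            model = res.model
        else:
            model = cross_validated_search(
                G, y, cov, method=method, k=k, n_folds=config.folds,
                seed=rng_seed, snp_ids=ids,
            )
        out[trait] = {
            "model": list(model.snp_tuple),
            "t_cv_score": model.t_cv_score,
            "cv_consistency": model.cv_consistency,
            "n_folds": model.n_folds,
            "permuted_p": model.permuted_p,
            "per_fold": [
                {
                    "fold": fr.fold,
                    "selected": list(fr.selected),
                    "train_stat": fr.train_stat,
                    "test_stat": fr.test_stat,
                }
                for fr in model.per_fold
            ],
            "_model_obj": model,
        }
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Emits per-trait QTL-scan TSVs, best two-/three-way interaction TSVs
    per subject subset, ordinal trait summaries, the cohort files (when
    simulated), and ``results.json`` carrying every statistic.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
    }

    try:
        cohort = _load_or_simulate(config)
    except Exception as err:
        raise RuntimeError(f"stage 'cohort': {err}") from err

    if config.ped is None:
        prov = {"seed": config.seed, "config": vars(config).copy(),
                "tool": f"copd-epistasis {__version__}"}
        write_ped_map(cohort.genotypes, out_dir / "cohort.ped",
                      out_dir / "cohort.map", cohort.phenotypes, prov)
        write_phenotypes_csv(cohort.phenotypes, out_dir / "cohort.pheno.csv", prov)

    bundle["n_cases"] = int(cohort.phenotypes.case_mask().sum())
    bundle["n_controls"] = int((~cohort.phenotypes.case_mask()).sum())

    try:
        summaries = summarize_phenotypes(cohort.phenotypes)
    except Exception as err:
        raise RuntimeError(f"stage 'summary': {err}") from err
    bundle["ordinal_summaries"] = summaries
    for trait, summ in summaries.items():
        rows = ["level\tcount\tpercent"]
        rows += [
            f"{lv}\t{ct}\t{pc}"
            for lv, ct, pc in zip(summ["levels"], summ["counts"], summ["percent"])
        ]
        rows.append(f"median\t{summ['median']}\t")
        rows.append(f"P5\t{summ['p5']}\t")
        rows.append(f"P95\t{summ['p95']}\t")
        (out_dir / f"summary_{trait}.tsv").write_text("\n".join(rows) + "\n")

    bundle["qtl"] = {}
    for subset in config.subject_sets:
        traits = config.traits_cases if subset == "cases" else config.traits_all
        try:
            scan = run_scan(cohort.genotypes, cohort.phenotypes,
                            list(traits), subjects=subset)
        except Exception as err:
            raise RuntimeError(f"stage 'qtl/{subset}': {err}") from err
        scan.to_csv(out_dir / f"qtl_{subset}.tsv", sep="\t", index=False)
        bundle["qtl"][subset] = {
            "m": int(scan.attrs["m"]),
            "rows": scan.drop(columns=[]).to_dict(orient="records"),
        }

    bundle["interactions"] = {}
    for subset in config.subject_sets:
        for method in config.methods:
            for k in config.ks:
                key = f"{method}_k{k}_{subset}"
                try:
                    stage = _interaction_stage(cohort, config, subset, method, k)
                except Exception as err:
                    raise RuntimeError(f"stage 'interaction/{key}': {err}") from err
                models = {t: d.pop("_model_obj") for t, d in stage.items()}
                tab = model_table(models)
                tab.to_csv(out_dir / f"interactions_{key}.tsv",
                           sep="\t", index=False)
                bundle["interactions"][key] = stage

    blob = json.dumps(bundle, indent=2, sort_keys=True, default=_json_default)
    (out_dir / "results.json").write_text(blob + "\n")
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
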