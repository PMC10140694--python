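"""End-to-end orchestration: exclusion cascade, scoring, regressions,
indices, decomposition, mediation, sensitivity analyses and report assembly.

The pipeline is deterministic given the configuration: every stage draws
its randomness from a seed sequence derived from the configured seed, and
every table in the report carries the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    ID_COLUMN,
    analysis_columns,
    apply_selection,
    generate_cohort,
    read_cohort,
)
from .concentration import concentration_with_ci
from .config import (
    ConfigurationError,
    GeneratorConfig,
    OUTCOMES,
    default_config,
    load_config,
)
from .decompose import (
    InequalityDecomposition,
    fit_ols,
    mediation_contrast,
    spearman_matrix,
)
from .factor import CapacityFactorModel
from .sensitivity import (
    SubgroupSpec,
    chained_imputation,
    heckman_adjust,
    pool_fits,
    subgroup_contrast,
)

logger = logging.getLogger("lifecap")


# ---------------------------------------------------------------------------
# exclusion cascade


@dataclass
class FilterRule:
    """One exclusion rule: require completeness on columns and/or keep only
    rows satisfying a pandas query expression."""

    name: str
    require_complete: Sequence[str] = ()
    query: str | None = None

    def apply(self, cohort: pd.DataFrame) -> np.ndarray:
        keep = np.ones(len(cohort), dtype=bool)
        for col in self.require_complete:
            if col not in cohort.columns:
                raise ConfigurationError(
                    f"filter rule {self.name!r} references unknown column {col!r}"
                )
            keep &= cohort[col].notna().to_numpy()
        if self.query:
            keep &= cohort.eval(self.query).to_numpy(dtype=bool)
        return keep


def filter_cascade(
    cohort: pd.DataFrame, rules: Sequence[FilterRule]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply exclusion rules in declared order, logging per-rule counts.

    Counts are order-dependent (each rule sees only the survivors of the
    previous ones); the final cohort is not.
    """
    current = cohort
    log_rows = []
    for rule in rules:
        keep = rule.apply(current)
        excluded = int((~keep).sum())
        log_rows.append(
            {
                "rule": rule.name,
                "excluded": excluded,
                "remaining": int(keep.sum()),
            }
        )
        logger.info(
            "filter %s: excluded %d, %d remaining", rule.name, excluded, keep.sum()
        )
        current = current.loc[keep]
    return current.reset_index(drop=True), pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    Either ``generator`` (simulate) or ``cohort_csv``/``cohort_schema``
    (load) must be provided.
    """

    generator: GeneratorConfig | None = None
    cohort_csv: str | None = None
    cohort_schema: str | None = None
    outcomes: Sequence[str] = OUTCOMES
    ranking: str = "wealth"
    variant: str = "shifted_minmax"
    weight_column: str | None = None
    bootstrap_B: int = 1000
    mediation_B: int = 200
    seed: int = 0
    mediators: Sequence[str] | None = None  # default: current-SES covariates
    run_heckman: bool = False
    run_imputation: bool = False
    imputation_m: int = 20
    imputation_iterations: int = 10
    run_subgroups: bool = False
    filter_rules: Sequence[FilterRule] = ()

    def __post_init__(self) -> None:
        if self.generator is None and not (self.cohort_csv and self.cohort_schema):
            raise ConfigurationError(
                "either a generator config or a cohort CSV + schema is required"
            )
        bad = set(self.outcomes) - set(OUTCOMES)
        if bad:
            raise ConfigurationError(f"unknown outcomes: {sorted(bad)}")
        if self.generator is not None and self.mediators is not None:
            names = {c.name for c in self.generator.covariates}
            missing = set(self.mediators) - names
            if missing:
                raise ConfigurationError(
                    f"mediators not among covariates: {sorted(missing)}"
                )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict() if self.generator else None
        d["outcomes"] = list(self.outcomes)
        d["mediators"] = list(self.mediators) if self.mediators else None
        d["filter_rules"] = [
            {
                "name": r.name,
                "require_complete": list(r.require_complete),
                "query": r.query,
            }
            for r in self.filter_rules
        ]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        gen = d.get("generator")
        rules = [
            FilterRule(
                name=r["name"],
                require_complete=tuple(r.get("require_complete", ())),
                query=r.get("query"),
            )
            for r in d.get("filter_rules", ())
        ]
        kwargs = {
            k: v
            for k, v in d.items()
            if k not in ("generator", "filter_rules")
        }
        return cls(
            generator=GeneratorConfig.from_dict(gen) if gen else None,
            filter_rules=rules,
            **kwargs,
        )


@dataclass
class RunReport:
    """Assembled pipeline output: provenance plus tidy tables."""

    provenance: dict[str, Any]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    texts: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = (
            f"# config_hash={self.provenance['config_hash']} "
            f"seed={self.provenance['seed']} lifecap={self.provenance['version']}\n"
        )
        for name, tab in self.tables.items():
            path = out / f"{name}.csv"
            with open(path, "w") as fh:
                fh.write(header)
                tab.to_csv(fh)
        with open(out / "report.json", "w") as fh:
            json.dump(
                {
                    "provenance": self.provenance,
                    "tables": sorted(self.tables),
                    "summaries": self.texts,
                },
                fh,
                indent=1,
                default=str,
            )


def _score_column(outcome: str) -> str:
    return f"score_{outcome}"


def default_filter_rules(config: GeneratorConfig) -> list[FilterRule]:
    """Completeness cascade mirroring a survey exclusion protocol:
    capacity indicators first, then early-life (life-history) factors, then
    socioeconomic/demographic information."""
    fs = config.factor_structure
    indicators = list(fs.indicators) if fs else []
    early = [c.name for c in config.by_category("early_life")]
    rest = [
        c.name
        for c in config.covariates
        if c.category in ("current_ses", "demographic", "lifestyle")
    ]
    return [
        FilterRule("capacity_indicators", require_complete=indicators),
        FilterRule("life_history", require_complete=early),
        FilterRule("socioeconomic", require_complete=rest + ["wealth"]),
    ]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Simulate-or-load -> filter -> score -> analyse -> report."""
    ss = np.random.SeedSequence(config.seed)
    seeds = dict(
        zip(
            ["selection", "bootstrap", "mediation", "imputation"],
            ss.spawn(4),
        )
    )
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "variant": config.variant,
    }
    report = RunReport(provenance=provenance)

    stage = "input"
    try:
        if config.generator is not None:
            gen = config.generator
            cohort = generate_cohort(gen)
        else:
            cohort = read_cohort(config.cohort_csv, config.cohort_schema)
            gen = default_config()  # taxonomy for references/categories
        references = {c.name: c.reference for c in gen.covariates}
        category_map = {c.name: c.category for c in gen.covariates}
        covariates = [c.name for c in gen.covariates]
        mediators = (
            list(config.mediators)
            if config.mediators is not None
            else [c.name for c in gen.by_category("current_ses")]
        )
        early = [c.name for c in gen.by_category("early_life")]

        full_cohort = None
        inclusion = None
        if config.run_heckman and gen.selection_model:
            stage = "selection"
            full_cohort = cohort
            cohort, inclusion = apply_selection(
                full_cohort, gen.selection_model, seed=seeds["selection"]
            )

        stage = "filter_cascade"
        rules = list(config.filter_rules) or default_filter_rules(gen)
        cohort, filter_log = filter_cascade(cohort, rules)
        report.tables["filter_log"] = filter_log.set_index("rule")
        if len(cohort) == 0:
            raise ConfigurationError("no rows left after exclusions")

        stage = "capacity_scoring"
        fs = gen.factor_structure
        if fs is None:
            raise ConfigurationError("a factor structure is required for scoring")
        cfa = CapacityFactorModel(cohort, fs).fit()
        if not cfa.converged:
            raise RuntimeError("capacity factor model did not converge")
        scores = cfa.scores(cohort)
        for out_name in OUTCOMES:
            cohort[_score_column(out_name)] = scores[out_name].to_numpy()
        report.texts["capacity_model"] = cfa.summary()

        stage = "spearman"
        ses_cols = [c.name for c in gen.by_category("current_ses")]
        report.tables["spearman_early_life_vs_ses"] = spearman_matrix(
            cohort, early + ses_cols
        )

        stage = "regression"
        weights = (
            cohort[config.weight_column].to_numpy(dtype=float)
            if config.weight_column
            else None
        )
        coef_tables = []
        for out_name in config.outcomes:
            fit = fit_ols(
                cohort, _score_column(out_name), covariates, references, weights
            )
            tab = fit.marginal_effects()
            tab.insert(0, "outcome", out_name)
            tab.insert(1, "n", fit.n)
            coef_tables.append(tab)
        report.tables["marginal_effects"] = pd.concat(coef_tables)

        stage = "concentration_index"
        boot_seeds = seeds["bootstrap"].spawn(len(config.outcomes))
        rows = []
        for out_name, bseed in zip(config.outcomes, boot_seeds):
            res = concentration_with_ci(
                cohort[_score_column(out_name)].to_numpy(),
                cohort[config.ranking].to_numpy(dtype=float),
                weights,
                config.variant,
                B=config.bootstrap_B,
                seed=bseed,
            )
            rows.append(
                {
                    "outcome": out_name,
                    "variant": res.variant,
                    "index": res.value,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "se": res.se,
                    "n": res.n,
                    "B": res.B,
                }
            )
        report.tables["concentration_indices"] = pd.DataFrame(rows).set_index(
            "outcome"
        )

        stage = "decomposition"
        share_rows = []
        for out_name in config.outcomes:
            res = InequalityDecomposition(
                cohort,
                _score_column(out_name),
                covariates,
                ranking=config.ranking,
                references=references,
                category_map=category_map,
                variant=config.variant,
                weights=weights,
            ).fit()
            shares = res.category_shares()
            for cat, s in shares.items():
                share_rows.append(
                    {
                        "outcome": out_name,
                        "category": cat,
                        "share_pct": s,
                        "total_index": res.decomposition.total,
                        "residual_share_pct": res.decomposition.residual_share,
                        "n": res.ols.n,
                        "variant": config.variant,
                    }
                )
            if out_name == "overall":
                report.tables["decomposition_overall"] = res.decomposition.table
                report.texts["decomposition_overall"] = res.summary()
        report.tables["category_shares"] = pd.DataFrame(share_rows).set_index(
            ["outcome", "category"]
        )

        stage = "mediation"
        med = mediation_contrast(
            cohort,
            _score_column("overall"),
            covariates,
            mediators,
            early,
            ranking=config.ranking,
            references=references,
            variant=config.variant,
            weights=weights,
            B=config.mediation_B,
            seed=seeds["mediation"],
        )
        report.tables["mediation"] = pd.DataFrame(
            [
                {
                    "share": "direct",
                    "value_pct": med.direct_share,
                    "ci_low": med.direct_ci[0] if med.direct_ci else None,
                    "ci_high": med.direct_ci[1] if med.direct_ci else None,
                },
                {
                    "share": "total",
                    "value_pct": med.total_share,
                    "ci_low": med.total_ci[0] if med.total_ci else None,
                    "ci_high": med.total_ci[1] if med.total_ci else None,
                },
                {
                    "share": "indirect",
                    "value_pct": med.indirect_share,
                    "ci_low": med.indirect_ci[0] if med.indirect_ci else None,
                    "ci_high": med.indirect_ci[1] if med.indirect_ci else None,
                },
            ]
        ).set_index("share")
        report.texts["mediation"] = med.summary()

        if config.run_heckman and full_cohort is not None:
            stage = "heckman"
            # observed selection covariates: the generator's latent wealth
            # index is proxied by the observed wealth variable
            full_cohort = full_cohort.copy()
            full_cohort["log_wealth"] = np.log(
                full_cohort["wealth"].to_numpy(dtype=float)
            )
            sel_cols = []
            for c in gen.selection_model:
                if c == "intercept":
                    continue
                name = "log_wealth" if c == "wealth_z" else c
                if name in full_cohort.columns:
                    sel_cols.append(name)
            # analytic inclusion: survived both the selection draw and the
            # exclusion cascade; scores exist exactly for those rows
            analytic = (
                full_cohort[ID_COLUMN].isin(cohort[ID_COLUMN]).to_numpy()
            )
            outcome_full = pd.merge(
                full_cohort[[ID_COLUMN]],
                cohort[[ID_COLUMN, _score_column("overall")]],
                on=ID_COLUMN,
                how="left",
            )[_score_column("overall")].to_numpy(dtype=float)
            heck = heckman_adjust(
                full_cohort,
                analytic,
                sel_cols,
                outcome=outcome_full,
                outcome_covariates=covariates,
                references=references,
            )
            report.tables["heckman"] = pd.DataFrame(
                [
                    {
                        "mills_coef": heck.mills_coef,
                        "mills_se": heck.mills_se,
                        "ci_low": heck.mills_ci[0],
                        "ci_high": heck.mills_ci[1],
                        "t": heck.mills_t,
                        "exclusion_restriction": heck.exclusion_restriction,
                    }
                ]
            )

        if config.run_imputation and gen.missing_rates:
            stage = "imputation"
            completed = chained_imputation(
                cohort,
                m=config.imputation_m,
                seed=int(seeds["imputation"].generate_state(1)[0] % (2**31)),
                iterations=config.imputation_iterations,
            )
            fits = [
                fit_ols(df, _score_column("overall"), covariates, references)
                for df in completed
            ]
            terms = fits[0].params.drop("const").index
            rows = []
            for term in terms:
                pooled = pool_fits(fits, term)
                lo, hi = pooled.conf_int()
                rows.append(
                    {
                        "term": term,
                        "estimate": pooled.qbar,
                        "se": pooled.se,
                        "ci_low": lo,
                        "ci_high": hi,
                        "m": pooled.m,
                    }
                )
            report.tables["imputation_pooled"] = pd.DataFrame(rows).set_index(
                "term"
            )

        if config.run_subgroups:
            stage = "subgroups"
            specs = [
                SubgroupSpec(
                    "pre_old_vs_old",
                    "age_group",
                    levels=["lt45", "45_60"],
                ),
                SubgroupSpec(
                    "cognition_median_split",
                    _score_column("cognitive"),
                    threshold=float(
                        np.median(cohort[_score_column("cognitive")])
                    ),
                ),
            ]
            for spec2 in specs:
                try:
                    con = subgroup_contrast(
                        cohort,
                        spec2,
                        _score_column("overall"),
                        covariates,
                        ranking=config.ranking,
                        references=references,
                        category_map=category_map,
                        variant=config.variant,
                    )
                except (KeyError, ValueError) as exc:
                    logger.warning("subgroup %s skipped: %s", spec2.name, exc)
                    continue
                report.tables[f"subgroup_{spec2.name}"] = con.coefficient_table
                report.texts[f"subgroup_{spec2.name}"] = con.summary()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for name, tab in report.tables.items():
        if name in ("filter_log",):
            continue
        if tab.isna().all(axis=None):
            raise RuntimeError(f"table {name!r} is entirely missing")
    return report


def load_pipeline_config(path: str) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    return PipelineConfig.from_dict(d)
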