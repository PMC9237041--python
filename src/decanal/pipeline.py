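"""End-to-end study workflow and machine-readable report.

Stages, in order: obtain a respondent table (synthetic draw or file), filter
to complete cases and derive analysis variables, fit the optimal-scaling PCA
of the explanatory variables, test whether residual categories occupy
distinct regions of the component space (dispersion check, PERMANOVA,
pairwise comparisons), map the running SD of glycemia over component-pair
subspaces, tabulate coefficients of variation and glycemia levels by income
x education, and run the income x education G-test on residual categories.

The report is a plain nested dict (serialized as YAML plus delimited side
tables) whose every number comes from a sub-module result object.  All
randomness flows from one global seed through named spawns, so identical
config + seed gives byte-identical reports; wall-clock timestamps are kept
in a separate run log, never in the report file.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, local_variance, ordinal_pca, survey_io, variance_tests
from .errors import ConfigError, InputError
from .synthetic_data import SimulationConfig, simulate_survey

__all__ = [
    "PipelineConfig",
    "StudyReport",
    "run",
    "summarize_table",
    "level_frequency_table",
    "linear_baseline_r2",
    "write_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "synthetic"                      # synthetic | file
    input_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    schema: survey_io.VariableSchema = field(default_factory=survey_io.default_schema)
    residual_cuts: tuple[float, float] = (40.0, 80.0)
    income_cuts: tuple[float, float, float] = (10_000.0, 20_000.0, 40_000.0)
    glycemia_edges: tuple[float, ...] = (70.0, 100.0, 126.0, 160.0, 200.0)
    n_components: int = 8
    runsd_subspaces: tuple[tuple[int, int], ...] = ((1, 2), (3, 4))
    runsd_k: int | None = None                   # None -> max(50, ceil(0.05 n))
    center_correct: bool = False
    n_permutations: int = 999
    seed: int = 0
    exclusion_flags: tuple[str, ...] = ()        # optional 0/1 columns for sensitivity reruns

    def validate(self) -> None:
        if self.mode not in ("synthetic", "file"):
            raise ConfigError("mode: must be 'synthetic' or 'file'")
        if self.mode == "file" and not self.input_path:
            raise ConfigError("input_path: required in file mode")


@dataclass
class StudyReport:
    report: dict
    derived: survey_io.DerivedTable
    pca: ordinal_pca.OrdinalPCAResult
    running_sd: dict
    cv_table: pd.DataFrame
    contingency: pd.DataFrame
    level_frequencies: pd.DataFrame


def _pca_scaling(schema: survey_io.VariableSchema) -> dict:
    out = {}
    for v in schema.explanatory:
        out[v.name] = {"continuous": "numeric", "ordinal": "ordinal",
                       "nominal": "nominal"}[v.scale]
    return out


def linear_baseline_r2(table: pd.DataFrame, schema: survey_io.VariableSchema) -> float:
    """R^2 of an ordinary linear model of glycemia on all explanatory
    variables (integer-coded ordinals, dummy-coded nominals) — the
    mean-modelling baseline the variance analysis is contrasted with."""
    y = table["glycemia"].to_numpy(dtype=float)
    cols = [np.ones(len(table))]
    for v in schema.explanatory:
        x = table[v.name].to_numpy(dtype=float)
        if v.scale == "nominal" and v.levels is not None:
            for lev in list(v.levels)[1:]:
                cols.append((x == lev).astype(float))
        else:
            cols.append(x)
    xm = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(xm, y, rcond=None)
    resid = y - xm @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return float(1.0 - (resid @ resid) / tss) if tss > 0 else 0.0


def summarize_table(table: pd.DataFrame, schema: survey_io.VariableSchema) -> pd.DataFrame:
    """Covariate summary: mean +/- SD for continuous, % per level otherwise."""
    rows = []
    for v in schema.variables:
        x = table[v.name].dropna()
        if v.scale == "continuous":
            rows.append({"variable": v.name, "units": v.units,
                         "summary": f"{x.mean():.2f} +/- {x.std(ddof=1):.2f}"})
        else:
            pct = (x.value_counts(normalize=True).sort_index() * 100)
            parts = [f"{lev}: {pct.get(lev, 0.0):.2f}%" for lev in v.levels]
            rows.append({"variable": v.name, "units": v.units,
                         "summary": "; ".join(parts)})
    return pd.DataFrame(rows)


def level_frequency_table(table: pd.DataFrame,
                          row_cols: tuple[str, ...] = ("income_category", "edu_interviewee"),
                          level_col: str = "glycemia_level") -> pd.DataFrame:
    """Relative frequency of each glycemia level per income x education cell.

    Frequencies sum to 1 within every populated cell; empty combinations are
    reported with n = 0 and missing frequencies.
    """
    for c in (*row_cols, level_col):
        if c not in table.columns:
            raise InputError(f"level_frequency_table: column {c!r} not in table")
    levels = list(range(1, 7))
    groups = []
    cats = [sorted(table[c].dropna().unique().tolist())
            if not isinstance(table[c].dtype, pd.CategoricalDtype)
            else list(table[c].cat.categories) for c in row_cols]
    import itertools as it

    for combo in it.product(*cats):
        mask = np.ones(len(table), dtype=bool)
        for c, val in zip(row_cols, combo):
            mask &= (table[c] == val).to_numpy()
        sub = table.loc[mask, level_col].dropna()
        n = len(sub)
        row = {**dict(zip(row_cols, combo)), "n": n}
        for lev in levels:
            row[f"level_{lev}"] = float((sub == lev).mean()) if n else np.nan
        groups.append(row)
    return pd.DataFrame(groups)


def run(config: PipelineConfig) -> StudyReport:
    """Execute the full workflow; any stage error aborts with the stage name."""
    config.validate()
    stage = "input"
    try:
        seeds = np.random.SeedSequence(config.seed).spawn(4)
        seed_perm, seed_disp, seed_pair, seed_grad = (
            int(s.generate_state(1)[0] % (2**31)) for s in seeds)
        if config.mode == "synthetic":
            # the pipeline's global seed drives the draw
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            table, truth = simulate_survey(sim_cfg)
        else:
            table = survey_io.read_survey(config.input_path, config.schema)
            truth = None
        n_input = len(table)

        stage = "derive"
        derived = survey_io.build_derived_table(
            table, config.schema,
            required=config.schema.names,
            residual_cuts=config.residual_cuts,
            income_cuts=config.income_cuts,
            glycemia_edges=config.glycemia_edges,
        )
        dt = derived.table

        stage = "ordinal_pca"
        expl = [v.name for v in config.schema.explanatory]
        pca_cfg = ordinal_pca.OrdinalPCAConfig(
            n_components=config.n_components,
            scaling=_pca_scaling(config.schema),
        )
        pca = ordinal_pca.fit(dt[expl], pca_cfg)
        scores = pca.object_scores.to_numpy()

        stage = "variance_tests"
        groups = dt["residual_category"]
        counts = groups.value_counts()
        usable = counts[counts >= 2].index
        dropped_groups = [str(c) for c in counts[counts < 2].index]
        mask = groups.isin(usable).to_numpy()
        disp = variance_tests.dispersion_test(scores[mask], groups[mask],
                                              B=config.n_permutations, seed=seed_disp)
        perm = variance_tests.permanova(scores[mask], groups[mask],
                                        B=config.n_permutations, seed=seed_perm)
        pair = variance_tests.pairwise_permanova(scores[mask], groups[mask],
                                                 B=config.n_permutations, seed=seed_pair)

        stage = "local_variance"
        runsd_out, runsd_report = {}, {}
        values = dt["glycemia"].to_numpy(dtype=float)
        for comps in config.runsd_subspaces:
            sub = ordinal_pca.scores_subspace(pca, comps)
            cfg = local_variance.RunningSDConfig(k=config.runsd_k,
                                                 center_correct=config.center_correct)
            res = local_variance.running_sd(sub, values, cfg)
            grad = local_variance.variance_gradient_test(
                res, sub[:, 0], B=min(config.n_permutations, 199), seed=seed_grad)
            key = "-".join(str(c) for c in comps)
            runsd_out[key] = res
            entry = {
                "components": list(comps), "k": res.k,
                "sd_mean": float(res.sd.mean()), "sd_min": float(res.sd.min()),
                "sd_max": float(res.sd.max()),
                "gradient_rho_pc_first": grad.rho, "gradient_p": grad.p_value,
            }
            if truth is not None and np.ptp(truth.sigma) > 0:
                from scipy.stats import spearmanr

                entry["spearman_sd_vs_true_sigma"] = float(
                    spearmanr(res.sd, truth.sigma).statistic)
            runsd_report[key] = entry

        stage = "cv_and_frequencies"
        cv_tab = survey_io.cv_by_group(dt, ["income_category", "edu_interviewee"])
        freqs = level_frequency_table(dt)

        stage = "g_test"
        ct = variance_tests.build_contingency(dt)
        gres = variance_tests.g_test(ct)

        stage = "report"
        report = {
            "provenance": {
                "package_version": __version__,
                "seed": config.seed,
                "mode": config.mode,
                "derived_rules": {
                    "residual_cuts": list(config.residual_cuts),
                    "income_cuts": list(config.income_cuts),
                    "glycemia_edges": list(config.glycemia_edges),
                },
            },
            "sample": {
                "n_input": n_input,
                "n_retained": derived.n_retained,
                "n_dropped": n_input - derived.n_retained,
            },
            "age_regression": {
                "intercept": derived.regression.intercept,
                "slope": derived.regression.slope,
            },
            "linear_baseline_r2": linear_baseline_r2(dt, config.schema),
            "pca": {
                "n_components": config.n_components,
                "vaf": [float(v) for v in pca.vaf],
                "cumulative_vaf": float(np.sum(pca.vaf)),
                "converged": bool(pca.converged),
                "n_iterations": int(pca.n_iterations),
            },
            "groups_dropped_from_space_tests": dropped_groups,
            "dispersion": {"f": disp.f_stat, "p": disp.p_value},
            "permanova": {
                "pseudo_f": perm.pseudo_f, "p": perm.p_value,
                "df_between": perm.df_between, "df_within": perm.df_within,
            },
            "pairwise_permanova": pair.to_dict(orient="records"),
            "running_sd": runsd_report,
            "g_test": {"g": gres.g, "df": gres.df, "p": gres.p_value},
        }
        if config.mode == "file" and config.exclusion_flags:
            report["sensitivity"] = _sensitivity_reruns(
                table, config, seed_perm, seed_disp)
        return StudyReport(report=report, derived=derived, pca=pca,
                           running_sd=runsd_out, cv_table=cv_tab,
                           contingency=ct, level_frequencies=freqs)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _sensitivity_reruns(table: pd.DataFrame, config: PipelineConfig,
                        seed_perm: int, seed_disp: int) -> dict:
    """Re-run the key tests excluding flagged individuals (e.g. those on
    glucose-lowering treatment or with a diabetes diagnosis), one flag at a
    time — the flags are treated independently."""
    out = {}
    for flag in config.exclusion_flags:
        if flag not in table.columns:
            logger.info("sensitivity: flag %r absent, skipped", flag)
            continue
        sub = table.loc[table[flag].fillna(0) == 0].drop(columns=[flag])
        sub_cfg = dataclasses.replace(config, exclusion_flags=())
        derived = survey_io.build_derived_table(
            sub, config.schema, required=config.schema.names,
            residual_cuts=config.residual_cuts, income_cuts=config.income_cuts,
            glycemia_edges=config.glycemia_edges)
        expl = [v.name for v in config.schema.explanatory]
        pca = ordinal_pca.fit(derived.table[expl], ordinal_pca.OrdinalPCAConfig(
            n_components=config.n_components, scaling=_pca_scaling(config.schema)))
        scores = pca.object_scores.to_numpy()
        perm = variance_tests.permanova(scores, derived.table["residual_category"],
                                        B=config.n_permutations, seed=seed_perm)
        ct = variance_tests.build_contingency(derived.table)
        gres = variance_tests.g_test(ct)
        out[flag] = {
            "n_retained": derived.n_retained,
            "permanova": {"pseudo_f": perm.pseudo_f, "p": perm.p_value},
            "g_test": {"g": gres.g, "df": gres.df, "p": gres.p_value},
        }
    return out


def write_report(result: StudyReport, outdir) -> Path:
    """Write report.yaml plus delimited side tables; returns the report path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(result.report, fh, sort_keys=True)
    result.pca.object_scores.to_csv(outdir / "object_scores.csv", index=False)
    result.pca.loadings.to_csv(outdir / "loadings.csv")
    result.cv_table.to_csv(outdir / "cv_by_group.csv", index=False)
    result.contingency.to_csv(outdir / "contingency.csv")
    result.level_frequencies.to_csv(outdir / "level_frequencies.csv", index=False)
    for key, res in result.running_sd.items():
        pd.DataFrame({"running_mean": res.mean, "running_sd": res.sd}).to_csv(
            outdir / f"running_sd_{key}.csv", index=False)
    return path
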