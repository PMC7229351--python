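"""Model/results interface for a whole-cohort dynamic-network study.

``DynamicNetworkStudy`` holds the data (per-subject ROI time series plus a
phenotype table) and the analysis configuration (window scheme, sparsity
grid); ``fit()`` runs metric extraction and group inference and returns a
``StudyResults`` with the per-subject metric tables, the group tests, the
clinical correlations and a text ``summary()``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import stats as _stats
from .io import load_timeseries_dir, read_phenotype
from .windows import ROITimeSeries, make_windows

logger = logging.getLogger(__name__)

__all__ = ["DynamicNetworkStudy", "StudyResults", "split_half"]

GLOBAL_METRICS = (
    "temporal_variability",
    "temporal_correlation",
    "temporal_path_length",
)


def _col(metric: str, s: float) -> str:
    return f"{metric}@{s:.2f}"


class DynamicNetworkStudy:
    """A cohort of ROI time series with its analysis configuration.

    Parameters
    ----------
    timeseries : mapping of subject id -> ROITimeSeries
        All subjects must share the same region count and TR.
    phenotype : DataFrame
        One row per subject (``subject_id``, ``group``, covariates, site,
        clinical scores).  Every time-series subject must appear here.
    window_s, step_s : float
        Sliding-window length and step in seconds (defaults 100 and 6).
    sparsity_grid : sequence of float, optional
        Defaults to 0.10..0.50 in steps of 0.01.
    """

    def __init__(
        self,
        timeseries,
        phenotype: pd.DataFrame,
        *,
        window_s: float = 100.0,
        step_s: float = 6.0,
        sparsity_grid=None,
        ranking: str = "signed",
        groups: tuple[str, str] = ("MDD", "HC"),
    ) -> None:
        if not isinstance(timeseries, dict):
            timeseries = dict(timeseries)
        if not timeseries:
            raise ValueError("no time series supplied")
        self.timeseries: dict[str, ROITimeSeries] = timeseries
        _stats.check_phenotype(phenotype)
        missing = set(timeseries) - set(phenotype["subject_id"].astype(str))
        if missing:
            raise ValueError(f"subjects missing from phenotype table: {sorted(missing)[:5]}")
        self.phenotype = (
            phenotype[phenotype["subject_id"].astype(str).isin(timeseries)]
            .reset_index(drop=True)
        )
        first = next(iter(timeseries.values()))
        for sid, ts in timeseries.items():
            if ts.n_regions != first.n_regions or ts.tr_s != first.tr_s:
                raise ValueError(f"subject {sid}: region count/TR mismatch")
        self.tr_s = first.tr_s
        self.node_labels = first.node_labels
        self.window_s = float(window_s)
        self.step_s = float(step_s)
        self.sparsity_grid = (
            _metrics.default_sparsity_grid()
            if sparsity_grid is None
            else np.asarray([float(s) for s in sparsity_grid])
        )
        self.ranking = ranking
        self.groups = groups
        self._records: dict[str, _metrics.SubjectMetricsRecord] | None = None

    @classmethod
    def from_directory(cls, data_dir, phenotype, tr_s: float, **kwargs):
        """Build a study from a directory of per-subject TSVs and a
        phenotype CSV path (or already-loaded DataFrame)."""
        ts = load_timeseries_dir(data_dir, tr_s)
        if not isinstance(phenotype, pd.DataFrame):
            phenotype = read_phenotype(phenotype)
        return cls(ts, phenotype, **kwargs)

    # -- metric extraction ---------------------------------------------------

    def compute_metrics(self) -> dict[str, _metrics.SubjectMetricsRecord]:
        """Per-subject metric records, computed once and cached."""
        if self._records is None:
            records = {}
            for sid in self.phenotype["subject_id"].astype(str):
                ts = self.timeseries[sid]
                scheme = make_windows(ts.n_volumes, ts.tr_s, self.window_s, self.step_s)
                records[sid] = _metrics.subject_metrics(
                    ts, scheme, self.sparsity_grid, ranking=self.ranking
                )
            self._records = records
        return self._records

    def metrics_table(self) -> pd.DataFrame:
        """Global metrics per subject: variability, sparsity-averaged and
        per-sparsity temporal correlation / path length, unreachable-pair
        fractions.  Index = subject id."""
        records = self.compute_metrics()
        rows = {}
        # row order must follow the phenotype table: the inference stage
        # pairs metric rows with covariate rows positionally
        for sid in self.phenotype["subject_id"].astype(str):
            rec = records[sid]
            g = rec.global_metrics
            row = {
                "temporal_variability": g.temporal_variability,
                "temporal_correlation": g.temporal_correlation_mean,
                "temporal_path_length": g.characteristic_temporal_path_length_mean,
                "unreachable_fraction": g.unreachable_pair_fraction_mean,
            }
            for s in self.sparsity_grid:
                s = float(s)
                row[_col("temporal_correlation", s)] = g.temporal_correlation_by_sparsity[s]
                row[_col("temporal_path_length", s)] = (
                    g.characteristic_temporal_path_length_by_sparsity[s]
                )
            rows[sid] = row
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject_id")

    def nodal_tables(self) -> dict[str, pd.DataFrame]:
        """Sparsity-averaged nodal values per metric: rows = subjects,
        columns = node labels."""
        records = self.compute_metrics()
        out = {}
        sids = list(self.phenotype["subject_id"].astype(str))
        labels = list(self.node_labels)
        out["temporal_variability"] = pd.DataFrame(
            [records[s].nodal_variability.values for s in sids],
            index=sids, columns=labels,
        )
        out["temporal_correlation"] = pd.DataFrame(
            [records[s].nodal_correlation_mean for s in sids],
            index=sids, columns=labels,
        )
        out["temporal_path_length"] = pd.DataFrame(
            [records[s].nodal_path_mean for s in sids],
            index=sids, columns=labels,
        )
        for df in out.values():
            df.rename_axis("subject_id", inplace=True)
        return out

    # -- inference -----------------------------------------------------------

    def fit(
        self,
        *,
        per_sparsity: bool = False,
        nodal: bool = False,
        subgroups: bool = False,
        correlations: bool = True,
        fdr_alpha: float = 0.05,
    ) -> "StudyResults":
        """Run the group comparison and return a results object.

        The primary family is the three global metrics (variability on
        weighted layers; sparsity-averaged temporal correlation and path
        length), FDR-adjusted together.  Optional families: per-sparsity
        tests, nodal tests (FDR across nodes per metric), subgroup
        contrasts and clinical partial Spearman correlations.
        """
        table = self.metrics_table()
        pheno = self.phenotype
        case, control = self.groups

        kw = dict(groups=self.groups)
        primary = [
            _stats.ancova_group_effect(
                table["temporal_variability"].to_numpy(), pheno,
                metric_name="temporal_variability", **kw,
            )
        ]
        per_sp: list[_stats.GroupTestResult] = []
        for metric in ("temporal_correlation", "temporal_path_length"):
            y = table[[_col(metric, float(s)) for s in self.sparsity_grid]]
            y = y.set_axis([float(s) for s in self.sparsity_grid], axis=1)
            if per_sparsity:
                avg, per = _stats.sparsity_profile_group_effect(
                    y, pheno, metric_name=metric, **kw
                )
                per_sp.extend(_stats.fdr_annotate(per))
            else:
                # between-subject effect only: identical to the
                # repeated-measures main effect via the sparsity mean
                avg = _stats.ancova_group_effect(
                    y.mean(axis=1).to_numpy(), pheno,
                    metric_name=metric, sparsity="averaged", **kw,
                )
            primary.append(avg)
        primary = _stats.fdr_annotate(primary)

        corr_results: list[_stats.CorrelationResult] = []
        if correlations:
            corr_results = self._clinical_correlations(table)

        nodal_tests = None
        if nodal:
            nodal_tests = {}
            for metric, df in self.nodal_tables().items():
                res = [
                    _stats.ancova_group_effect(
                        df[c].to_numpy(), pheno, metric_name=str(c), **kw
                    )
                    for c in df.columns
                ]
                nodal_tests[metric] = _group_results_frame(_stats.fdr_annotate(res))

        subgroup_tests = None
        if subgroups:
            sub = _stats.subgroup_contrasts(table[list(GLOBAL_METRICS)], pheno)
            subgroup_tests = _group_results_frame(sub)

        return StudyResults(
            model=self,
            subject_metrics=table,
            group_tests=_group_results_frame(primary),
            per_sparsity_tests=_group_results_frame(per_sp) if per_sparsity else None,
            correlations=_corr_results_frame(corr_results) if corr_results else None,
            nodal_tests=nodal_tests,
            subgroup_tests=subgroup_tests,
            fdr_alpha=fdr_alpha,
        )

    def _clinical_correlations(self, table: pd.DataFrame):
        """Partial Spearman of each global metric with HAMD and illness
        duration in patients, adjusting for age, sex and site; FDR across
        the three metrics per clinical variable."""
        case = self.groups[0]
        patients = self.phenotype["group"].astype(str) == case
        sub = self.phenotype.loc[patients]
        results = []
        for variable in ("hamd", "duration_months"):
            if variable not in sub.columns:
                continue
            fam = []
            Z, _ = _stats._covariate_design(sub, ("age", "sex"), "site")
            Zdf = pd.DataFrame(Z[:, 1:])  # intercept added inside partial_spearman
            for metric in GLOBAL_METRICS:
                y = table.loc[sub["subject_id"].astype(str), metric].to_numpy()
                try:
                    fam.append(
                        _stats.partial_spearman(
                            sub[variable].to_numpy(dtype=float), y, Zdf,
                            metric_name=metric, variable=variable,
                        )
                    )
                except ValueError as err:
                    logger.warning("correlation %s ~ %s skipped: %s", metric, variable, err)
            results.extend(_stats.fdr_annotate(fam) if fam else [])
        return results


def _group_results_frame(results) -> pd.DataFrame:
    rows = [
        {
            "metric": r.metric_name,
            "contrast": r.contrast,
            "sparsity": r.sparsity,
            "F": r.F,
            "df1": r.df1,
            "df2": r.df2,
            "p": r.p,
            "p_fdr": r.p_fdr,
            "direction": r.direction,
            "n": r.n,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def _corr_results_frame(results) -> pd.DataFrame:
    rows = [
        {
            "metric": r.metric_name,
            "variable": r.variable,
            "rho": r.rho,
            "p": r.p,
            "p_fdr": r.p_fdr,
            "n_used": r.n_used,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True, eq=False)
class StudyResults:
    """Fitted results of a :class:`DynamicNetworkStudy`."""

    model: DynamicNetworkStudy
    subject_metrics: pd.DataFrame
    group_tests: pd.DataFrame
    per_sparsity_tests: pd.DataFrame | None
    correlations: pd.DataFrame | None
    nodal_tests: dict | None
    subgroup_tests: pd.DataFrame | None
    fdr_alpha: float

    @property
    def direction_triplet(self) -> dict[str, int]:
        """Sign of the adjusted (case - control) difference per metric."""
        return dict(zip(self.group_tests["metric"], self.group_tests["direction"]))

    @property
    def significant(self) -> dict[str, bool]:
        return dict(
            zip(self.group_tests["metric"], self.group_tests["p_fdr"] < self.fdr_alpha)
        )

    def summary(self) -> str:
        case, control = self.model.groups
        pheno = self.model.phenotype
        n_case = int((pheno["group"].astype(str) == case).sum())
        n_control = len(pheno) - n_case
        lines = [
            "Dynamic functional-network group comparison",
            "=" * 60,
            f"Groups: {case} (n={n_case}) vs {control} (n={n_control}); "
            f"sites: {pheno['site'].nunique()}",
            f"Window {self.model.window_s:g} s, step {self.model.step_s:g} s, "
            f"TR {self.model.tr_s:g} s; sparsities "
            f"{self.model.sparsity_grid[0]:.2f}-{self.model.sparsity_grid[-1]:.2f} "
            f"({len(self.model.sparsity_grid)} levels)",
            "",
            "Group effects (ANCOVA, covariates: age, sex, education, mean FD, site)",
            self.group_tests[["metric", "F", "df1", "df2", "p", "p_fdr", "direction"]]
            .to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        if self.correlations is not None and len(self.correlations):
            lines += [
                "",
                "Partial Spearman correlations in patients (age, sex, site adjusted)",
                self.correlations.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            ]
        if self.subgroup_tests is not None and len(self.subgroup_tests):
            lines += [
                "",
                "Subgroup contrasts",
                self.subgroup_tests[["metric", "contrast", "F", "p", "p_fdr", "direction"]]
                .to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            ]
        return "\n".join(lines)

    def plot_sparsity_profile(self, metric: str = "temporal_correlation", ax=None):
        """Group mean +/- 95% CI of a per-sparsity metric across the grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = [float(s) for s in self.model.sparsity_grid]
        cols = [_col(metric, s) for s in grid]
        pheno = self.model.phenotype
        for grp in self.model.groups:
            ids = pheno.loc[pheno["group"].astype(str) == grp, "subject_id"].astype(str)
            vals = self.subject_metrics.loc[ids, cols].to_numpy()
            mean = vals.mean(axis=0)
            half = 1.96 * vals.std(axis=0, ddof=1) / np.sqrt(vals.shape[0])
            ax.plot(grid, mean, label=grp)
            ax.fill_between(grid, mean - half, mean + half, alpha=0.25)
        ax.set_xlabel("sparsity")
        ax.set_ylabel(metric.replace("_", " "))
        ax.legend()
        return ax

    def to_csv(self, outdir) -> None:
        """Write the tidy result tables to a directory."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.subject_metrics.to_csv(outdir / "subject_metrics.csv")
        self.group_tests.to_csv(outdir / "group_tests.csv", index=False)
        if self.per_sparsity_tests is not None:
            self.per_sparsity_tests.to_csv(outdir / "per_sparsity_tests.csv", index=False)
        if self.correlations is not None:
            self.correlations.to_csv(outdir / "correlations.csv", index=False)
        if self.subgroup_tests is not None:
            self.subgroup_tests.to_csv(outdir / "subgroup_tests.csv", index=False)
        if self.nodal_tests is not None:
            for metric, df in self.nodal_tests.items():
                df.to_csv(outdir / f"nodal_tests_{metric}.csv", index=False)


def split_half(
    pheno: pd.DataFrame, seed: int, *, strata=("group", "site")
) -> tuple[list[str], list[str]]:
    """Random split of subjects into two halves, stratified by group and site.

    Within each stratum the subjects are shuffled and split as evenly as
    possible; a stratum with a single subject is kept whole in one half
    (with a warning), alternating which half receives the odd subject.
    The halves are disjoint and exhaustive.
    """
    rng = np.random.default_rng(seed)
    ids_a: list[str] = []
    ids_b: list[str] = []
    odd_to_a = True
    for _, sub in pheno.groupby(list(strata), sort=True):
        ids = sub["subject_id"].astype(str).to_numpy()
        if len(ids) < 2:
            warnings.warn(
                f"stratum with {len(ids)} subject(s) kept whole in one half",
                stacklevel=2,
            )
        rng.shuffle(ids)
        half = len(ids) // 2 + (len(ids) % 2 if odd_to_a else 0)
        if len(ids) % 2:
            odd_to_a = not odd_to_a
        ids_a.extend(ids[:half])
        ids_b.extend(ids[half:])
    return ids_a, ids_b
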