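"""End-to-end study orchestration.

``run_study`` takes a :class:`StudyConfig` and a cohort (synthesized, passed
in, or read from a directory) and produces the four analysis families over
the per-subject AUC summaries:

1. liars, state (honest vs dishonest) × age RM-ANOVAs per metric, with the
   follow-ups on global efficiency (one-sample t on the state difference and
   its age correlation);
2. lie-free subjects, period (first vs second) × age RM-ANOVAs per metric;
3. liars vs non-liars group × age ANOVAs on the overall (whole-series) AUCs;
4. behavior–network coupling in liars: age-controlled partial correlations of
   lie frequency and first-lie trial with the overall AUCs, plus two-block
   hierarchical regressions (age, then stepwise {FLT, lie frequency}) on the
   state-change scores.

Subjects whose honest (or first) segment is too short to estimate a
correlation matrix — e.g. a liar whose first lie falls on trial 1 — are
excluded and the exclusion is recorded in the result; an analysis whose group
has fewer than 3 usable subjects is skipped and marked as such.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import correlation_matrix
from .errors import (
    ConfigError,
    DataError,
    TooShortSegmentError,
)
from .graph_metrics import (
    METRIC_NAMES,
    MetricCurves,
    auc_summary,
    metric_curves,
    sparsity_grid,
)
from .preprocess import (
    DEFAULT_MIN_SEGMENT_SECONDS,
    DEFAULT_SPLIT_FRACTION,
    bandpass_filter,
    split_at_first_lie,
    split_at_fraction,
)
from .stats import (
    between_group_anova,
    hierarchical_stepwise_regression,
    one_sample_t,
    partial_correlation,
    pearson_with_p,
    rm_anova_state_by_age,
)
from .synthetic import CohortConfig, SubjectRecord, generate_cohort, read_cohort

__all__ = ["StudyConfig", "StudyResult", "run_study", "compute_subject_aucs", "summarize", "save_result"]


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of a study run; the defaults are the reference settings.

    band 0.008-0.09 Hz, sparsity grid 0.25..0.48 step 0.01, fraction 11.5/36
    for the lie-free split, 100 degree-preserving references with 10 swap
    attempts per edge.
    """

    band_low: float = 0.008
    band_high: float = 0.09
    s1: float = 0.25
    sn: float = 0.48
    delta_s: float = 0.01
    n_random: int = 100
    rewires_per_edge: int = 10
    edge_rank: str = "abs"
    auc_rule: str = "rect"
    split_fraction: float = DEFAULT_SPLIT_FRACTION
    min_segment_seconds: float = DEFAULT_MIN_SEGMENT_SECONDS
    seed: int = 0
    n_subjects: int = 59
    cohort: CohortConfig = field(default_factory=CohortConfig)
    compute_overall: bool = True
    #: estimate both state matrices from equal-duration windows adjacent to
    #: the split point; unequal window lengths otherwise bias every
    #: threshold-based metric toward the noisier segment (see docs/methods.md)
    match_segment_lengths: bool = True

    def __post_init__(self):
        if not 0 < self.band_low < self.band_high:
            raise ConfigError("need 0 < band_low < band_high")
        if not (0 < self.s1 <= self.sn <= 1) or self.delta_s <= 0:
            raise ConfigError("invalid sparsity grid")
        if not 0 < self.split_fraction < 1:
            raise ConfigError("split_fraction must be in (0, 1)")
        if self.n_random < 1 or self.rewires_per_edge < 1:
            raise ConfigError("n_random and rewires_per_edge must be >= 1")
        if self.edge_rank not in ("abs", "positive"):
            raise ConfigError("edge_rank must be 'abs' or 'positive'")
        if self.auc_rule not in ("rect", "trapezoid"):
            raise ConfigError("auc_rule must be 'rect' or 'trapezoid'")

    def grid(self) -> np.ndarray:
        return sparsity_grid(self.s1, self.sn, self.delta_s)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["band"] = list(d["cohort"]["band"])
        d["cohort"]["age_range"] = list(d["cohort"]["age_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        try:
            if "cohort" in d:
                c = dict(d["cohort"])
                if "band" in c:
                    c["band"] = tuple(c["band"])
                if "age_range" in c:
                    c["age_range"] = tuple(c["age_range"])
                if "behavior" in c and isinstance(c["behavior"], dict):
                    from .synthetic import BehaviorModel

                    c["behavior"] = BehaviorModel(**c["behavior"])
                d["cohort"] = CohortConfig(**c)
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid study config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        try:
            with open(path) as fh:
                d = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


@dataclass
class StudyResult:
    """Result bundle of one study run."""

    config: StudyConfig
    auc_table: pd.DataFrame
    anova_liars: pd.DataFrame | None
    anova_nonliars: pd.DataFrame | None
    anova_groups: pd.DataFrame | None
    followups: pd.DataFrame | None
    partial_correlations: pd.DataFrame | None
    stepwise: dict[str, object]
    exclusions: list[tuple[str, str]]
    manifest: dict
    curves: dict[str, dict[str, MetricCurves]] = field(default_factory=dict)


def _segment_seed(master_seed: int, subject_index: int, segment_index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, subject_index, segment_index])
    return int(ss.generate_state(1)[0] & 0x3FFFFFFF)


def compute_subject_aucs(
    records: list[SubjectRecord],
    config: StudyConfig,
    keep_curves: bool = False,
) -> tuple[pd.DataFrame, list[tuple[str, str]], dict]:
    """Per-subject segment-wise (and overall) AUCs for the five metrics.

    Returns (table, exclusions, curves). The table has one row per usable
    subject with columns ``{metric}_s1``, ``{metric}_s2`` (and
    ``{metric}_overall`` when configured), plus age, group, FLT and lie count.
    """
    grid = config.grid()
    rows = []
    exclusions: list[tuple[str, str]] = []
    curves_store: dict[str, dict[str, MetricCurves]] = {}
    for idx, rec in enumerate(records):
        try:
            filtered = bandpass_filter(rec.timeseries, config.band_low, config.band_high)
            if rec.is_liar:
                segs = split_at_first_lie(filtered, rec.trial_log, config.min_segment_seconds)
            else:
                segs = split_at_fraction(filtered, config.split_fraction, config.min_segment_seconds)
        except TooShortSegmentError as exc:
            exclusions.append((rec.subject_id, str(exc)))
            continue
        s1, s2 = segs.first, segs.second
        if config.match_segment_lengths:
            n_min = min(s1.n_samples, s2.n_samples)
            s1 = s1.slice_samples(s1.n_samples - n_min, s1.n_samples)
            s2 = s2.slice_samples(0, n_min)
        segments = {"s1": s1, "s2": s2}
        if config.compute_overall:
            segments["overall"] = filtered
        row = {
            "subject_id": rec.subject_id,
            "age_years": rec.age_years,
            "group": "liar" if rec.is_liar else "nonliar",
            "flt_trial": rec.flt_trial if rec.flt_trial is not None else np.nan,
            "lie_count": rec.lie_count,
        }
        sub_curves: dict[str, MetricCurves] = {}
        for seg_idx, (label, seg) in enumerate(segments.items()):
            C = correlation_matrix(seg, segment_label=f"{rec.subject_id}:{label}")
            curves = metric_curves(
                C,
                grid,
                n_random=config.n_random,
                rewires_per_edge=config.rewires_per_edge,
                seed=_segment_seed(config.seed, idx, seg_idx),
                edge_rank=config.edge_rank,
            )
            summary = auc_summary(curves, rule=config.auc_rule)
            for metric in METRIC_NAMES:
                row[f"{metric}_{label}"] = summary.auc[metric]
            if keep_curves:
                sub_curves[label] = curves
        rows.append(row)
        if keep_curves:
            curves_store[rec.subject_id] = sub_curves
    table = pd.DataFrame(rows)
    return table, exclusions, curves_store


def _anova_table(table: pd.DataFrame) -> pd.DataFrame | None:
    if len(table) < 3:
        return None
    out = []
    for metric in METRIC_NAMES:
        for res in rm_anova_state_by_age(table, metric):
            out.append((metric, res.effect, res.f, res.df1, res.df2, res.p, res.eta_squared))
    return pd.DataFrame(out, columns=["metric", "effect", "F", "df1", "df2", "p", "eta_sq"])


def run_study(
    config: StudyConfig | None = None,
    cohort: list[SubjectRecord] | None = None,
    data_dir: str | Path | None = None,
    keep_curves: bool = False,
) -> StudyResult:
    """Run the full analysis battery; see the module docstring for the four families."""
    config = config or StudyConfig()
    if cohort is None:
        if data_dir is not None:
            try:
                cohort = read_cohort(data_dir, config.cohort.sampling_rate)
            except (OSError, KeyError, ValueError) as exc:
                raise DataError(f"cannot read cohort from {data_dir}: {exc}") from exc
        else:
            cohort = generate_cohort(config.n_subjects, config.cohort, seed=config.seed)
    if len(cohort) < 2:
        raise DataError("cohort must have at least 2 subjects")

    table, exclusions, curves = compute_subject_aucs(cohort, config, keep_curves=keep_curves)
    liars = table[table.group == "liar"].reset_index(drop=True)
    nonliars = table[table.group == "nonliar"].reset_index(drop=True)
    if len(liars) < 3 and len(nonliars) < 3:
        raise DataError(
            f"fewer than 3 usable subjects in both groups "
            f"({len(liars)} liars, {len(nonliars)} non-liars)"
        )

    # analysis 1: state x age in liars (+ global-efficiency follow-ups)
    anova_liars = _anova_table(liars)
    followups = None
    if anova_liars is not None:
        d_eglob = (liars["e_glob_s2"] - liars["e_glob_s1"]).to_numpy()
        rows = []
        try:
            t, df, p, cd = one_sample_t(d_eglob)
            rows.append(("e_glob state change: one-sample t", t, df, p, cd))
        except Exception:  # zero-variance difference: nothing to report
            pass
        try:
            r, p = pearson_with_p(liars["age_years"].to_numpy(), d_eglob)
            rows.append(("e_glob state change vs age: Pearson r", r, len(liars) - 2, p, np.nan))
        except Exception:
            pass
        followups = pd.DataFrame(rows, columns=["test", "statistic", "df", "p", "effect_size"])

    # analysis 2: period x age in non-liars
    anova_nonliars = _anova_table(nonliars)

    # analysis 3: liars vs non-liars on overall AUCs
    anova_groups = None
    if config.compute_overall and len(liars) >= 3 and len(nonliars) >= 3:
        out = []
        for metric in METRIC_NAMES:
            results = between_group_anova(
                table[f"{metric}_overall"].to_numpy(),
                table["group"].to_numpy(),
                table["age_years"].to_numpy(),
            )
            for res in results:
                out.append((metric, res.effect, res.f, res.df1, res.df2, res.p, res.eta_squared))
        anova_groups = pd.DataFrame(out, columns=["metric", "effect", "F", "df1", "df2", "p", "eta_sq"])

    # analysis 4: behavior-network coupling in liars
    partials = None
    stepwise: dict[str, object] = {}
    # the stepwise model uses 3 predictors: need n > 3 + 2
    if len(liars) >= 6 and config.compute_overall:
        age = liars["age_years"].to_numpy()
        rows = []
        for behavior_var in ("lie_count", "flt_trial"):
            b = liars[behavior_var].to_numpy(float)
            for metric in METRIC_NAMES:
                r, p = partial_correlation(b, liars[f"{metric}_overall"].to_numpy(), age)
                rows.append((behavior_var, metric, r, p))
        partials = pd.DataFrame(rows, columns=["behavior", "metric", "partial_r", "p"])
        for metric in METRIC_NAMES:
            change = (liars[f"{metric}_s2"] - liars[f"{metric}_s1"]).to_numpy()
            stepwise[metric] = hierarchical_stepwise_regression(
                change,
                block1={"age_years": age},
                block2_candidates={
                    "flt_trial": liars["flt_trial"].to_numpy(float),
                    "lie_count": liars["lie_count"].to_numpy(float),
                },
            )

    manifest = {
        "netlie_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "n_subjects_in": len(cohort),
        "n_subjects_used": int(len(table)),
        "n_liars": int(len(liars)),
        "n_nonliars": int(len(nonliars)),
        "exclusions": [{"subject_id": s, "reason": r} for s, r in exclusions],
        "versions": _versions(),
    }
    return StudyResult(
        config=config,
        auc_table=table,
        anova_liars=anova_liars,
        anova_nonliars=anova_nonliars,
        anova_groups=anova_groups,
        followups=followups,
        partial_correlations=partials,
        stepwise=stepwise,
        exclusions=exclusions,
        manifest=manifest,
        curves=curves,
    )


def _versions() -> dict:
    import networkx
    import numba
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "numba": numba.__version__,
    }


# ---------------------------------------------------------------------------
# reporting and persistence
# ---------------------------------------------------------------------------

def _fmt_table(df: pd.DataFrame) -> str:
    return df.to_string(index=False, float_format=lambda v: f"{v:.4f}")


def summarize(result: StudyResult) -> str:
    """Deterministic human-readable markdown report of the four analyses."""
    lines = [
        "# Study report",
        "",
        f"Subjects used: {result.manifest['n_subjects_used']} "
        f"({result.manifest['n_liars']} liars, {result.manifest['n_nonliars']} lie-free); "
        f"excluded: {len(result.exclusions)}",
        f"Seed: {result.manifest['seed']}; config sha256: {result.manifest['config_sha256'][:12]}",
        "",
    ]
    sections = [
        ("Analysis 1: state (honest vs dishonest) x age RM-ANOVAs, liars", result.anova_liars),
        ("Analysis 2: period (first vs second) x age RM-ANOVAs, lie-free subjects", result.anova_nonliars),
        ("Analysis 3: group (liar vs lie-free) x age ANOVAs, overall AUCs", result.anova_groups),
    ]
    for title, df in sections:
        lines.append(f"## {title}")
        lines.append("")
        lines.append(_fmt_table(df) if df is not None else "skipped: fewer than 3 usable subjects in a group")
        lines.append("")
    if result.followups is not None and len(result.followups):
        lines.append("### Global-efficiency follow-ups (liars)")
        lines.append("")
        lines.append(_fmt_table(result.followups))
        lines.append("")
    lines.append("## Analysis 4: behavior-network coupling, liars")
    lines.append("")
    if result.partial_correlations is not None:
        lines.append("Age-controlled partial correlations:")
        lines.append("")
        lines.append(_fmt_table(result.partial_correlations))
        lines.append("")
        for metric, sw in result.stepwise.items():
            lines.append(f"Stepwise regression on {metric} state change "
                         f"(final R^2 = {sw.r_squared:.4f}; "
                         f"predictors: {', '.join(sw.final_predictors) or 'none'})")
            lines.append("")
            lines.append(_fmt_table(sw.coefficients))
            lines.append("")
    else:
        lines.append("skipped: fewer than 6 usable liars")
        lines.append("")
    if result.exclusions:
        lines.append("## Exclusions")
        lines.append("")
        for sid, reason in result.exclusions:
            lines.append(f"- {sid}: {reason}")
        lines.append("")
    return "\n".join(lines)


def save_result(result: StudyResult, out_dir: str | Path) -> None:
    """Write the result bundle as CSVs, a manifest, and the markdown report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.auc_table.to_csv(out / "subject_aucs.csv", index=False)
    for name, df in [
        ("anova_liars", result.anova_liars),
        ("anova_nonliars", result.anova_nonliars),
        ("anova_groups", result.anova_groups),
        ("followups", result.followups),
        ("partial_correlations", result.partial_correlations),
    ]:
        if df is not None:
            df.to_csv(out / f"{name}.csv", index=False)
    if result.stepwise:
        frames = []
        for metric, sw in result.stepwise.items():
            steps = pd.DataFrame([asdict(s) for s in sw.steps])
            steps.insert(0, "metric", metric)
            frames.append(steps)
        pd.concat(frames).to_csv(out / "stepwise_steps.csv", index=False)
        frames = []
        for metric, sw in result.stepwise.items():
            coef = sw.coefficients.copy()
            coef.insert(0, "metric", metric)
            frames.append(coef)
        pd.concat(frames).to_csv(out / "stepwise_coefficients.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    with open(out / "report.md", "w") as fh:
        fh.write(summarize(result))


def plot_group_curves(result: StudyResult, path: str | Path) -> None:
    """Group-mean metric curves over the sparsity grid (requires keep_curves)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not result.curves:
        raise DataError("run_study(..., keep_curves=True) required for plotting")
    grid = result.config.grid()
    groups = dict(zip(result.auc_table.subject_id, result.auc_table.group))
    fig, axes = plt.subplots(1, len(METRIC_NAMES), figsize=(4 * len(METRIC_NAMES), 3.2))
    for ax, metric in zip(np.atleast_1d(axes), METRIC_NAMES):
        for group, seg, style in [("liar", "s1", "-"), ("liar", "s2", "--"),
                                  ("nonliar", "s1", ":"), ("nonliar", "s2", "-.")]:
            vals = [
                c[seg][metric]
                for sid, c in result.curves.items()
                if groups.get(sid) == group and seg in c
            ]
            if vals:
                ax.plot(grid, np.mean(vals, axis=0), style, label=f"{group} {seg}")
        ax.set_title(metric)
        ax.set_xlabel("sparsity")
    np.atleast_1d(axes)[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
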