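"""Statistical comparison of pulse-extraction methods over paired videos.

The benchmark produces, per comparison metric, an N (videos) x k (methods)
matrix of paired measurements.  The engine then follows the standard
decision tree for repeated-measure designs:

* assumptions: Shapiro-Wilk normality per group; variance homogeneity via
  Bartlett when every group is normal, Levene otherwise;
* two groups: paired t-test when both normal, Wilcoxon signed-rank
  otherwise;
* more than two groups: repeated-measures ANOVA when normal and
  homoskedastic, Friedman otherwise;
* post hoc: Tukey (after ANOVA) or Nemenyi (after Friedman), plus the
  critical-difference (CD) value that renders a CD diagram;
* effect sizes: Cohen's d for normal populations, Akinshin's gamma (a
  robust, MAD-scaled median difference) otherwise, with the conventional
  negligible/small/medium/large labels at 0.2/0.5/0.8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

from .errors import ParameterError, ResultsFormatError, StatsError

__all__ = [
    "ResultsTable",
    "Assumptions",
    "StatReport",
    "check_assumptions",
    "select_test",
    "run_comparison",
    "cd_diagram_data",
    "cohens_d",
    "akinshin_gamma",
    "effect_magnitude",
]

#: Minimum paired observations for any test.
MIN_SAMPLES = 5

_RESULTS_FORMAT_VERSION = 1
_COLUMNS = ["dataset", "video_id", "method", "metric", "value"]


class ResultsTable:
    """Long-format per-video, per-method metric records.

    One row per (dataset, video_id, method, metric); the matrix view used
    by the tests keeps complete cases only (videos with a value for every
    method).
    """

    def __init__(self, records: pd.DataFrame | None = None):
        if records is None:
            records = pd.DataFrame(columns=_COLUMNS)
        missing = set(_COLUMNS) - set(records.columns)
        if missing:
            raise ParameterError(f"results table missing columns {sorted(missing)}")
        self.records = records[_COLUMNS].reset_index(drop=True)

    def add(self, dataset: str, video_id: str, method: str, metric: str, value: float) -> None:
        row = pd.DataFrame(
            [[dataset, video_id, method, metric, float(value)]], columns=_COLUMNS
        )
        if self.records.empty:
            self.records = row
        else:
            self.records = pd.concat([self.records, row], ignore_index=True)

    def __len__(self) -> int:
        return len(self.records)

    def methods(self) -> list[str]:
        return sorted(self.records["method"].unique())

    def matrix(self, metric: str) -> pd.DataFrame:
        """Complete-case N x k matrix (videos x methods) for one metric."""
        sub = self.records[self.records["metric"] == metric]
        if sub.empty:
            raise ParameterError(f"no records for metric {metric!r}")
        if sub.duplicated(["dataset", "video_id", "method"]).any():
            raise ParameterError("duplicate (video, method) entries for metric")
        wide = sub.pivot_table(
            index=["dataset", "video_id"], columns="method", values="value"
        )
        return wide.dropna(axis=0, how="any")

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        """Persist as HDF5 (``.h5``/``.hdf5``) or CSV, by extension."""
        path = str(path)
        if path.endswith((".h5", ".hdf5")):
            import h5py

            with h5py.File(path, "w") as f:
                f.attrs["format_version"] = _RESULTS_FORMAT_VERSION
                g = f.create_group("records")
                for col in _COLUMNS:
                    data = self.records[col].to_numpy()
                    if col == "value":
                        g.create_dataset(col, data=data.astype(float))
                    else:
                        g.create_dataset(
                            col, data=np.array([str(x) for x in data], dtype=object),
                            dtype=h5py.string_dtype(),
                        )
        else:
            self.records.to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "ResultsTable":
        path = str(path)
        if path.endswith((".h5", ".hdf5")):
            import h5py

            with h5py.File(path, "r") as f:
                version = f.attrs.get("format_version")
                if version != _RESULTS_FORMAT_VERSION:
                    raise ResultsFormatError(
                        f"unsupported results format version {version!r}"
                    )
                if "records" not in f:
                    raise ResultsFormatError("missing 'records' group")
                g = f["records"]
                data = {}
                for col in _COLUMNS:
                    if col not in g:
                        raise ResultsFormatError(f"missing column {col!r}")
                    arr = g[col][()]
                    if col == "value":
                        data[col] = arr.astype(float)
                    else:
                        data[col] = [
                            x.decode() if isinstance(x, bytes) else str(x) for x in arr
                        ]
                return cls(pd.DataFrame(data))
        df = pd.read_csv(path)
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise ResultsFormatError(f"CSV missing columns {sorted(missing)}")
        return cls(df)


# --------------------------------------------------------------------------
# Assumption checks and test selection
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Assumptions:
    """Outcome of normality and variance-homogeneity checks."""

    normal: dict  # method -> bool (True = normality retained)
    normality_p: dict  # method -> p-value (NaN where skipped)
    all_normal: bool
    homoskedastic: bool
    homogeneity_test: str  # 'bartlett' | 'levene' | 'skipped'
    homogeneity_p: float
    degenerate: tuple  # methods with (near-)zero variance, tests skipped


def check_assumptions(matrix: pd.DataFrame | np.ndarray, alpha: float = 0.05) -> Assumptions:
    """Shapiro-Wilk per group, then Bartlett (all normal) or Levene.

    Groups with (near-)zero variance are flagged degenerate: the normality
    test is skipped for them and they are treated as non-normal so the
    downstream choice falls back to the rank-based path.
    """
    mat, names = _as_matrix(matrix)
    N = mat.shape[0]
    if N < MIN_SAMPLES:
        raise StatsError(f"need at least {MIN_SAMPLES} paired samples, got {N}")
    normal, norm_p, degenerate = {}, {}, []
    for j, name in enumerate(names):
        col = mat[:, j]
        if np.std(col) < 1e-12:
            degenerate.append(name)
            normal[name] = False
            norm_p[name] = np.nan
            continue
        stat, p = sst.shapiro(col)
        normal[name] = bool(p > alpha)
        norm_p[name] = float(p)
    all_normal = all(normal.values())
    nondeg = [mat[:, j] for j, n in enumerate(names) if n not in degenerate]
    if len(nondeg) < 2:
        test, p = "skipped", np.nan
        homo = True
    elif all_normal:
        test = "bartlett"
        _, p = sst.bartlett(*nondeg)
        homo = bool(p > alpha)
    else:
        test = "levene"
        _, p = sst.levene(*nondeg)
        homo = bool(p > alpha)
    return Assumptions(
        normal=normal,
        normality_p=norm_p,
        all_normal=all_normal,
        homoskedastic=homo,
        homogeneity_test=test,
        homogeneity_p=float(p) if p == p else np.nan,
        degenerate=tuple(degenerate),
    )


def select_test(k: int, assumptions: Assumptions) -> str:
    """Decision tree mapping group count and assumptions to a test id.

    Returns one of ``paired_t``, ``wilcoxon``, ``rm_anova``, ``friedman``.
    """
    if k < 2:
        raise ParameterError("need at least two groups to compare")
    if k == 2:
        return "paired_t" if assumptions.all_normal else "wilcoxon"
    if assumptions.all_normal and assumptions.homoskedastic:
        return "rm_anova"
    return "friedman"


# --------------------------------------------------------------------------
# Effect sizes
# --------------------------------------------------------------------------


def cohens_d(a, b) -> float:
    """Paired Cohen's d: mean difference over the sd of the differences."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    s = d.std(ddof=1)
    if s == 0:
        return 0.0
    return float(d.mean() / s)


def akinshin_gamma(a, b) -> float:
    """Robust effect size: median difference over a pooled MAD scale.

    gamma = (MD_a - MD_b) / sqrt((s_a^2 + s_b^2) / 2) with
    s = 1.4826 * MAD, the Gaussian-consistent robust scale.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    md_a, md_b = np.median(a), np.median(b)
    s_a = 1.4826 * np.median(np.abs(a - md_a))
    s_b = 1.4826 * np.median(np.abs(b - md_b))
    pooled = np.sqrt((s_a**2 + s_b**2) / 2.0)
    if pooled == 0:
        return 0.0
    return float((md_a - md_b) / pooled)


def effect_magnitude(value: float, cuts=(0.2, 0.5, 0.8)) -> str:
    """Conventional magnitude label for an effect size."""
    v = abs(value)
    if v < cuts[0]:
        return "negligible"
    if v < cuts[1]:
        return "small"
    if v < cuts[2]:
        return "medium"
    return "large"


# --------------------------------------------------------------------------
# Omnibus + post hoc
# --------------------------------------------------------------------------


def _as_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), [str(c) for c in matrix.columns]
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2:
        raise ParameterError("matrix must be 2-D (videos x methods)")
    return mat, [f"method_{j}" for j in range(mat.shape[1])]


def _mean_ranks(mat: np.ndarray) -> np.ndarray:
    """Mean rank per method; rank 1 = smallest value within each video."""
    ranks = np.apply_along_axis(sst.rankdata, 1, mat)
    return ranks.mean(axis=0)


def _rm_anova(mat: np.ndarray) -> tuple[float, float, float, float]:
    """One-way repeated-measures ANOVA (subject-blocked two-way layout).

    Returns (F, p, df_treat, df_error).  No sphericity correction is
    applied.
    """
    N, k = mat.shape
    grand = mat.mean()
    ss_treat = N * ((mat.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((mat.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((mat - grand) ** 2).sum()
    ss_err = ss_total - ss_treat - ss_subj
    df_t = k - 1
    df_e = (N - 1) * (k - 1)
    ms_t = ss_treat / df_t
    ms_e = ss_err / df_e if df_e > 0 else np.nan
    if not np.isfinite(ms_e) or ms_e <= 0:
        return np.inf, 0.0, df_t, df_e
    F = ms_t / ms_e
    return float(F), float(sst.f.sf(F, df_t, df_e)), df_t, df_e


def _tukey_posthoc(mat: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Tukey HSD p-values using the repeated-measures error term."""
    N, k = mat.shape
    _, _, _, df_e = _rm_anova(mat)
    grand = mat.mean()
    ss_treat = N * ((mat.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((mat.mean(axis=1) - grand) ** 2).sum()
    ss_err = ((mat - grand) ** 2).sum() - ss_treat - ss_subj
    ms_e = ss_err / df_e
    means = mat.mean(axis=0)
    p = np.ones((k, k))
    se = np.sqrt(ms_e / N) if ms_e > 0 else 0.0
    for i in range(k):
        for j in range(i + 1, k):
            if se == 0:
                pij = 0.0 if means[i] != means[j] else 1.0
            else:
                q = abs(means[i] - means[j]) / se
                pij = float(sst.studentized_range.sf(q, k, df_e))
            p[i, j] = p[j, i] = pij
    return pd.DataFrame(p, index=names, columns=names)


def _nemenyi_posthoc(mat: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Nemenyi p-values from the mean-rank differences."""
    N, k = mat.shape
    R = _mean_ranks(mat)
    se = np.sqrt(k * (k + 1) / (6.0 * N))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(R[i] - R[j]) / se * np.sqrt(2.0)
            pij = float(sst.studentized_range.sf(q, k, np.inf))
            p[i, j] = p[j, i] = min(1.0, pij)
    return pd.DataFrame(p, index=names, columns=names)


def cd_diagram_data(
    mean_ranks,
    N: int,
    k: int,
    alpha: float = 0.05,
    test: str = "friedman",
) -> tuple[float, list[tuple[str, ...]]]:
    """Critical difference and groups of statistically tied methods.

    CD = q_alpha * sqrt(k(k+1)/(6N)) with q_alpha the alpha-level
    studentized-range quantile (infinite df) divided by sqrt(2).  Methods
    whose mean-rank difference does not exceed the CD are joined; the
    returned groups are the maximal such runs in rank order — exactly the
    thick lines of a CD diagram.

    Only meaningful downstream of a Friedman analysis; any other ``test``
    raises :class:`StatsError`.
    """
    if test != "friedman":
        raise StatsError("critical-difference analysis applies to the Friedman path only")
    if isinstance(mean_ranks, dict):
        names = list(mean_ranks)
        ranks = np.array([mean_ranks[n] for n in names], dtype=float)
    else:
        ranks = np.asarray(mean_ranks, dtype=float)
        names = [f"method_{j}" for j in range(len(ranks))]
    if len(ranks) != k:
        raise ParameterError("mean_ranks length must equal k")
    q_alpha = sst.studentized_range.ppf(1.0 - alpha, k, np.inf) / np.sqrt(2.0)
    cd = float(q_alpha * np.sqrt(k * (k + 1) / (6.0 * N)))
    order = np.argsort(ranks)
    groups: list[tuple[str, ...]] = []
    for start in range(k):
        members = [
            names[order[j]]
            for j in range(start, k)
            if ranks[order[j]] - ranks[order[start]] <= cd
        ]
        if not any(set(members) <= set(g) for g in groups):
            groups.append(tuple(members))
    return cd, groups


@dataclass
class StatReport:
    """Full outcome of one method-comparison analysis."""

    metric: str
    alpha: float
    assumptions: Assumptions
    test: str
    statistic: float
    p_value: float
    group_stats: pd.DataFrame  # index method: MD, SD, MAD, MR
    posthoc: pd.DataFrame | None
    effect_sizes: pd.DataFrame  # columns: a, b, name, value, magnitude
    cd: float | None = None
    cd_groups: list | None = None
    no_variance: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def rejected(self) -> bool:
        return bool(self.p_value < self.alpha) if np.isfinite(self.p_value) else False

    def summary(self) -> str:
        """Plain-text narrative of the analysis."""
        lines = []
        if self.no_variance:
            return (
                f"All groups are identical for metric {self.metric}; "
                "no variance, no test run."
            )
        a = self.assumptions
        rej = [m for m, ok in a.normal.items() if not ok and m not in a.degenerate]
        if rej:
            lines.append(
                "The Shapiro-Wilk test rejected normality for: " + ", ".join(rej) + "."
            )
        else:
            lines.append("The Shapiro-Wilk test retained normality for all populations.")
        if a.degenerate:
            lines.append(
                "Degenerate (zero-variance) populations, normality test skipped: "
                + ", ".join(a.degenerate) + "."
            )
        lines.append(
            f"Selected test: {self.test} (alpha={self.alpha}); "
            f"statistic={self.statistic:.4g}, p={self.p_value:.4g} -> "
            + ("rejected" if self.rejected else "not rejected") + "."
        )
        for m, row in self.group_stats.iterrows():
            lines.append(
                f"  {m}: MD={row['MD']:.4g} +/- {row['SD']:.4g}, "
                f"MAD={row['MAD']:.4g}, MR={row['MR']:.4g}"
            )
        if self.effect_sizes is not None and len(self.effect_sizes):
            for _, r in self.effect_sizes.iterrows():
                lines.append(
                    f"  effect {r['a']} vs {r['b']}: {r['name']}={r['value']:.3f} "
                    f"({r['magnitude']})"
                )
        if self.cd is not None:
            lines.append(f"Critical difference at alpha={self.alpha}: CD={self.cd:.4g}")
            lines.append("Tied groups: " + "; ".join(str(g) for g in self.cd_groups))
        return "\n".join(lines)

    def to_json(self) -> str:
        import json

        payload = {
            "metric": self.metric,
            "alpha": self.alpha,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "rejected": self.rejected,
            "no_variance": self.no_variance,
            "normality": self.assumptions.normal,
            "homoskedastic": self.assumptions.homoskedastic,
            "group_stats": self.group_stats.to_dict(orient="index"),
            "effect_sizes": self.effect_sizes.to_dict(orient="records"),
            "cd": self.cd,
            "cd_groups": [list(g) for g in self.cd_groups] if self.cd_groups else None,
        }
        return json.dumps(payload, indent=2, default=float)


def run_comparison(
    table: "ResultsTable | pd.DataFrame | np.ndarray",
    metric: str = "CCC",
    alpha: float = 0.05,
) -> StatReport:
    """Full automatic comparison of k methods on one metric.

    Accepts a :class:`ResultsTable` (pivoted on ``metric``), a wide
    DataFrame (videos x methods) or a plain matrix.  Runs the assumption
    checks, picks and executes the omnibus test, and on rejection adds the
    matching post hoc (Tukey after ANOVA, Nemenyi after Friedman) and, on
    the Friedman path, the critical-difference data.
    """
    if isinstance(table, ResultsTable):
        wide = table.matrix(metric)
    else:
        wide = table
    mat, names = _as_matrix(wide)
    N, k = mat.shape
    if N < MIN_SAMPLES:
        raise StatsError(f"need at least {MIN_SAMPLES} complete cases, got {N}")
    if k < 2:
        raise ParameterError("need at least two methods to compare")

    group_stats = pd.DataFrame(
        {
            "MD": np.median(mat, axis=0),
            "SD": mat.std(axis=0, ddof=1),
            "MAD": np.median(np.abs(mat - np.median(mat, axis=0)), axis=0),
            "MR": _mean_ranks(mat),
        },
        index=names,
    )

    if np.all(mat.std(axis=0) < 1e-12):
        return StatReport(
            metric=metric, alpha=alpha,
            assumptions=Assumptions({}, {}, False, True, "skipped", np.nan, tuple(names)),
            test="none", statistic=np.nan, p_value=np.nan,
            group_stats=group_stats, posthoc=None,
            effect_sizes=pd.DataFrame(columns=["a", "b", "name", "value", "magnitude"]),
            no_variance=True,
        )

    assumptions = check_assumptions(wide if isinstance(wide, pd.DataFrame) else mat, alpha)
    test = select_test(k, assumptions)

    posthoc = None
    cd = cd_groups = None
    if test == "paired_t":
        stat, p = sst.ttest_rel(mat[:, 0], mat[:, 1])
    elif test == "wilcoxon":
        d = mat[:, 0] - mat[:, 1]
        if np.all(d == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sst.wilcoxon(mat[:, 0], mat[:, 1])
    elif test == "rm_anova":
        stat, p, _, _ = _rm_anova(mat)
        if p < alpha:
            posthoc = _tukey_posthoc(mat, names)
    else:  # friedman
        stat, p = sst.friedmanchisquare(*[mat[:, j] for j in range(k)])
        if p < alpha:
            posthoc = _nemenyi_posthoc(mat, names)
        cd, cd_groups = cd_diagram_data(
            dict(zip(names, group_stats["MR"])), N, k, alpha, test="friedman"
        )

    es_rows = []
    es_fn, es_name = (
        (cohens_d, "d") if assumptions.all_normal else (akinshin_gamma, "gamma")
    )
    for i in range(k):
        for j in range(i + 1, k):
            v = es_fn(mat[:, i], mat[:, j])
            es_rows.append(
                {"a": names[i], "b": names[j], "name": es_name, "value": v,
                 "magnitude": effect_magnitude(v)}
            )
    effect_sizes = pd.DataFrame(es_rows)

    return StatReport(
        metric=metric,
        alpha=alpha,
        assumptions=assumptions,
        test=test,
        statistic=float(stat),
        p_value=float(p),
        group_stats=group_stats,
        posthoc=posthoc,
        effect_sizes=effect_sizes,
        cd=cd,
        cd_groups=cd_groups,
    )
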