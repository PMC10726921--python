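"""Tumour mutation burden estimation accuracy per library.

For each library the cohort's per-sample library TMB (captured mutations over
library coverage) is compared with the WGS TMB via Pearson correlation, the
median absolute rate difference (mutations/Mb) and a multiplicative bias
theta = median(lib_rate / wgs_rate). The library-level error is regressed on
coverage on log2-log2 scale; binomial sampling of uniformly placed mutations
predicts a slope of -1/2 (error halves for each 4-fold coverage increase),
while mutation clustering in real genomes flattens the slope.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .digest import FragmentLibrary, capture_mutations
from .genome_io import GenomeSequence, MutationCatalog
from .signatures import adjust_pvalues

logger = logging.getLogger(__name__)


def mutation_rate(count: int, denom_bp: int) -> float:
    """Mutations per megabase."""
    if denom_bp <= 0:
        raise ValueError(f"denominator must be positive, got {denom_bp}")
    return count / denom_bp * 1e6


@dataclass
class LibraryEvaluation:
    """TMB-accuracy metrics of one library over a cohort."""

    library_name: str
    coverage_bp: int
    pairs: pd.DataFrame  # columns: sample, wgs_rate, lib_rate
    pearson_r: float
    pearson_p: float
    median_abs_diff: float
    theta: float
    n_theta_excluded: int  # samples with wgs_rate == 0, excluded from theta


@dataclass
class ErrorRegressionFit:
    """OLS of log2(error metric) on log2(coverage) across libraries."""

    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]
    libraries_used: list[str]
    metric: str
    # sufficient statistics for prediction intervals
    n: int
    x_mean: float
    sxx: float
    residual_se: float

    def predict(self, log2_coverage: float) -> float:
        return self.intercept + self.slope * log2_coverage

    def prediction_interval(
        self, log2_coverage: float, level: float = 0.95
    ) -> tuple[float, float]:
        """Two-sided prediction interval for a new library's log2(metric)."""
        t = stats.t.ppf(0.5 + level / 2, self.n - 2)
        se = self.residual_se * np.sqrt(
            1 + 1 / self.n + (log2_coverage - self.x_mean) ** 2 / self.sxx
        )
        mid = self.predict(log2_coverage)
        return mid - t * se, mid + t * se


def evaluate_library(
    cohort: Mapping[str, MutationCatalog],
    library: FragmentLibrary,
    genome: GenomeSequence,
    wgs_denom_bp: int | None = None,
) -> LibraryEvaluation:
    """Per-sample library vs WGS mutation rates and the three accuracy metrics.

    wgs_denom_bp defaults to the genome's non-N length. Samples with zero WGS
    rate are excluded from theta and counted.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if library.coverage_bp <= 0:
        raise ValueError(f"library {library.name} has zero coverage")
    denom = wgs_denom_bp if wgs_denom_bp is not None else genome.non_n_length
    rows = []
    for sample in sorted(cohort):
        cat = cohort[sample]
        lib_n = capture_mutations(cat, library).n_records
        rows.append(
            (
                sample,
                mutation_rate(cat.n_records, denom),
                mutation_rate(lib_n, library.coverage_bp),
            )
        )
    pairs = pd.DataFrame(rows, columns=["sample", "wgs_rate", "lib_rate"])
    if len(pairs) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    r, p = stats.pearsonr(pairs["wgs_rate"], pairs["lib_rate"])
    mad = float(np.median(np.abs(pairs["lib_rate"] - pairs["wgs_rate"])))
    nonzero = pairs["wgs_rate"] > 0
    theta = float(np.median(pairs.loc[nonzero, "lib_rate"] / pairs.loc[nonzero, "wgs_rate"]))
    n_excl = int((~nonzero).sum())
    if n_excl:
        logger.info(
            "%s: %d samples with zero WGS rate excluded from theta",
            library.name,
            n_excl,
        )
    return LibraryEvaluation(
        library.name, library.coverage_bp, pairs, float(r), float(p), mad, theta, n_excl
    )


def correlation_significance(
    evals: Sequence[LibraryEvaluation], method: str = "holm"
) -> pd.DataFrame:
    """Per-library Pearson r with multiplicity-adjusted p-values."""
    df = pd.DataFrame(
        {
            "library": [e.library_name for e in evals],
            "pearson_r": [e.pearson_r for e in evals],
            "p_raw": [e.pearson_p for e in evals],
        }
    )
    df["p_adj"] = adjust_pvalues(df["p_raw"], method=method)
    return df


def _metric_value(ev: LibraryEvaluation, metric: str) -> float:
    if metric == "median_abs_diff":
        return ev.median_abs_diff
    if metric == "theta":
        # distance of the multiplicative bias from 1 on log2 scale
        return abs(np.log2(ev.theta)) if ev.theta > 0 else np.nan
    raise ValueError(f"unknown metric {metric!r}")


def coverage_error_regression(
    evals: Sequence[LibraryEvaluation],
    r_min: float = 0.9,
    metric: str = "median_abs_diff",
) -> ErrorRegressionFit:
    """OLS of log2(error metric) on log2(coverage_bp) across libraries, after
    removing libraries with Pearson r below ``r_min``. 95% CIs via the t
    distribution."""
    eligible = [
        e
        for e in evals
        if e.pearson_r >= r_min and np.isfinite(_metric_value(e, metric))
        and _metric_value(e, metric) > 0
    ]
    if len(eligible) < 3:
        raise ValueError(
            f"need >= 3 eligible libraries with positive {metric}; "
            f"have {len(eligible)}"
        )
    x = np.log2([e.coverage_bp for e in eligible])
    y = np.log2([_metric_value(e, metric) for e in eligible])
    n = len(x)
    res = stats.linregress(x, y)
    dof = n - 2
    t = stats.t.ppf(0.975, dof)
    resid = y - (res.intercept + res.slope * x)
    s2 = float(np.sum(resid**2) / dof)
    return ErrorRegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci95=(float(res.slope - t * res.stderr), float(res.slope + t * res.stderr)),
        intercept_ci95=(
            float(res.intercept - t * res.intercept_stderr),
            float(res.intercept + t * res.intercept_stderr),
        ),
        libraries_used=[e.library_name for e in eligible],
        metric=metric,
        n=n,
        x_mean=float(np.mean(x)),
        sxx=float(np.sum((x - np.mean(x)) ** 2)),
        residual_se=float(np.sqrt(s2)),
    )


def fold_coverage_to_halve_error(slope: float) -> float:
    """Coverage fold-change that halves the error under a log2-log2 fit of
    slope < 0: 2 ** (-1/slope). A slope of -1/3 gives 8-fold."""
    if slope >= 0:
        raise ValueError("error does not decrease with coverage (slope >= 0)")
    return 2 ** (-1 / slope)


def outlier_vs_model(ev: LibraryEvaluation, fit: ErrorRegressionFit) -> bool:
    """True when the library's log2(metric) exceeds the upper bound of the 95%
    prediction interval at its log2(coverage)."""
    y = np.log2(_metric_value(ev, fit.metric))
    _, upper = fit.prediction_interval(np.log2(ev.coverage_bp))
    return bool(y > upper)


def evaluation_table(evals: Sequence[LibraryEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "library": [e.library_name for e in evals],
            "coverage_bp": [e.coverage_bp for e in evals],
            "pearson_r": [e.pearson_r for e in evals],
            "median_abs_diff": [e.median_abs_diff for e in evals],
            "theta": [e.theta for e in evals],
            "n_samples": [len(e.pairs) for e in evals],
        }
    )
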