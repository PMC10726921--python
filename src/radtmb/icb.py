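"""Monte-Carlo simulation of TMB-stratified immune-checkpoint-blockade trials.

Response probability rises with true TMB (linear ramp from 0 at 0 mutations/Mb
to a plateau of 0.5 at 11 mutations/Mb by default). Each simulated trial draws
Bernoulli responses, dichotomises the cohort at each TMB cutoff using the
*measured* TMB (WGS truth or a library estimate), tests the response-by-cutoff
association with Fisher's exact test, and Bonferroni-corrects across cutoffs
within the trial. The power summary is the proportion of trials significant at
each cutoff.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio

from .signatures import adjust_pvalues

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResponseModel:
    """Probability of response to ICB as a function of TMB (mutations/Mb)."""

    p_min: float = 0.0
    p_max: float = 0.5
    plateau_tmb: float = 11.0
    shape: str = "linear"  # or "logistic"

    def __post_init__(self) -> None:
        # p_min == p_max is allowed: a flat model with no TMB effect (null)
        if not 0 <= self.p_min <= self.p_max <= 1:
            raise ValueError("need 0 <= p_min <= p_max <= 1")
        if self.plateau_tmb <= 0:
            raise ValueError("plateau_tmb must be positive")
        if self.shape not in {"linear", "logistic"}:
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class TrialConfig:
    n_trials: int = 100
    cutoffs: tuple[float, ...] = tuple(range(2, 11))
    alpha: float = 0.05
    correction: str = "bonferroni"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cutoffs or list(self.cutoffs) != sorted(self.cutoffs):
            raise ValueError("cutoffs must be nonempty and ascending")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Responder/non-responder x TMB >= cutoff / < cutoff."""

    a: int  # responder, high TMB
    b: int  # responder, low TMB
    c: int  # non-responder, high TMB
    d: int  # non-responder, low TMB

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class TrialSummary:
    per_trial: pd.DataFrame  # trial, cutoff, odds_ratio, p, p_adj
    per_cutoff: pd.DataFrame  # cutoff, proportion_significant
    config: TrialConfig


def response_probability(
    tmb: float | np.ndarray, model: ResponseModel = ResponseModel()
) -> np.ndarray | float:
    """Response probability at a TMB value (vectorised)."""
    tmb = np.asarray(tmb, dtype=float)
    if (tmb < 0).any():
        raise ValueError("TMB must be non-negative")
    if model.p_max == model.p_min:
        p = np.full(tmb.shape, model.p_min)
    elif model.shape == "linear":
        p = model.p_min + (model.p_max - model.p_min) * np.minimum(
            tmb, model.plateau_tmb
        ) / model.plateau_tmb
    else:  # logistic alternative through the same anchors
        # midpoint at plateau/2, scale chosen so p(plateau) ~ 0.95 * p_max
        k = 6.0 / model.plateau_tmb
        raw = 1 / (1 + np.exp(-k * (tmb - model.plateau_tmb / 2)))
        p = model.p_min + (model.p_max - model.p_min) * raw
    return p if p.shape else float(p)


def draw_responses(
    probs: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Independent Bernoulli response outcomes."""
    probs = np.asarray(probs, dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return (rng.random(probs.shape) < probs).astype(np.int8)


def contingency_at_cutoff(
    tmb_measured: Sequence[float], responses: Sequence[int], cutoff: float
) -> ContingencyTable2x2:
    """2x2 table of response by measured TMB >= cutoff."""
    tmb = np.asarray(tmb_measured, dtype=float)
    resp = np.asarray(responses)
    if tmb.shape != resp.shape:
        raise ValueError("tmb_measured and responses differ in length")
    high = tmb >= cutoff
    return ContingencyTable2x2(
        a=int((resp.astype(bool) & high).sum()),
        b=int((resp.astype(bool) & ~high).sum()),
        c=int((~resp.astype(bool) & high).sum()),
        d=int((~resp.astype(bool) & ~high).sum()),
    )


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact p and the conditional-MLE odds ratio (the R
    fisher.test convention). Degenerate tables give p = 1 and an odds ratio of
    0 or inf as appropriate."""
    arr = table.as_array()
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    or_hat = float(odds_ratio(arr, kind="conditional").statistic)
    return p, or_hat


def haldane_odds_ratio(table: ContingencyTable2x2) -> float:
    """Sample odds ratio with the Haldane-Anscombe 0.5 correction."""
    a, b, c, d = (x + 0.5 for x in (table.a, table.b, table.c, table.d))
    return (a * d) / (b * c)


def simulate_trials(
    tmb_true: Sequence[float],
    tmb_measured: Sequence[float] | None = None,
    apobec_flags: Sequence[bool] | None = None,
    model: ResponseModel = ResponseModel(),
    config: TrialConfig = TrialConfig(),
) -> TrialSummary:
    """Run the full trial simulation.

    ``tmb_true`` drives the response model; ``tmb_measured`` (defaults to the
    truth) drives the cutoff classification, so measurement error degrades the
    detectable association. ``apobec_flags`` optionally restricts the cohort to
    flagged samples before simulation (pre-screening). Per-trial RNG substreams
    are derived from ``config.seed`` by trial index.
    """
    tmb_true = np.asarray(tmb_true, dtype=float)
    tmb_measured = (
        tmb_true if tmb_measured is None else np.asarray(tmb_measured, dtype=float)
    )
    if tmb_true.shape != tmb_measured.shape:
        raise ValueError("tmb_true and tmb_measured differ in length")
    if apobec_flags is not None:
        mask = np.asarray(apobec_flags, dtype=bool)
        tmb_true, tmb_measured = tmb_true[mask], tmb_measured[mask]
    probs = np.asarray(response_probability(tmb_true, model))
    n_degenerate = 0
    rows = []
    for trial in range(1, config.n_trials + 1):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(trial,))
        )
        resp = draw_responses(probs, rng)
        ps, ors = [], []
        for cutoff in config.cutoffs:
            tab = contingency_at_cutoff(tmb_measured, resp, cutoff)
            if min(tab.a + tab.c, tab.b + tab.d) == 0 or min(
                tab.a + tab.b, tab.c + tab.d
            ) == 0:
                n_degenerate += 1
            p, or_hat = fisher_exact(tab)
            ps.append(p)
            ors.append(or_hat)
        p_adj = adjust_pvalues(ps, method=config.correction)
        for cutoff, or_hat, p, pa in zip(config.cutoffs, ors, ps, p_adj):
            rows.append((trial, cutoff, or_hat, p, pa))
    if n_degenerate:
        logger.info("%d degenerate tables (empty margin) yielded p = 1", n_degenerate)
    per_trial = pd.DataFrame(
        rows, columns=["trial", "cutoff", "odds_ratio", "p", "p_adj"]
    )
    per_cutoff = (
        per_trial.assign(sig=per_trial["p_adj"] < config.alpha)
        .groupby("cutoff", as_index=False)["sig"]
        .mean()
        .rename(columns={"sig": "proportion_significant"})
    )
    return TrialSummary(per_trial, per_cutoff, config)
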