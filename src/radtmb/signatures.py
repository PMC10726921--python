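"""SBS96 mutation-signature profiles and the statistics built on them.

Covers profile construction, cosine similarity, the random-subsampling
recapitulation experiment with its exact binomial threshold test, APOBEC
hypermutation classification and TCW enrichment testing, plus the small-sample
statistics used downstream (Wilcoxon rank-sum, Bonferroni/Holm adjustment).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import (
    CHANNEL_INDEX,
    SBS96_CHANNELS,
    TCW_CHANNELS,
    ContextError,
    GenomeSequence,
    MutationCatalog,
    sbs96_channel,
)

logger = logging.getLogger(__name__)

TCW_INDICES = np.array([CHANNEL_INDEX[c] for c in TCW_CHANNELS])


@dataclass
class SBS96Profile:
    """Counts over the 96 canonical trinucleotide substitution channels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError(f"expected 96 channels, got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative channel count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("zero-total profile has no frequency vector")
        return self.counts / self.total

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(SBS96_CHANNELS))


@dataclass
class EnrichmentResult:
    """Outcome of the one-sided TCW binomial enrichment test."""

    k: int
    n: int
    pi0: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class RecapThreshold:
    """Per-n recapitulation test results and the threshold n*."""

    table: pd.DataFrame  # columns: n_sub, successes, n_tested, p_raw, p_adj, ci_lower
    n_star: int | None
    cs_cut: float
    p0: float
    alpha: float
    correction: str


def channel_indices(
    catalog: MutationCatalog, genome: GenomeSequence, strict: bool = True
) -> tuple[np.ndarray, int]:
    """Channel index of every record; context-failing records are dropped and
    counted. Ref mismatches propagate in strict mode."""
    idx: list[int] = []
    n_failed = 0
    for rec in catalog:
        try:
            idx.append(CHANNEL_INDEX[sbs96_channel(genome, rec, strict=strict)])
        except ContextError:
            n_failed += 1
    if n_failed:
        logger.info(
            "%s: %d records excluded for unavailable context",
            catalog.sample_id,
            n_failed,
        )
    return np.asarray(idx, dtype=np.int64), n_failed


def build_profile(
    catalog: MutationCatalog, genome: GenomeSequence, strict: bool = True
) -> SBS96Profile:
    """SBS96 profile of a catalogue (order-invariant)."""
    idx, _ = channel_indices(catalog, genome, strict=strict)
    return SBS96Profile(np.bincount(idx, minlength=96))


def cosine_similarity(a: SBS96Profile | np.ndarray, b: SBS96Profile | np.ndarray) -> float:
    """Cosine similarity of two profiles (scale-invariant)."""
    va = a.counts if isinstance(a, SBS96Profile) else np.asarray(a, dtype=float)
    vb = b.counts if isinstance(b, SBS96Profile) else np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero profile")
    return float(np.dot(va, vb) / (na * nb))


def subsample_catalog(
    catalog: MutationCatalog, n: int, rng: np.random.Generator
) -> MutationCatalog:
    """Uniform subsample of n records without replacement."""
    if n > catalog.n_records:
        raise ValueError(
            f"cannot subsample {n} from {catalog.n_records} records "
            f"({catalog.sample_id})"
        )
    take = rng.choice(catalog.n_records, size=n, replace=False)
    return MutationCatalog(catalog.sample_id, [catalog.records[i] for i in take])


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: one generator per (seed, key) tuple."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def run_subsampling_experiment(
    cohort: Mapping[str, MutationCatalog],
    genome: GenomeSequence,
    n_grid: Sequence[int],
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Random-subsampling recapitulation experiment.

    For every sample, every subset size n in ``n_grid`` with n <= the sample's
    catalogue size, and every replicate, subsample n mutations, rebuild the
    SBS96 profile, and record its cosine similarity to the sample's
    full-catalogue profile. Returns a tidy table (sample, n_sub, replicate,
    cosine). Reproducible: replicate r of sample s at size n uses a dedicated
    RNG substream of ``seed``.
    """
    n_grid = list(n_grid)
    if n_grid != sorted(n_grid):
        raise ValueError("n_grid must be sorted ascending")
    rows: list[tuple[str, int, int, float]] = []
    for s_i, (sample, catalog) in enumerate(sorted(cohort.items())):
        idx, _ = channel_indices(catalog, genome)
        full = np.bincount(idx, minlength=96).astype(float)
        if np.linalg.norm(full) == 0:
            logger.info("%s: empty profile, skipped", sample)
            continue
        full /= np.linalg.norm(full)
        eligible = [n for n in n_grid if n <= len(idx)]
        if len(eligible) < len(n_grid):
            logger.info(
                "%s: only %d records; sizes above that skipped", sample, len(idx)
            )
        for n_i, n in enumerate(n_grid):
            if n > len(idx):
                continue
            for rep in range(1, reps + 1):
                rng = _substream(seed, s_i, n_i, rep)
                take = rng.choice(len(idx), size=n, replace=False)
                sub = np.bincount(idx[take], minlength=96).astype(float)
                cs = float(np.dot(sub, full) / np.linalg.norm(sub))
                rows.append((sample, n, rep, cs))
    return pd.DataFrame(rows, columns=["sample", "n_sub", "replicate", "cosine"])


def pr_cs_exceeds(table: pd.DataFrame, threshold: float = 0.9) -> pd.DataFrame:
    """Pr(CS > threshold) per (sample, n_sub): the fraction of replicates whose
    cosine similarity strictly exceeds the threshold."""
    if table.empty:
        raise ValueError("empty subsample table")
    out = (
        table.assign(passed=table["cosine"] > threshold)
        .groupby(["sample", "n_sub"], as_index=False)["passed"]
        .mean()
        .rename(columns={"passed": "proportion"})
    )
    return out


def recapitulation_threshold(
    table: pd.DataFrame,
    cs_cut: float = 0.9,
    p0: float = 0.95,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> RecapThreshold:
    """Smallest subset size at which the cohort recapitulates WGS profiles.

    A sample succeeds at size n when the majority of its replicates have
    cosine similarity > ``cs_cut``. Per n, a one-sided exact binomial test of
    success proportion > ``p0`` is run; p-values are corrected across the
    n-grid; n* is the smallest n with corrected p < ``alpha``. ``ci_lower`` is
    the one-sided 95% exact (Clopper-Pearson) lower bound on the proportion.
    """
    if table.empty:
        raise ValueError("empty subsample table")
    reps = table.groupby(["sample", "n_sub"])["replicate"].count()
    if reps.nunique() != 1:
        raise ValueError("unequal replicate counts across (sample, n_sub) cells")
    r = int(reps.iloc[0])
    majority = math.ceil(r / 2)
    passed = (
        table.assign(ok=table["cosine"] > cs_cut)
        .groupby(["sample", "n_sub"])["ok"]
        .sum()
        .ge(majority)
    )
    per_n = passed.groupby("n_sub").agg(successes="sum", n_tested="count")
    p_raw = [
        stats.binomtest(int(k), int(m), p=p0, alternative="greater").pvalue
        for k, m in zip(per_n["successes"], per_n["n_tested"])
    ]
    p_adj = adjust_pvalues(p_raw, method=correction)
    ci_lower = [
        float(stats.beta.ppf(0.05, k, m - k + 1)) if k > 0 else 0.0
        for k, m in zip(per_n["successes"], per_n["n_tested"])
    ]
    out = per_n.reset_index()
    out["p_raw"] = p_raw
    out["p_adj"] = p_adj
    out["ci_lower"] = ci_lower
    sig = out.loc[out["p_adj"] < alpha, "n_sub"]
    n_star = int(sig.min()) if not sig.empty else None
    if n_star is None:
        logger.info("no subset size reached corrected p < %g", alpha)
    return RecapThreshold(out, n_star, cs_cut, p0, alpha, correction)


def classify_apobec(
    profile: SBS96Profile, frac_threshold: float = 0.4
) -> tuple[bool, float]:
    """APOBEC hypermutation call: >40% of mutations in the four T(C>T/G)W
    channels (strict inequality). Returns (is_hyper, tcw_fraction)."""
    if profile.total == 0:
        raise ValueError("cannot classify a zero-total profile")
    frac = float(profile.counts[TCW_INDICES].sum() / profile.total)
    return frac > frac_threshold, frac


def tcw_enrichment_pvalue(k: int, n: int, pi0: float) -> float:
    """One-sided upper-tail exact binomial P(X >= k | n, pi0)."""
    if not 0 < pi0 < 1:
        raise ValueError(f"pi0 must be in (0,1), got {pi0}")
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    return float(stats.binom.sf(k - 1, n, pi0))


def ytca_rtca_fractions(
    catalog: MutationCatalog, genome: GenomeSequence
) -> tuple[float, float]:
    """Among T[C>*]W mutations, the fraction with a pyrimidine (Y: C/T) versus
    purine (R: A/G) base two positions 5' of the mutated C, in pyrimidine-strand
    orientation. Distinguishes APOBEC3A-like (YTCA) from APOBEC3B-like (RTCA)
    editing."""
    tcw_any = {c for c in SBS96_CHANNELS if c[0] == "T" and c[2] == "C" and c[-1] in "AT"}
    n_y = n_r = 0
    for rec in catalog:
        try:
            ch = sbs96_channel(genome, rec)
        except (ContextError, KeyError):
            continue
        if ch not in tcw_any:
            continue
        seq = genome.contigs[rec.chrom]
        if rec.ref == "C":  # pyrimidine strand is the forward strand
            if rec.pos < 3:
                continue
            minus2 = seq[rec.pos - 3]
        else:  # mutated C on the reverse strand: -2 base is downstream, complemented
            if rec.pos + 1 > len(seq):
                continue
            minus2 = seq[rec.pos + 1].translate(str.maketrans("ACGT", "TGCA"))
        if minus2 in "CT":
            n_y += 1
        elif minus2 in "AG":
            n_r += 1
    if n_y + n_r == 0:
        raise ValueError("no TCW-context mutations with a resolvable -2 base")
    tot = n_y + n_r
    return n_y / tot, n_r / tot


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon rank-sum test. W is the Mann-Whitney statistic of x (its
    rank-sum minus n1(n1+1)/2, ties mid-ranked), as reported by R's
    wilcox.test. Exact p for small tie-free samples, otherwise the normal
    approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def adjust_pvalues(p: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Bonferroni or Holm multiplicity adjustment, order-preserving."""
    p = np.asarray(p, dtype=float)
    if method not in {"bonferroni", "holm"}:
        raise ValueError(f"unknown correction {method!r}")
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]
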