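"""Downstream statistics for RADseq-profiled monoclonal cell lines.

Starts from per-clone variant calls (VCF-derived sites with depth and allele
fraction): depth/AF filtering, mutation rate over well-covered bases, pairwise
cosine-similarity matrices of SBS96 profiles, and the APOBEC-gain binomial
test of each derived clone against the parental clone's T(C>T)W proportion.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import (
    CHANNEL_INDEX,
    TCW_CHANNELS,
    TCW_CT_CHANNELS,
    GenomeSequence,
    MutationCatalog,
    MutationRecord,
    VariantSite,
)
from .signatures import (
    EnrichmentResult,
    SBS96Profile,
    build_profile,
    channel_indices,
    cosine_similarity,
    tcw_enrichment_pvalue,
)

__all__ = [
    "VariantSite",
    "CloneStats",
    "filter_variant_sites",
    "clone_mutation_rate",
    "sites_to_catalog",
    "clone_stats",
    "pairwise_cosine_matrix",
    "apobec_gain_test",
]

logger = logging.getLogger(__name__)


@dataclass
class CloneStats:
    sample_id: str
    n_mutations: int
    covered_bp: int
    rate: float  # mutations/Mb over bases at >= min_depth
    profile: SBS96Profile


def filter_variant_sites(
    sites: Sequence[VariantSite], min_depth: int = 20, max_af: float = 0.75
) -> list[VariantSite]:
    """Keep sites with depth >= min_depth and AF <= max_af. Shallow sites and
    high-AF sites (germline / artefact candidates) are both removed."""
    return [s for s in sites if s.depth >= min_depth and s.af <= max_af]


def clone_mutation_rate(n_mutations: int, covered_bp: int) -> float:
    """Mutations per Mb of adequately covered sequence."""
    if covered_bp <= 0:
        raise ValueError(f"covered_bp must be positive, got {covered_bp}")
    return n_mutations / covered_bp * 1e6


def sites_to_catalog(
    sites: Sequence[VariantSite], sample_id: str
) -> MutationCatalog:
    return MutationCatalog(
        sample_id,
        [MutationRecord(sample_id, s.chrom, s.pos, s.ref, s.alt) for s in sites],
    )


def clone_stats(
    catalog: MutationCatalog,
    covered_bp: int,
    genome: GenomeSequence,
) -> CloneStats:
    return CloneStats(
        catalog.sample_id,
        catalog.n_records,
        covered_bp,
        clone_mutation_rate(catalog.n_records, covered_bp),
        build_profile(catalog, genome),
    )


def pairwise_cosine_matrix(
    profiles: Sequence[SBS96Profile], names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Symmetric cosine-similarity matrix over clone profiles (diagonal 1)."""
    names = list(names) if names is not None else [str(i) for i in range(len(profiles))]
    for name, p in zip(names, profiles):
        if p.total == 0:
            raise ValueError(f"zero-total profile for sample {name!r}")
    n = len(profiles)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = cosine_similarity(profiles[i], profiles[j])
    return pd.DataFrame(mat, index=names, columns=names)


def apobec_gain_test(
    clone: MutationCatalog,
    parental: MutationCatalog,
    genome: GenomeSequence,
    scope: str = "c_to_t",
) -> EnrichmentResult:
    """Test whether a derived clone gained T(C>T)W mutations relative to the
    parental clone.

    k = the clone's T[C>T]W count, n = the clone's total mutations (with a
    resolvable context), pi0 = the parental clone's T[C>T]W fraction; p is the
    one-sided upper-tail binomial P(X >= k | n, pi0). ``scope='c_to_any'``
    widens the numerator to the four T(C>T/G)W channels. A parental fraction of
    exactly 0 or 1 falls back to 0.5 pseudo-counts."""
    if scope == "c_to_t":
        channels = TCW_CT_CHANNELS
    elif scope == "c_to_any":
        channels = TCW_CHANNELS
    else:
        raise ValueError(f"unknown scope {scope!r}")
    target = np.array([CHANNEL_INDEX[c] for c in channels])

    par_idx, _ = channel_indices(parental, genome)
    if par_idx.size == 0:
        raise ValueError("parental catalogue has no context-resolvable mutations")
    par_k = int(np.isin(par_idx, target).sum())
    par_n = par_idx.size
    if par_k in (0, par_n):
        logger.info(
            "parental TCW fraction degenerate (%d/%d); using 0.5 pseudo-counts",
            par_k,
            par_n,
        )
        pi0 = (par_k + 0.5) / (par_n + 1)
    else:
        pi0 = par_k / par_n

    clone_idx, _ = channel_indices(clone, genome)
    if clone_idx.size == 0:
        raise ValueError("clone catalogue has no context-resolvable mutations")
    k = int(np.isin(clone_idx, target).sum())
    n = clone_idx.size
    return EnrichmentResult(k, n, pi0, tcw_enrichment_pvalue(k, n, pi0))
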