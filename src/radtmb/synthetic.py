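"""Synthetic genomes, signatures, catalogues and cohorts.

Emulates the statistical structure the analyses assume: per-sample SNV
catalogues whose trinucleotide-context distribution follows a chosen 96-channel
signature; a cohort with a minority APOBEC-hypermutated subpopulation carrying
higher mutation counts (defaults calibrated to group medians of 10,110 vs
3,270 mutations and a 49/560 hypermutated fraction); and small genomes with
controllable GC content, hence restriction-site density.

Mutations are placed uniformly over context-matching positions (no clustering
or kataegis) unless the clustered mode is requested; under uniform placement
the binomial-sampling error law (log2 error vs log2 coverage slope of -1/2)
holds exactly, which real, clustered genomes soften.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import (
    CHANNEL_INDEX,
    SBS96_CHANNELS,
    GenomeSequence,
    MutationCatalog,
    MutationRecord,
)

_COMPL = str.maketrans("ACGT", "TGCA")

# default split of the APOBEC mass over the four TCW channels: C>T-dominant
_APOBEC_WEIGHTS = {
    "T[C>T]A": 0.4,
    "T[C>T]T": 0.4,
    "T[C>G]A": 0.1,
    "T[C>G]T": 0.1,
}


@dataclass(frozen=True)
class SignatureSpec:
    """A 96-channel signature as a probability vector."""

    probs: np.ndarray
    kind: str = "custom"
    f_tcw: float | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (96,) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ValueError("probs must be 96 non-negative values summing to 1")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure: a minority of APOBEC hypermutators with higher counts.

    Counts are log-normal per group; the medians default to the breast-cancer
    cohort values this pipeline was designed around (10,110 hypermutated vs
    3,270 typical, 49/560 hypermutated). sigma is the log-normal shape shared
    by both groups, chosen for a right-skewed spread of roughly an order of
    magnitude across a cohort.
    """

    n_samples: int = 560
    apobec_fraction: float = 49 / 560
    median_hyper: float = 10110.0
    median_typical: float = 3270.0
    sigma: float = 0.8
    f_tcw_hyper: float = 0.6
    f_tcw_typical: float = 0.0  # 0 -> flat signature for typical samples
    min_count: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.apobec_fraction <= 1:
            raise ValueError("apobec_fraction must lie in [0, 1]")
        if self.median_hyper <= 0 or self.median_typical <= 0:
            raise ValueError("group medians must be positive")


def make_genome(
    length: int, gc: float = 0.41, seed: int = 0, name: str = "chr1"
) -> GenomeSequence:
    """I.i.d. random genome with the given GC content (human-like default)."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not 0 < gc < 1:
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)
    return GenomeSequence({name: seq.tobytes().decode()})


def make_signature(kind: str = "flat", f_tcw: float | None = None) -> SignatureSpec:
    """Build a signature: 'flat' (1/96 per channel), 'apobec' (mass ``f_tcw``
    on the four TCW channels, C>T-dominant, remainder flat), or pass a mixture
    via :func:`mix_signatures`."""
    if kind == "flat":
        return SignatureSpec(np.full(96, 1 / 96), "flat")
    if kind == "apobec":
        if f_tcw is None or not 0 < f_tcw < 1:
            raise ValueError("apobec signature needs f_tcw in (0, 1)")
        probs = np.full(96, (1 - f_tcw) / 92)
        for ch, w in _APOBEC_WEIGHTS.items():
            probs[CHANNEL_INDEX[ch]] = f_tcw * w
        return SignatureSpec(probs, "apobec", f_tcw)
    raise ValueError(f"unknown signature kind {kind!r}")


def mix_signatures(a: SignatureSpec, b: SignatureSpec, weight_a: float) -> SignatureSpec:
    """Convex combination of two signatures."""
    if not 0 <= weight_a <= 1:
        raise ValueError("weight must lie in [0, 1]")
    return SignatureSpec(weight_a * a.probs + (1 - weight_a) * b.probs, "mixture")


class ContextIndex:
    """One-pass index of a genome's pyrimidine-normalised trinucleotide
    contexts: for each of the 32 contexts (centre C or T x 16 flank pairs), the
    1-based positions carrying it and the strand it was found on."""

    def __init__(self, genome: GenomeSequence):
        self.genome = genome
        self.contig_names = list(genome.contigs)
        # per context: (contig_index, 1-based position, on-forward-strand)
        self.positions: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        acc: dict[int, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
        bases = "ACGT"
        for c_i, contig in enumerate(self.contig_names):
            seq = genome.contigs[contig]
            arr = np.frombuffer(seq.encode(), dtype="S1")
            codes = np.full(arr.size, -1, dtype=np.int8)
            for b_i, b in enumerate(bases):
                codes[arr == b.encode()] = b_i
            if codes.size < 3:
                continue
            c5, cc, c3 = codes[:-2], codes[1:-1], codes[2:]
            valid = (c5 >= 0) & (cc >= 0) & (c3 >= 0)
            fwd = (cc == 1) | (cc == 3)  # centre C or T
            # pyrimidine-normalised context key as 0..31 x centre-type
            key = np.where(
                fwd,
                c5 * 16 + cc * 4 + c3,
                (3 - c3) * 16 + (3 - cc) * 4 + (3 - c5),
            )
            pos = np.arange(2, codes.size, dtype=np.int64)  # 1-based centres
            for k in np.unique(key[valid]):
                sel = valid & (key == k)
                acc.setdefault(int(k), []).append(
                    (np.full(sel.sum(), c_i), pos[sel], fwd[sel])
                )
        for k, chunks in acc.items():
            ctx = bases[k // 16] + bases[(k % 16) // 4] + bases[k % 4]
            self.positions[ctx] = tuple(
                np.concatenate([c[i] for c in chunks]) for i in range(3)
            )

    def sites_for(self, context: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        empty = np.array([], dtype=np.int64)
        return self.positions.get(context, (empty, empty, empty.astype(bool)))

    def n_sites(self, context: str) -> int:
        return self.sites_for(context)[1].size


def _parse_channel(channel: str) -> tuple[str, str, str]:
    """channel 'X[R>A]Y' -> (context XRY, ref R, alt A)."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, ref, alt


def simulate_catalog(
    genome: GenomeSequence,
    signature: SignatureSpec,
    n_mut: int,
    sample_id: str = "S1",
    seed: int = 0,
    context_index: ContextIndex | None = None,
) -> MutationCatalog:
    """Draw a catalogue of ``n_mut`` SNVs whose channels follow ``signature``.

    Each mutation draws a channel, then a uniform genome position whose
    pyrimidine-normalised trinucleotide matches the channel's context; the
    emitted ref/alt are strand-resolved so re-extracting every record's channel
    returns the drawn one. Positions are unique within a sample.
    """
    rng = np.random.default_rng(seed)
    index = context_index if context_index is not None else ContextIndex(genome)
    channel_counts = rng.multinomial(n_mut, signature.probs)
    # group channels by context so shared positions stay unique within sample
    by_context: dict[str, list[tuple[int, str, str]]] = {}
    for ci, cnt in enumerate(channel_counts):
        if cnt == 0:
            continue
        context, ref, alt = _parse_channel(SBS96_CHANNELS[ci])
        by_context.setdefault(context, []).append((cnt, ref, alt))
    records: list[MutationRecord] = []
    for context, wants in sorted(by_context.items()):
        contig_ids, positions, fwd_flags = index.sites_for(context)
        needed = sum(c for c, _, _ in wants)
        if needed > positions.size:
            raise ValueError(
                f"context {context} has only {positions.size} sites in the "
                f"genome but {needed} mutations were drawn; use a larger genome"
            )
        picks = iter(rng.choice(positions.size, size=needed, replace=False))
        for cnt, ref, alt in wants:
            for _ in range(cnt):
                j = next(picks)
                contig = index.contig_names[contig_ids[j]]
                pos = int(positions[j])
                if fwd_flags[j]:
                    records.append(MutationRecord(sample_id, contig, pos, ref, alt))
                else:
                    records.append(
                        MutationRecord(
                            sample_id,
                            contig,
                            pos,
                            ref.translate(_COMPL),
                            alt.translate(_COMPL),
                        )
                    )
    rng.shuffle(records)  # no context ordering artefacts
    return MutationCatalog(sample_id, records)


def simulate_uniform_catalog(
    genome: GenomeSequence,
    n_mut: int,
    sample_id: str = "S1",
    seed: int = 0,
    cluster_size: int = 1,
    cluster_span: int = 1000,
) -> MutationCatalog:
    """Catalogue with positions uniform over non-N bases (any context), random
    alt. ``cluster_size`` > 1 places mutations in bursts of that size within
    ``cluster_span`` bp, emulating kataegis-like clustering."""
    rng = np.random.default_rng(seed)
    contigs = list(genome.contigs)
    lengths = np.array([len(genome.contigs[c]) for c in contigs])
    weights = lengths / lengths.sum()
    if cluster_size == 1 and len(contigs) == 1:
        # fast path: vectorised draw of distinct interior non-N positions
        contig, seq = contigs[0], genome.contigs[contigs[0]]
        arr = np.frombuffer(seq.encode(), dtype="S1")
        draw = rng.integers(2, len(seq), size=4 * n_mut + 16)
        pool = rng.permutation(np.unique(draw))
        pool = pool[arr[pool - 1] != b"N"][:n_mut]
        if pool.size < n_mut:
            raise ValueError("genome too small for the requested mutation count")
        refs = arr[pool - 1].astype("U1")
        alt_of = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
        alt_pick = rng.integers(0, 3, size=n_mut)
        records = [
            MutationRecord(sample_id, contig, int(p), r, alt_of[r][a])
            for p, r, a in zip(pool, refs, alt_pick)
        ]
        return MutationCatalog(sample_id, records)
    used: set[tuple[str, int]] = set()
    records: list[MutationRecord] = []
    while len(records) < n_mut:
        ci = rng.choice(len(contigs), p=weights)
        contig, seq = contigs[ci], genome.contigs[contigs[ci]]
        anchor = int(rng.integers(2, len(seq)))  # 1-based, needs a 5' neighbour
        burst = min(cluster_size, n_mut - len(records))
        offsets = (
            np.zeros(1, dtype=int)
            if burst == 1
            else rng.integers(0, cluster_span, size=burst)
        )
        for off in offsets:
            pos = anchor + int(off)
            if pos < 2 or pos > len(seq) - 1 or (contig, pos) in used:
                continue
            ref = seq[pos - 1]
            if ref == "N":
                continue
            alt = rng.choice([b for b in "ACGT" if b != ref])
            used.add((contig, pos))
            records.append(MutationRecord(sample_id, contig, pos, ref, str(alt)))
    return MutationCatalog(sample_id, records)


def simulate_cohort(
    spec: CohortSpec, genome: GenomeSequence
) -> tuple[dict[str, MutationCatalog], pd.DataFrame]:
    """Simulate a cohort per ``spec``: each sample is hypermutated with
    probability ``apobec_fraction``; counts are log-normal around the group
    median; hypermutated samples draw from an APOBEC signature with
    ``f_tcw_hyper`` TCW mass, typical samples from a flat (or low-TCW mixture)
    signature. Returns the cohort and a per-sample truth table."""
    rng = np.random.default_rng(spec.seed)
    index = ContextIndex(genome)
    sig_hyper = make_signature("apobec", spec.f_tcw_hyper)
    sig_typical = (
        make_signature("flat")
        if spec.f_tcw_typical <= 0
        else make_signature("apobec", spec.f_tcw_typical)
    )
    cohort: dict[str, MutationCatalog] = {}
    truth_rows = []
    width = len(str(spec.n_samples))
    for i in range(spec.n_samples):
        sample = f"S{i + 1:0{width}d}"
        hyper = bool(rng.random() < spec.apobec_fraction)
        median = spec.median_hyper if hyper else spec.median_typical
        count = max(
            spec.min_count, int(round(rng.lognormal(np.log(median), spec.sigma)))
        )
        sub_seed = int(
            np.random.SeedSequence(spec.seed, spawn_key=(i,)).generate_state(1)[0]
            % (2**31)
        )
        cohort[sample] = simulate_catalog(
            genome,
            sig_hyper if hyper else sig_typical,
            count,
            sample,
            seed=sub_seed,
            context_index=index,
        )
        truth_rows.append((sample, hyper, count))
    truth = pd.DataFrame(truth_rows, columns=["sample", "hyper", "n_mutations"])
    return cohort, truth
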