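"""In-silico restriction digestion and fragment libraries.

A digest library is the set of genomic intervals lying between adjacent
restriction-site breakpoints, optionally size-selected to the range a RADseq
protocol would sequence. A panel library is a merged set of BED-defined target
regions. Both expose merged non-N coverage and support mutation capture.
"""

from __future__ import annotations

import json
import re
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    GenomeSequence,
    GenomicInterval,
    MutationCatalog,
    ParseError,
    reverse_complement,
)

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",  # N in the motif matches any real base (never genome N)
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class EnzymeDef:
    """A restriction enzyme: name, IUPAC recognition motif, and flags."""

    name: str
    motif: str
    methylation_sensitive: bool = False
    hf_variant: bool = False

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError(f"enzyme {self.name}: empty motif")
        bad = set(self.motif.upper()) - set(IUPAC_EXPAND)
        if bad:
            raise ParseError(
                f"enzyme {self.name}: invalid IUPAC letters {sorted(bad)} "
                f"in motif {self.motif!r}"
            )


@dataclass
class FragmentLibrary:
    """A named, sorted, non-overlapping set of captured genomic intervals."""

    name: str
    fragments: list[GenomicInterval]
    coverage_bp: int = 0

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


def reverse_complement_iupac(motif: str) -> str:
    return motif.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def iupac_regex(motif: str) -> str:
    return "".join(
        b if len(IUPAC_EXPAND[b]) == 1 else "[" + IUPAC_EXPAND[b] + "]"
        for b in motif.upper()
    )


def parse_enzyme_table(path: str | Path) -> list[EnzymeDef]:
    """Read an enzyme table TSV (name, motif, methylation_sensitive[, hf_variant]).

    An enzyme is flagged as a high-fidelity variant when its name ends in
    "-HF" (case-insensitive) or the hf_variant column says so.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("name", "motif"):
        if needed not in cols:
            raise ParseError(f"enzyme table missing column {needed!r}")
    out: list[EnzymeDef] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        name = d[cols["name"]].strip()
        meth = _truthy(d.get(cols.get("methylation_sensitive", ""), "no"))
        hf = name.upper().endswith("-HF")
        if "hf_variant" in cols:
            hf = hf or _truthy(d[cols["hf_variant"]])
        out.append(EnzymeDef(name, d[cols["motif"]].strip().upper(), meth, hf))
    return out


def _truthy(val) -> bool:
    return str(val).strip().lower() in {"yes", "true", "1", "y"}


def find_recognition_sites(
    genome: GenomeSequence, motif: str
) -> dict[str, np.ndarray]:
    """All forward-strand start positions (0-based) where the motif — or, for
    non-palindromic motifs, its reverse complement — occurs. Overlapping
    matches are reported; genome N never matches."""
    EnzymeDef("query", motif)  # validates the alphabet
    patterns = [iupac_regex(motif)]
    rc = reverse_complement_iupac(motif)
    if rc != motif.upper():
        patterns.append(iupac_regex(rc))
    sites: dict[str, np.ndarray] = {}
    for contig, seq in genome.contigs.items():
        hits: set[int] = set()
        for pat in patterns:
            hits.update(m.start() for m in re.finditer(f"(?={pat})", seq))
        sites[contig] = np.array(sorted(hits), dtype=np.int64)
    return sites


def fragments_from_sites(
    sites: Sequence[int], contig: str, contig_length: int
) -> list[GenomicInterval]:
    """Intervals between adjacent breakpoints. Terminal regions (before the
    first and after the last breakpoint) are excluded: a sequenced RAD fragment
    needs a cut site at both ends."""
    sites = np.asarray(sites, dtype=np.int64)
    if sites.size and (sites[0] < 0 or sites[-1] >= contig_length):
        raise ValueError(f"breakpoints outside contig {contig}")
    return [
        GenomicInterval(contig, int(a), int(b))
        for a, b in zip(sites[:-1], sites[1:])
        if a < b
    ]


def digest_genome(
    genome: GenomeSequence, motifs: str | Sequence[str]
) -> list[GenomicInterval]:
    """Fragments of a single- or double-digest: breakpoints from all motifs are
    pooled per contig before fragment construction."""
    if isinstance(motifs, str):
        motifs = [motifs]
    fragments: list[GenomicInterval] = []
    per_motif = [find_recognition_sites(genome, m) for m in motifs]
    for contig, seq in genome.contigs.items():
        pooled = np.unique(np.concatenate([s[contig] for s in per_motif]))
        fragments.extend(fragments_from_sites(pooled, contig, len(seq)))
    return fragments


def size_select(
    fragments: Sequence[GenomicInterval],
    size_min: int = 70,
    size_max: int = 378,
    name: str = "library",
    genome: GenomeSequence | None = None,
) -> FragmentLibrary:
    """Keep fragments with size_min <= length <= size_max (inclusive bounds),
    the range commonly sequenced in RADseq experiments."""
    if size_min > size_max:
        raise ValueError(f"size_min {size_min} > size_max {size_max}")
    kept = sorted(f for f in fragments if size_min <= len(f) <= size_max)
    lib = FragmentLibrary(name, kept)
    if genome is not None:
        lib.coverage_bp = library_coverage(kept, genome)
    return lib


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or bookended intervals are merged."""
    merged: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        cur_s = cur_e = None
        for iv in sorted(by_chrom[chrom]):
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def library_coverage(
    fragments: Sequence[GenomicInterval], genome: GenomeSequence
) -> int:
    """Bases captured: the merged interval union, excluding N bases (assembly
    gaps are unsequencable and must not inflate coverage)."""
    total = 0
    for iv in merge_intervals(fragments):
        seq = genome.contigs[iv.chrom][iv.start : iv.end]
        total += len(seq) - seq.count("N")
    return total


def capture_mutations(
    catalog: MutationCatalog, library: FragmentLibrary
) -> MutationCatalog:
    """Records falling inside any library fragment (half-open intervals,
    1-based positions tested at pos-1)."""
    starts_l: dict[str, list[int]] = {}
    ends_l: dict[str, list[int]] = {}
    for iv in library.fragments:
        starts_l.setdefault(iv.chrom, []).append(iv.start)
        ends_l.setdefault(iv.chrom, []).append(iv.end)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, vals in starts_l.items():
        order = np.argsort(vals)
        starts[chrom] = np.asarray(vals)[order]
        ends[chrom] = np.asarray(ends_l[chrom])[order]
    rec_idx: dict[str, list[int]] = {}
    for i, rec in enumerate(catalog.records):
        rec_idx.setdefault(rec.chrom, []).append(i)
    keep = np.zeros(catalog.n_records, dtype=bool)
    for chrom, idxs in rec_idx.items():
        if chrom not in starts:
            continue
        idx_arr = np.asarray(idxs)
        pos0 = np.array([catalog.records[i].pos - 1 for i in idxs])
        j = np.searchsorted(starts[chrom], pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[chrom][np.clip(j, 0, None)])
        keep[idx_arr[ok]] = True
    return MutationCatalog(
        catalog.sample_id, [r for r, k in zip(catalog.records, keep) if k]
    )


def panel_from_bed(
    intervals: Sequence[GenomicInterval],
    name: str,
    genome: GenomeSequence | None = None,
) -> FragmentLibrary:
    """A panel 'library' from BED target regions: intervals merged, no size
    selection (panel baits are not fragment-length limited)."""
    merged = merge_intervals(intervals)
    lib = FragmentLibrary(name, merged)
    if genome is not None:
        lib.coverage_bp = library_coverage(merged, genome)
    return lib


def filter_library_set(
    libraries: Sequence[tuple[FragmentLibrary, EnzymeDef]],
    cohort: Mapping[str, MutationCatalog],
    genome: GenomeSequence,
    max_coverage_fraction: float = 0.10,
    min_captured: float = 2,
    capture_stat: str = "median",
) -> tuple[list[FragmentLibrary], pd.DataFrame]:
    """Apply the library retention rules, in order: high-fidelity duplicate
    enzymes; methylation-sensitive enzymes; libraries capturing a median of
    fewer than ``min_captured`` mutations per sample; libraries covering more
    than ``max_coverage_fraction`` of the non-N genome. Each library gets the
    first applicable drop reason, or 'kept'.
    """
    if capture_stat not in {"median", "mean"}:
        raise ValueError("capture_stat must be 'median' or 'mean'")
    genome_bp = genome.non_n_length
    # among enzymes sharing a motif, keep the lexicographically first name
    seen_motifs: dict[str, str] = {}
    for lib, enz in sorted(libraries, key=lambda t: t[1].name):
        if not enz.hf_variant:
            seen_motifs.setdefault(enz.motif, enz.name)
    rows = []
    retained: list[FragmentLibrary] = []
    for lib, enz in libraries:
        captured = np.array(
            [capture_mutations(cat, lib).n_records for cat in cohort.values()]
        )
        stat = float(np.median(captured) if capture_stat == "median" else captured.mean())
        cov_frac = lib.coverage_bp / genome_bp if genome_bp else 0.0
        if enz.hf_variant or seen_motifs.get(enz.motif) != enz.name:
            reason = "hf_duplicate"
        elif enz.methylation_sensitive:
            reason = "methylation_sensitive"
        elif stat < min_captured:
            reason = "low_capture"
        elif cov_frac > max_coverage_fraction:
            reason = "high_coverage"
        else:
            reason = "kept"
            retained.append(lib)
        rows.append(
            {
                "library": lib.name,
                "retained": reason == "kept",
                "reason": reason,
                "median_captured": stat,
                "coverage_fraction": cov_frac,
            }
        )
    return retained, pd.DataFrame(rows)


def write_library(lib: FragmentLibrary, bed_path: str | Path, enzyme: str = "") -> None:
    """Export a library as BED plus a JSON sidecar with its metadata."""
    from .genome_io import write_bed

    write_bed(lib.fragments, bed_path)
    sidecar = Path(bed_path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "name": lib.name,
                "enzyme": enzyme,
                "coverage_bp": lib.coverage_bp,
                "n_fragments": lib.n_fragments,
            },
            indent=2,
        )
    )
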