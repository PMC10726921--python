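"""Reading/writing the formats the pipeline touches and trinucleotide-context
resolution of somatic SNVs against a reference genome.

Coordinate conventions: mutation positions are 1-based (VCF convention); all
genomic intervals are 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

IUPAC_CODES = set("ACGTNRYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Canonical SBS96 channel order: the six pyrimidine-centred substitutions,
# each crossed with the 16 flanking-base pairs in lexicographic order.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)
CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(SBS96_CHANNELS)}

# The four channels diagnostic of APOBEC editing: T(C>T/G)W, W in {A, T}.
TCW_CHANNELS = ("T[C>T]A", "T[C>T]T", "T[C>G]A", "T[C>G]T")
TCW_CT_CHANNELS = ("T[C>T]A", "T[C>T]T")


class ParseError(ValueError):
    """Malformed input file."""


class ConfigError(ValueError):
    """Invalid configuration (e.g. a missing mapped column)."""


class DataIntegrityError(ValueError):
    """Input contradicts the reference genome (e.g. ref-base mismatch)."""


class ContextError(ValueError):
    """Trinucleotide context unavailable (N base or contig edge)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A reference genome held in memory as uppercase {A,C,G,T,N} strings."""

    contigs: dict[str, str]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def non_n_length(self) -> int:
        return sum(len(s) - s.count("N") for s in self.contigs.values())

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.contigs[chrom][pos - 1]

    def triplet(self, chrom: str, pos: int) -> str:
        """The trinucleotide centred on a 1-based position."""
        seq = self.contigs[chrom]
        if pos < 2 or pos > len(seq) - 1:
            raise ContextError(
                f"position {chrom}:{pos} lacks a flanking base for context"
            )
        return seq[pos - 2 : pos + 1]


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide variant."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass
class MutationCatalog:
    """All somatic SNVs of one sample."""

    sample_id: str
    records: list[MutationRecord] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MutationRecord]:
        return iter(self.records)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ParseError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ParseError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV with read depth and allele fraction (from a VCF)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    af: float


class CatalogSet(Mapping):
    """Mapping sample_id -> MutationCatalog, plus the count of skipped rows."""

    def __init__(self, catalogs: dict[str, MutationCatalog], n_skipped: int = 0):
        self._catalogs = catalogs
        self.n_skipped = n_skipped

    def __getitem__(self, key: str) -> MutationCatalog:
        return self._catalogs[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._catalogs)

    def __len__(self) -> int:
        return len(self._catalogs)


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into memory, uppercasing and normalising the alphabet.

    IUPAC ambiguity codes other than the four bases are stored as N; any
    non-IUPAC residue raises :class:`ParseError`.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_CODES
        if bad:
            raise ParseError(
                f"contig {rec.id!r} contains non-IUPAC residues: {sorted(bad)}"
            )
        if rec.id in contigs:
            raise ParseError(f"duplicate contig name {rec.id!r}")
        # keep only the unambiguous alphabet; other codes are unsequencable here
        ambiguous = set(seq) - set("ACGTN")
        for code in ambiguous:
            seq = seq.replace(code, "N")
        contigs[rec.id] = seq
    return GenomeSequence(contigs)


DEFAULT_COLUMN_MAP = {
    "sample": "Sample",
    "chrom": "Chrom",
    "pos": "Pos",
    "ref": "Ref",
    "alt": "Alt",
}


def read_mutation_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> CatalogSet:
    """Read a tab-separated somatic-mutation table into per-sample catalogues.

    Rows whose ref or alt is not a single base (indels, MNVs) are skipped and
    counted on the returned :class:`CatalogSet`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise ConfigError(
            f"mapped columns {missing} not in table (have {list(df.columns)})"
        )
    catalogs: dict[str, MutationCatalog] = {}
    n_skipped = 0
    bases = {"A", "C", "G", "T"}
    for row in df.itertuples(index=False):
        rowd = row._asdict() if hasattr(row, "_asdict") else dict(row)
        sample = rowd[cmap["sample"]]
        ref = str(rowd[cmap["ref"]]).upper()
        alt = str(rowd[cmap["alt"]]).upper()
        if ref not in bases or alt not in bases:
            n_skipped += 1
            continue
        try:
            pos = int(rowd[cmap["pos"]])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-integer position {rowd[cmap['pos']]!r}") from exc
        cat = catalogs.setdefault(sample, MutationCatalog(sample))
        cat.records.append(
            MutationRecord(sample, str(rowd[cmap["chrom"]]), pos, ref, alt)
        )
    if n_skipped:
        logger.info("skipped %d non-SNV rows in %s", n_skipped, path)
    return CatalogSet(catalogs, n_skipped)


def write_mutation_table(
    catalogs: Mapping[str, MutationCatalog], path: str | Path
) -> None:
    rows = [
        (r.sample_id, r.chrom, r.pos, r.ref, r.alt)
        for cat in catalogs.values()
        for r in cat
    ]
    pd.DataFrame(rows, columns=["Sample", "Chrom", "Pos", "Ref", "Alt"]).to_csv(
        path, sep="\t", index=False
    )


def read_vcf(
    path: str | Path, depth_field: str = "DP", af_field: str = "AF"
) -> list[VariantSite]:
    """Read biallelic SNVs with depth and allele fraction from a VCF.

    Depth/AF are looked up in INFO first, then in the first sample's FORMAT
    fields. Non-SNV and multiallelic records are skipped.
    """
    import pysam

    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                continue
            depth = _vcf_field(rec, depth_field)
            af = _vcf_field(rec, af_field)
            sites.append(
                VariantSite(rec.chrom, rec.pos, ref, alt, int(depth), float(af))
            )
    return sites


def _vcf_field(rec, name: str):
    if name in rec.info:
        val = rec.info[name]
    else:
        sample = next(iter(rec.samples.values()), None)
        if sample is None or name not in sample:
            avail = sorted(set(rec.info.keys()) | set(rec.format.keys() if rec.format else []))
            raise ConfigError(
                f"field {name!r} absent from record {rec.chrom}:{rec.pos}; "
                f"available fields: {avail}"
            )
        val = sample[name]
    if isinstance(val, tuple):
        val = val[0]
    return val


def sbs96_channel(
    genome: GenomeSequence, record: MutationRecord, strict: bool = True
) -> str:
    """Resolve a mutation to its SBS96 channel label.

    Purine-reference records are reverse-complemented onto the pyrimidine
    strand. Raises :class:`DataIntegrityError` on a ref-base mismatch (always
    when ``strict``), :class:`ContextError` when the trinucleotide is
    unavailable or contains N.
    """
    triplet = genome.triplet(record.chrom, record.pos)
    if "N" in triplet:
        raise ContextError(
            f"N in trinucleotide context at {record.chrom}:{record.pos}"
        )
    if triplet[1] != record.ref:
        raise DataIntegrityError(
            f"reference mismatch at {record.chrom}:{record.pos}: "
            f"genome has {triplet[1]}, record says {record.ref}"
        )
    ref, alt = record.ref, record.alt
    if ref in "AG":  # purine strand: flip to the pyrimidine-centred description
        triplet = reverse_complement(triplet)
        ref = triplet[1]
        alt = reverse_complement(alt)
    return f"{triplet[0]}[{ref}>{alt}]{triplet[2]}"


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ file (0-based half-open)."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            intervals.append(GenomicInterval(parts[0], start, end))
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
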