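import numpy as np
import pytest

from radtmb import GenomeSequence, MutationCatalog, MutationRecord, make_genome
from radtmb.synthetic import ContextIndex

_COMPL = str.maketrans("ACGT", "TGCA")


@pytest.fixture(scope="session")
def rand_genome() -> GenomeSequence:
    """A 100 kb random genome shared across tests."""
    return make_genome(100_000, gc=0.41, seed=11)


@pytest.fixture(scope="session")
def rand_index(rand_genome) -> ContextIndex:
    return ContextIndex(rand_genome)


def records_for_context(
    index: ContextIndex,
    context: str,
    alt: str,
    n: int,
    sample_id: str = "S",
    skip: int = 0,
) -> list[MutationRecord]:
    """Deterministically build n records whose pyrimidine-strand context is
    ``context`` and alt (pyrimidine-strand) is ``alt``."""
    contig_ids, positions, fwd = index.sites_for(context)
    if positions.size < n + skip:
        raise AssertionError(f"not enough {context} sites in fixture genome")
    out = []
    ref = context[1]
    for j in range(skip, skip + n):
        contig = index.contig_names[contig_ids[j]]
        if fwd[j]:
            out.append(MutationRecord(sample_id, contig, int(positions[j]), ref, alt))
        else:
            out.append(
                MutationRecord(
                    sample_id,
                    contig,
                    int(positions[j]),
                    ref.translate(_COMPL),
                    alt.translate(_COMPL),
                )
            )
    return out


def catalog_of(records, sample_id="S") -> MutationCatalog:
    return MutationCatalog(sample_id, list(records))
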