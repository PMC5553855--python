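"""Shared fixtures: a reusable toy target and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from chromguide.amplicon import AmpliconTarget
from chromguide.sequtils import revcomp
from chromguide.synthetic import IndelSpectrumEntry, ReadSimSpec

PRIMER_LEN = 22
AMP_HALF = 110

SINGLE_DEL5 = (IndelSpectrumEntry("del", 5, 0, 1.0),)


def build_target(
    target_id: str = "tgt1",
    chrom: str = "chrT",
    cut: int = 1110,
    strand: str = "+",
    seed: int = 0,
) -> tuple[AmpliconTarget, str]:
    """An amplicon target centered on ``cut`` plus a matching amplicon sequence."""
    rng = np.random.default_rng(seed)
    amp_start, amp_end = cut - AMP_HALF, cut + AMP_HALF
    amplicon = "".join(np.array(list("ACGT"))[rng.integers(0, 4, amp_end - amp_start)])
    proto_start = cut - 17 if strand == "+" else cut - 3
    target = AmpliconTarget(
        target_id=target_id,
        gene="toygene",
        chrom=chrom,
        proto_start=proto_start,
        proto_end=proto_start + 20,
        strand=strand,
        amplicon_start=amp_start,
        amplicon_end=amp_end,
        fwd_primer=amplicon[:PRIMER_LEN],
        rev_primer=revcomp(amplicon[-PRIMER_LEN:]),
    )
    return target, amplicon


@pytest.fixture
def target_and_amplicon():
    return build_target()


@pytest.fixture
def read_spec(target_and_amplicon):
    target, amplicon = target_and_amplicon
    return ReadSimSpec(
        target=target, amplicon_seq=amplicon, indel_fraction=0.3,
        n_pairs=500, seed=11,
    )
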