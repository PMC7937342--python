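import numpy as np
import pysam
import pytest

from ripseq import depurination as dep
from ripseq import simulate as sim


@pytest.fixture(scope="session")
def reference():
    return sim.default_srl_reference()


@pytest.fixture(scope="session")
def span(reference):
    return dep.locate_srl(reference)


def write_sam(path, reference, segments):
    """Write a small SAM file of (name, start, sequence, cigar) tuples
    against ``reference`` plus a decoy contig."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [
            {"SN": reference.id, "LN": len(reference)},
            {"SN": "decoy", "LN": 500},
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, start, seq, cigar in segments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.query_sequence = seq
            a.reference_id = 0
            a.reference_start = start
            a.cigarstring = cigar
            a.mapping_quality = 60
            out.write(a)
    return path
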