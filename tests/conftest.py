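import edlib
import pytest

from amplihap.seqio import revcomp
from amplihap.simulate import StrSpec, make_amplicon_template


@pytest.fixture(scope="session")
def template():
    """Default 9 kb diploid template (102 SNPs, 7 indels, one het STR)."""
    return make_amplicon_template(seed=1)


@pytest.fixture(scope="session")
def small_template():
    """A 2 kb template for fast tests."""
    return make_amplicon_template(
        length=2000, n_snps=20, n_indels=3, str_spec=StrSpec(pos=369),
        homopolymer_spec=(("T", 10), ("A", 8)), seed=3, max_indel_len=2,
    )


def orient_to(seq: str, truth: str) -> str:
    """Return seq or its reverse complement, whichever matches truth better.

    A reference-free consensus has arbitrary orientation.
    """
    d_f = edlib.align(seq, truth, task="distance")["editDistance"]
    d_r = edlib.align(revcomp(seq), truth, task="distance")["editDistance"]
    return seq if d_f <= d_r else revcomp(seq)


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def error_positions(seq: str, truth: str):
    """Positions (on truth) where seq differs, via a full alignment path."""
    import re

    res = edlib.align(seq, truth, task="path")
    pos = 0
    errs = []
    for m in re.finditer(r"(\d+)([=XIDM])", res["cigar"]):
        n, op = int(m.group(1)), m.group(2)
        if op in "=M":
            pos += n
        elif op == "X":
            errs.extend(range(pos, pos + n))
            pos += n
        elif op == "I":
            errs.append(pos)
        else:
            errs.extend(range(pos, pos + n))
            pos += n
    return errs
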