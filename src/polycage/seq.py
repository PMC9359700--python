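"""Small sequence helpers shared by the annotation and start-site modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end) (0-based half-open), uppercased.

    ``genome`` may be a plain dict of chromosome strings or a
    ``pyfaidx.Fasta`` handle; both support the same slicing pattern.
    """
    if start < 0:
        raise IndexError(f"negative coordinate {start} on {chrom}")
    seg = genome[chrom][start:end]
    seq = seg if isinstance(seg, str) else seg.seq
    if len(seq) < end - start:
        raise IndexError(f"{chrom}:{start}-{end} exceeds chromosome bounds")
    return seq.upper()


def chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])
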