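"""Small sequence/coordinate helpers shared across modules.

Internal convention: 0-based half-open reference coordinates everywhere;
"sense" coordinates count in the direction of transcription, so for a
minus-strand feature sense offset 0 is the highest reference coordinate.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Union

import pyfaidx

_COMP = str.maketrans("ACGTNRYacgtnry", "TGCANYRtgcanyr")

GenomeLike = Union[Mapping[str, str], str, Path]


def revcomp(seq: str) -> str:
    """Reverse complement (preserves case, N stays N)."""
    return seq.translate(_COMP)[::-1]


def load_genome(source: GenomeLike) -> dict[str, str]:
    """Return {chrom: uppercase sequence} from a FASTA path or mapping."""
    if isinstance(source, (str, Path)):
        fa = pyfaidx.Fasta(str(source))
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    return {name: str(seq).upper() for name, seq in source.items()}


def sense_sequence(genome: Mapping[str, str], chrom: str, start: int, end: int,
                   strand: str) -> str:
    """Sense-strand sequence of the reference interval [start, end)."""
    seq = genome[chrom][start:end]
    return revcomp(seq) if strand == "-" else seq


def sense_offset(ref_pos: int, start: int, end: int, strand: str) -> int:
    """Sense offset of reference position ``ref_pos`` within [start, end)."""
    return (end - 1 - ref_pos) if strand == "-" else (ref_pos - start)


def ref_position(offset: int, start: int, end: int, strand: str) -> int:
    """Inverse of :func:`sense_offset`."""
    return (end - 1 - offset) if strand == "-" else (start + offset)
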