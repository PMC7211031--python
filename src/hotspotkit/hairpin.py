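"""Hairpin stem-strength scoring for APOBEC3A passenger-hotspot labelling.

A mutated base is placed at every loop position of every loop length from
3 to 11, and the flanking arms are paired outward from the loop: each
contiguous Watson-Crick pair scores 3 (G:C) or 1 (A:T), stopping at the
first mismatch. The best-scoring configuration is compared against a
table of minimum stem strengths defined only for nine amenable
(loop position, loop length) combinations; configurations outside the
table are labelled ``No``, amenable ones ``Likely`` or ``Unlikely``
depending on the threshold. Mutations reported on G or T are scored on
the reverse-complement strand so the mutated base is always C or A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from pyfaidx import Fasta

logger = logging.getLogger(__name__)

LOOP_LENGTHS = range(3, 12)
DEFAULT_WINDOW = 25
DEFAULT_MAX_STEM = 10

#: (loop_position, loop_length) -> minimum stem strength for "Likely".
DEFAULT_THRESHOLDS: Mapping[tuple[int, int], int] = {
    (3, 3): 7,
    (3, 4): 12,
    (4, 4): 11,
    (4, 5): 12,
    (4, 6): 15,
    (5, 6): 14,
    (4, 7): 18,
    (5, 7): 15,
    (6, 8): 16,
}

_PAIR_SCORE = {
    ("G", "C"): 3,
    ("C", "G"): 3,
    ("A", "T"): 1,
    ("T", "A"): 1,
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HairpinConfig:
    """One loop placement and its stem strength."""

    loop_length: int
    loop_position: int
    stem_strength: int

    def __post_init__(self) -> None:
        if not 3 <= self.loop_length <= 11:
            raise ValueError("loop_length must be in 3..11")
        if not 1 <= self.loop_position <= self.loop_length:
            raise ValueError("loop_position must be in 1..loop_length")
        if self.stem_strength < 0:
            raise ValueError("stem_strength must be >= 0")


@dataclass
class HairpinAnnotation:
    best: HairpinConfig
    label: str  # Likely | Unlikely | No
    strand_flipped: bool
    context: str


def extract_context(
    reference: Fasta | str,
    chrom: str,
    genomic_pos: int,
    window: int = DEFAULT_WINDOW,
) -> str:
    """Sequence of length 2*window+1 centered on a 1-based position.

    Positions running off the contig are padded with N (with a warning).
    """
    fasta = Fasta(reference) if isinstance(reference, str) else reference
    if chrom not in fasta:
        raise KeyError(f"contig {chrom!r} not found in reference")
    contig = fasta[chrom]
    length = len(contig)
    if not 1 <= genomic_pos <= length:
        raise ValueError(f"position {genomic_pos} outside contig {chrom} (1..{length})")
    lo = genomic_pos - 1 - window  # 0-based inclusive
    hi = genomic_pos + window  # 0-based exclusive
    left_pad = max(0, -lo)
    right_pad = max(0, hi - length)
    seq = str(contig[max(lo, 0):min(hi, length)]).upper()
    if left_pad or right_pad:
        logger.warning(
            "context at %s:%d truncated by contig edge, padded with %d N",
            chrom, genomic_pos, left_pad + right_pad,
        )
    return "N" * left_pad + seq + "N" * right_pad


def orient_sequence(context: str, center_ref_base: str | None = None) -> tuple[str, bool]:
    """Reverse-complement the context when the centered base is G or T."""
    center = center_ref_base or context[len(context) // 2]
    center = center.upper()
    if center not in "ACGT":
        raise ValueError(f"center base {center!r} is not A/C/G/T")
    if center in "GT":
        return reverse_complement(context), True
    return context, False


def stem_strength(
    context: str,
    loop_length: int,
    loop_position: int,
    max_stem: int = DEFAULT_MAX_STEM,
    center: int | None = None,
) -> int:
    """Score the stem of a loop placed so the center base sits at loop_position.

    Pairs the bases immediately flanking the loop and steps outward,
    adding 3 per G:C and 1 per A:T, stopping at the first non-pairing
    step, at a context edge or N, or after ``max_stem`` pairs.
    """
    if center is None:
        center = len(context) // 2
    loop_start = center - (loop_position - 1)
    loop_end = loop_start + loop_length - 1
    if loop_start < 0 or loop_end >= len(context):
        raise ValueError(
            f"loop (length {loop_length}, position {loop_position}) exceeds context"
        )
    score = 0
    for step in range(max_stem):
        left = loop_start - 1 - step
        right = loop_end + 1 + step
        if left < 0 or right >= len(context):
            break
        pair_score = _PAIR_SCORE.get((context[left], context[right]))
        if pair_score is None:
            break
        score += pair_score
    return score


def best_hairpin(
    context: str, max_stem: int = DEFAULT_MAX_STEM, center: int | None = None
) -> HairpinConfig:
    """Argmax of stem strength over all loop length/position combinations.

    Ties prefer the smaller loop length, then the smaller loop position.
    """
    best: HairpinConfig | None = None
    for length in LOOP_LENGTHS:
        for pos in range(1, length + 1):
            try:
                ss = stem_strength(context, length, pos, max_stem=max_stem, center=center)
            except ValueError:
                continue
            if best is None or ss > best.stem_strength:
                best = HairpinConfig(loop_length=length, loop_position=pos, stem_strength=ss)
    if best is None:
        raise ValueError("context too short for any loop configuration")
    return best


def classify(
    config: HairpinConfig,
    table: Mapping[tuple[int, int], int] = DEFAULT_THRESHOLDS,
) -> str:
    """Label a configuration Likely / Unlikely / No.

    The label depends only on (loop_position, loop_length, stem strength)
    and the threshold table; the surrounding sequence context is
    deliberately not consulted.
    """
    key = (config.loop_position, config.loop_length)
    threshold = table.get(key)
    if threshold is None:
        return "No"
    return "Likely" if config.stem_strength >= threshold else "Unlikely"


def annotate_context(
    context: str,
    table: Mapping[tuple[int, int], int] = DEFAULT_THRESHOLDS,
    max_stem: int = DEFAULT_MAX_STEM,
) -> HairpinAnnotation:
    """Orient, score and label a pre-extracted, centered context."""
    center_base = context[len(context) // 2]
    if center_base not in "ACGT":
        logger.warning("center base %r is not A/C/G/T; labelling No", center_base)
        return HairpinAnnotation(
            best=HairpinConfig(3, 1, 0), label="No", strand_flipped=False, context=context
        )
    oriented, flipped = orient_sequence(context, center_base)
    best = best_hairpin(oriented, max_stem=max_stem)
    return HairpinAnnotation(
        best=best, label=classify(best, table), strand_flipped=flipped, context=oriented
    )


def annotate_mutation(
    reference: Fasta | str,
    record,
    table: Mapping[tuple[int, int], int] = DEFAULT_THRESHOLDS,
    window: int = DEFAULT_WINDOW,
    max_stem: int = DEFAULT_MAX_STEM,
) -> HairpinAnnotation:
    """Extract the mutation's genomic context and annotate it."""
    if record.genomic_pos is None or not record.chrom:
        raise ValueError("record lacks chrom/genomic_pos for hairpin annotation")
    context = extract_context(reference, record.chrom, record.genomic_pos, window=window)
    return annotate_context(context, table=table, max_stem=max_stem)


__all__ = [
    "HairpinConfig",
    "HairpinAnnotation",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_WINDOW",
    "DEFAULT_MAX_STEM",
    "LOOP_LENGTHS",
    "reverse_complement",
    "extract_context",
    "orient_sequence",
    "stem_strength",
    "best_hairpin",
    "classify",
    "annotate_context",
    "annotate_mutation",
]
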