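"""Simplified gene-level dN/dS estimation.

Selection opportunities are counted by exhaustive enumeration of all
single-nucleotide changes over a gene's coding sequence, optionally
weighted by a context-free substitution-rate model. Observed mutation
counts per consequence class are then compared with the neutral
expectation anchored on the silent count:

    w_X = observed_X / (observed_silent * opp_X / opp_silent)

for X in {missense, nonsense, splice, indel}, with one-sided Poisson
p-values and an overall summary max(wmis, wnon). This is a deliberately
simple counting estimator: no covariate regression and no trinucleotide
context model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import poisson

from hotspotkit.mutation_io import MutationRecord, normalize_consequence

logger = logging.getLogger(__name__)

#: Consequence classes that enter the dN/dS computation.
DNDS_CLASSES = frozenset(
    {"missense", "nonsense", "nonstop", "silent", "splice", "frameshift",
     "inframe_indel", "start_site"}
)

_BASES = "ACGT"

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass
class OpportunityCounts:
    """Neutral opportunity fractions for one gene.

    ``silent``, ``missense`` and ``nonsense`` are the expected fractions
    of random single-nucleotide changes in each class (they sum to 1).
    ``splice`` and ``indel`` are optional opportunity weights on the same
    relative scale; when absent the corresponding w is not estimated.
    """

    gene: str
    silent: float
    missense: float
    nonsense: float
    splice: float | None = None
    indel: float | None = None


@dataclass
class DnDsEstimate:
    gene: str
    wmis: float
    wnon: float
    wspl: float | None
    wind: float | None
    p_mis: float
    p_non: float
    p_spl: float | None
    p_ind: float | None
    w_summary: float
    n_silent: int
    silent_pseudocount: bool = False


def classify_consequence(record: MutationRecord | str) -> str:
    """Canonical consequence class of a record; ``other`` is excluded downstream."""
    raw = record.consequence if isinstance(record, MutationRecord) else record
    return normalize_consequence(raw)


def opportunities_from_cds(
    cds: str,
    rates: Mapping[tuple[str, str], float] | None = None,
    gene: str = "",
    n_introns: int | None = None,
    indel_rate_per_bp: float | None = None,
) -> OpportunityCounts:
    """Enumerate all 3L single-nucleotide changes of a coding sequence.

    Each change is classified against the standard codon table (stop-gain
    is nonsense, stop-loss counts with missense) and weighted by the
    substitution model ``rates`` mapping (ref, alt) to a relative rate
    (uniform when omitted). Splice opportunity, when ``n_introns`` is
    given, assumes 2 essential sites per intron boundary; indel
    opportunity is proportional to CDS length.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    weights = {"silent": 0.0, "missense": 0.0, "nonsense": 0.0}
    for codon_start in range(0, len(cds), 3):
        codon = cds[codon_start:codon_start + 3]
        aa = _CODON_TABLE.get(codon)
        if aa is None:
            raise ValueError(f"non-ACGT codon {codon!r} at {codon_start}")
        for offset in range(3):
            ref = codon[offset]
            for alt in _BASES:
                if alt == ref:
                    continue
                w = 1.0 if rates is None else float(rates[(ref, alt)])
                new_codon = codon[:offset] + alt + codon[offset + 1:]
                new_aa = _CODON_TABLE[new_codon]
                if new_aa == aa:
                    cls = "silent"
                elif new_aa == "*":
                    cls = "nonsense"
                else:
                    cls = "missense"  # includes stop-loss
                weights[cls] += w
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("empty CDS")
    splice = None
    if n_introns is not None:
        # 2 essential bases per boundary, 2 boundaries per intron, relative
        # to the 3L possible coding changes
        splice = (4.0 * n_introns) / len(cds)
    indel = None
    if indel_rate_per_bp is not None:
        indel = indel_rate_per_bp * len(cds) / 3.0
    return OpportunityCounts(
        gene=gene,
        silent=weights["silent"] / total,
        missense=weights["missense"] / total,
        nonsense=weights["nonsense"] / total,
        splice=splice,
        indel=indel,
    )


def _one_sided_poisson(observed: int, expected: float) -> float:
    """P-value of the observed count in its direction of deviation."""
    if expected <= 0:
        return 1.0
    if observed >= expected:
        return float(poisson.sf(observed - 1, expected))
    return float(poisson.cdf(observed, expected))


def estimate_dnds(
    mutations: Sequence[MutationRecord | str],
    opp: OpportunityCounts,
    pseudocount: float = 0.5,
) -> DnDsEstimate:
    """Estimate wmis/wnon (and wspl/wind when opportunities are known).

    The neutral expectation for class X is anchored on the observed
    silent count: ``expected_X = silent * opp_X / opp_silent``. A zero
    silent count is replaced by ``pseudocount`` and flagged.
    """
    counts = {"missense": 0, "nonsense": 0, "silent": 0, "splice": 0, "indel": 0}
    for m in mutations:
        cls = classify_consequence(m)
        if cls in ("missense", "nonstop"):
            counts["missense"] += 1
        elif cls == "nonsense":
            counts["nonsense"] += 1
        elif cls == "silent":
            counts["silent"] += 1
        elif cls == "splice":
            counts["splice"] += 1
        elif cls in ("frameshift", "inframe_indel"):
            counts["indel"] += 1
        # start_site and other: excluded

    n_silent = counts["silent"]
    used_pseudo = n_silent == 0
    silent_anchor = float(n_silent) if n_silent > 0 else pseudocount
    if used_pseudo:
        logger.warning("gene %s: zero silent mutations, pseudocount %.2f applied",
                       opp.gene, pseudocount)

    def ratio(observed: int, opp_x: float | None) -> tuple[float | None, float | None]:
        if opp_x is None:
            return None, None
        expected = silent_anchor * opp_x / opp.silent
        w = observed / expected if expected > 0 else np.inf
        return float(w), _one_sided_poisson(observed, expected)

    wmis, p_mis = ratio(counts["missense"], opp.missense)
    wnon, p_non = ratio(counts["nonsense"], opp.nonsense)
    wspl, p_spl = ratio(counts["splice"], opp.splice)
    wind, p_ind = ratio(counts["indel"], opp.indel)
    return DnDsEstimate(
        gene=opp.gene,
        wmis=wmis,
        wnon=wnon,
        wspl=wspl,
        wind=wind,
        p_mis=p_mis,
        p_non=p_non,
        p_spl=p_spl,
        p_ind=p_ind,
        w_summary=max(wmis, wnon),
        n_silent=n_silent,
        silent_pseudocount=used_pseudo,
    )


__all__ = [
    "DNDS_CLASSES",
    "OpportunityCounts",
    "DnDsEstimate",
    "classify_consequence",
    "opportunities_from_cds",
    "estimate_dnds",
]
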