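"""Synthetic cohorts, hairpin sequences and neutral genes with known truth.

Everything here is deterministic under a seed and writes the same
MAF-dialect TSV / FASTA the real readers consume, so fixtures exercise
the production code paths end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import betabinom as _betabinom_dist

from hotspotkit.dnds import OpportunityCounts
from hotspotkit.mutation_io import MutationRecord


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: background BetaBin(a, b) per-site counts."""

    name: str
    protein_length: int
    a: float
    b: float


@dataclass(frozen=True)
class SpikeSpec:
    """A position whose recurrence is forced (a planted hotspot)."""

    gene: str
    position: int
    recurrence: int


@dataclass
class SimSpec:
    n_patients: int
    genes: list[GeneSpec]
    spikes: list[SpikeSpec] = field(default_factory=list)
    seed: int = 0
    cancer_type: str = "SIM"

    def validate(self) -> None:
        names = {g.name for g in self.genes}
        lengths = {g.name: g.protein_length for g in self.genes}
        for s in self.spikes:
            if s.gene not in names:
                raise ValueError(f"spike references unknown gene {s.gene!r}")
            if s.recurrence > self.n_patients:
                raise ValueError(f"spike recurrence {s.recurrence} > n_patients")
            if not 1 <= s.position <= lengths[s.gene]:
                raise ValueError(f"spike position {s.position} outside gene {s.gene}")


def simulate_cohort(spec: SimSpec) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Draw per-site patient counts and expand them into mutation records.

    Each site's distinct-patient count is BetaBin(n_patients, a, b);
    spiked sites are overridden to their stated recurrence. Returns the
    records plus a truth table of all mutated sites with a ``spiked``
    column. Deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    patients = [f"P{j:05d}" for j in range(spec.n_patients)]
    spiked = {(s.gene, s.position): s.recurrence for s in spec.spikes}

    records: list[MutationRecord] = []
    truth_rows = []
    for gi, gene in enumerate(sorted(spec.genes, key=lambda g: g.name)):
        counts = _betabinom_dist.rvs(
            spec.n_patients, gene.a, gene.b, size=gene.protein_length, random_state=rng
        )
        for pos0, count in enumerate(counts):
            pos = pos0 + 1
            count = int(spiked.get((gene.name, pos), count))
            if count == 0:
                continue
            chosen = rng.choice(spec.n_patients, size=count, replace=False)
            for pj in sorted(chosen):
                records.append(
                    MutationRecord(
                        patient_id=patients[pj],
                        gene=gene.name,
                        transcript_id=f"TX_{gene.name}",
                        protein_pos=pos,
                        aa_change=f"A{pos}V",
                        consequence="missense",
                        chrom="chrS",
                        genomic_pos=gi * 10_000_000 + pos * 3,
                        ref_allele="C",
                        alt_allele="T",
                        cancer_type=spec.cancer_type,
                    )
                )
            truth_rows.append(
                {
                    "gene": gene.name,
                    "protein_pos": pos,
                    "recurrence": count,
                    "spiked": (gene.name, pos) in spiked,
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "protein_pos", "recurrence", "spiked"]
    )
    return records, truth


def make_hairpin_sequence(
    loop_length: int,
    loop_position: int,
    stem_pairs: Sequence[str],
    flank: int = 12,
) -> tuple[str, int, int]:
    """Build a sequence containing one designed hairpin with known score.

    ``stem_pairs`` lists the pairs from the loop outward, each ``"GC"``
    or ``"AT"`` (first letter on the 5' arm). The mutated base (center)
    is a C at ``loop_position`` within the loop; the other loop bases
    are N, which never pairs, so any rival configuration whose stem
    would start inside the designed loop scores zero. Flanks beyond the
    stem are homopolymers (left C / right A) that cannot pair with the
    bases facing them, making the designed configuration the argmax.

    Returns ``(sequence, center_index, expected_stem_strength)``.
    """
    if not 3 <= loop_length <= 11:
        raise ValueError("loop_length must be in 3..11")
    if not 1 <= loop_position <= loop_length:
        raise ValueError("loop_position must be in 1..loop_length")
    scores = {"GC": 3, "AT": 1}
    for p in stem_pairs:
        if p not in scores:
            raise ValueError(f"stem pair must be 'GC' or 'AT', got {p!r}")

    loop = ["N"] * loop_length
    loop[loop_position - 1] = "C"
    left_arm = "".join(p[0] for p in reversed(stem_pairs))   # outermost first
    right_arm = "".join(p[1] for p in stem_pairs)            # innermost first
    seq = "C" * flank + left_arm + "".join(loop) + right_arm + "A" * flank
    center = flank + len(stem_pairs) + (loop_position - 1)
    expected_ss = sum(scores[p] for p in stem_pairs)
    return seq, center, expected_ss


def simulate_neutral_gene(
    n_positions: int,
    n_mutations: int,
    opportunities: OpportunityCounts,
    seed: int = 0,
    gene: str | None = None,
) -> list[MutationRecord]:
    """Mutations drawn with class probabilities equal to the opportunities.

    Under this null every dN/dS ratio has expectation 1. Deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    gene = gene or opportunities.gene or "NEUTRAL"
    classes = ["silent", "missense", "nonsense"]
    probs = np.array(
        [opportunities.silent, opportunities.missense, opportunities.nonsense]
    )
    probs = probs / probs.sum()
    drawn = rng.choice(len(classes), size=n_mutations, p=probs)
    positions = rng.integers(1, n_positions + 1, size=n_mutations)
    records = []
    for j, (ci, pos) in enumerate(zip(drawn, positions)):
        records.append(
            MutationRecord(
                patient_id=f"P{j:05d}",
                gene=gene,
                transcript_id=f"TX_{gene}",
                protein_pos=int(pos),
                aa_change=None,
                consequence=classes[ci],
                chrom="chrS",
                genomic_pos=int(pos) * 3,
                ref_allele="C",
                alt_allele="T",
                cancer_type="SIM",
            )
        )
    return records


__all__ = [
    "GeneSpec",
    "SpikeSpec",
    "SimSpec",
    "simulate_cohort",
    "make_hairpin_sequence",
    "simulate_neutral_gene",
]
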