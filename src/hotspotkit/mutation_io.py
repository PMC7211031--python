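"""Reading, filtering and aggregating MAF-style somatic mutation tables.

The canonical record keeps 1-based protein and genomic coordinates. Input
is tab-separated with a header row; TCGA-dialect column names are
recognized out of the box and other dialects can be mapped via
``column_map``.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical consequence classes. Anything else maps to ``other``.
CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "nonstop",
        "silent",
        "splice",
        "frameshift",
        "inframe_indel",
        "start_site",
        "other",
    }
)

#: MAF ``Variant_Classification`` strings -> canonical consequence.
VARIANT_CLASSIFICATION_MAP: Mapping[str, str] = {
    "missense_mutation": "missense",
    "missense": "missense",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "nonstop_mutation": "nonstop",
    "nonstop": "nonstop",
    "silent": "silent",
    "synonymous": "silent",
    "splice_site": "splice",
    "splice_region": "splice",
    "splice": "splice",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "frameshift": "frameshift",
    "in_frame_del": "inframe_indel",
    "in_frame_ins": "inframe_indel",
    "inframe_indel": "inframe_indel",
    "translation_start_site": "start_site",
    "start_codon_snp": "start_site",
    "start_codon_del": "start_site",
    "start_codon_ins": "start_site",
    "start_site": "start_site",
}

#: Canonical field -> accepted header names, first match wins.
_DIALECT_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "gene": ("Hugo_Symbol", "gene", "Gene"),
    "patient_id": ("Tumor_Sample_Barcode", "patient_id", "Patient", "sample"),
    "transcript_id": ("Transcript_ID", "Annotation_Transcript", "transcript_id", "Feature"),
    "protein_change": ("Protein_Change", "HGVSp_Short", "protein_change", "amino_acid_change"),
    "consequence": ("Variant_Classification", "consequence", "Consequence"),
    "chrom": ("Chromosome", "chrom", "CHROM"),
    "genomic_pos": ("Start_Position", "Start_position", "genomic_pos", "POS"),
    "ref_allele": ("Reference_Allele", "ref_allele", "REF"),
    "alt_allele": ("Tumor_Seq_Allele2", "Tumor_Seq_Allele1", "alt_allele", "ALT"),
    "cancer_type": ("Cancer_Type", "cancer_type", "Project", "cohort"),
}

_MANDATORY = ("gene", "patient_id", "consequence")

# p.V600E, p.Q61*, p.*757L, V600E ... captures (ref aa, position, rest)
_PROTEIN_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Za-z*])(\d+)(.*)$")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation row.

    ``protein_pos`` is a 1-based amino-acid index (``None`` when the raw
    row did not provide a parseable protein position); ``genomic_pos`` is
    a 1-based genomic coordinate.
    """

    patient_id: str
    gene: str
    transcript_id: str = ""
    protein_pos: int | None = None
    aa_change: str | None = None
    consequence: str = "other"
    chrom: str = ""
    genomic_pos: int | None = None
    ref_allele: str = ""
    alt_allele: str = ""
    cancer_type: str = ""

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.protein_pos is not None and self.protein_pos < 1:
            raise ValueError("protein_pos must be >= 1")
        if self.genomic_pos is not None and self.genomic_pos < 1:
            raise ValueError("genomic_pos must be >= 1")


@dataclass
class PositionCounts:
    """Distinct-patient recurrence per protein position for one gene."""

    gene: str
    transcript_id: str = ""
    counts: dict[int, int] = field(default_factory=dict)
    protein_length: int | None = None

    def max_recurrence(self) -> int:
        return max(self.counts.values(), default=0)

    def n_sites(self) -> int:
        """Assayable positions: protein length when known, else max mutated."""
        if self.protein_length is not None:
            return self.protein_length
        return max(self.counts.keys(), default=0)


def normalize_consequence(raw: str) -> str:
    """Map a MAF variant-classification string to the canonical enum."""
    key = str(raw).strip().lower()
    return VARIANT_CLASSIFICATION_MAP.get(key, key if key in CONSEQUENCES else "other")


def parse_protein_change(raw: object) -> tuple[int | None, str | None]:
    """Parse a short protein change like ``p.V600E`` -> ``(600, "V600E")``."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None, None
    text = str(raw).strip()
    if not text or text.lower() in {"nan", ".", "na"}:
        return None, None
    m = _PROTEIN_CHANGE_RE.match(text)
    if not m:
        return None, None
    ref_aa, pos, rest = m.groups()
    return int(pos), f"{ref_aa}{pos}{rest}"


def _resolve_columns(
    header: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for canon, candidates in _DIALECT_COLUMNS.items():
        if canon in column_map:
            if column_map[canon] in header:
                resolved[canon] = column_map[canon]
            continue
        for cand in candidates:
            if cand in header:
                resolved[canon] = cand
                break
    missing = [c for c in _MANDATORY if c not in resolved]
    if missing:
        raise ValueError(
            "MAF is missing mandatory column(s): "
            + ", ".join(f"{c} (accepted: {', '.join(_DIALECT_COLUMNS[c])})" for c in missing)
        )
    return resolved


def read_maf(
    path: str, column_map: Mapping[str, str] | None = None
) -> list[MutationRecord]:
    """Read a MAF-style TSV into canonical mutation records.

    Rows lacking a parseable protein position are kept with
    ``protein_pos=None``; rows with unparseable numeric genomic fields are
    skipped with a warning. A load report (rows read / skipped) goes to
    the module logger.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    cols = _resolve_columns(list(df.columns), column_map)

    records: list[MutationRecord] = []
    n_skipped = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))

        def get(canon: str, default: str = "") -> str:
            col = cols.get(canon)
            return str(row_d[col]).strip() if col is not None else default

        genomic_pos: int | None = None
        raw_pos = get("genomic_pos")
        if raw_pos:
            try:
                genomic_pos = int(float(raw_pos))
            except ValueError:
                logger.warning("row %d: unparseable genomic position %r, skipped", idx, raw_pos)
                n_skipped += 1
                continue

        protein_pos, aa_change = parse_protein_change(get("protein_change"))
        try:
            records.append(
                MutationRecord(
                    patient_id=get("patient_id"),
                    gene=get("gene"),
                    transcript_id=get("transcript_id"),
                    protein_pos=protein_pos,
                    aa_change=aa_change,
                    consequence=normalize_consequence(get("consequence")),
                    chrom=get("chrom"),
                    genomic_pos=genomic_pos,
                    ref_allele=get("ref_allele"),
                    alt_allele=get("alt_allele"),
                    cancer_type=get("cancer_type"),
                )
            )
        except ValueError as exc:
            logger.warning("row %d: %s, skipped", idx, exc)
            n_skipped += 1
    logger.info("read_maf(%s): %d records, %d skipped", path, len(records), n_skipped)
    return records


_CANONICAL_COLUMNS = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Transcript_ID",
    "Protein_Change",
    "Variant_Classification",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Cancer_Type",
)


def write_maf(records: Iterable[MutationRecord], path: str) -> None:
    """Write records as canonical tab-separated MAF (fixed column order)."""
    rows = []
    for r in records:
        rows.append(
            {
                "Hugo_Symbol": r.gene,
                "Tumor_Sample_Barcode": r.patient_id,
                "Transcript_ID": r.transcript_id,
                "Protein_Change": f"p.{r.aa_change}" if r.aa_change else "",
                "Variant_Classification": r.consequence,
                "Chromosome": r.chrom,
                "Start_Position": "" if r.genomic_pos is None else r.genomic_pos,
                "Reference_Allele": r.ref_allele,
                "Tumor_Seq_Allele2": r.alt_allele,
                "Cancer_Type": r.cancer_type,
            }
        )
    pd.DataFrame(rows, columns=list(_CANONICAL_COLUMNS)).to_csv(path, sep="\t", index=False)


def filter_coding(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Keep only records that provide a protein position (order preserved)."""
    return [r for r in records if r.protein_pos is not None]


def aggregate_positions(
    records: Sequence[MutationRecord],
    protein_lengths: Mapping[str, int] | None = None,
    dedup_patients: bool = True,
) -> dict[str, PositionCounts]:
    """Aggregate mutations per (gene, protein position).

    Recurrence counts distinct patients per position by default
    (``dedup_patients=False`` counts raw rows). The transcript recorded
    per gene is the most frequent one among its rows; ties break
    lexicographically for determinism.
    """
    protein_lengths = protein_lengths or {}
    per_pos: dict[str, dict[int, set[str] | int]] = defaultdict(dict)
    transcripts: dict[str, Counter] = defaultdict(Counter)
    for r in records:
        if r.protein_pos is None:
            raise ValueError(f"record without protein_pos in aggregate_positions: {r}")
        slot = per_pos[r.gene]
        if dedup_patients:
            slot.setdefault(r.protein_pos, set()).add(r.patient_id)  # type: ignore[union-attr]
        else:
            slot[r.protein_pos] = slot.get(r.protein_pos, 0) + 1  # type: ignore[operator]
        if r.transcript_id:
            transcripts[r.gene][r.transcript_id] += 1

    out: dict[str, PositionCounts] = {}
    for gene, slot in per_pos.items():
        counts = {
            pos: (len(v) if isinstance(v, set) else int(v)) for pos, v in sorted(slot.items())
        }
        tcounter = transcripts.get(gene, Counter())
        transcript = min(
            (t for t, c in tcounter.items() if c == max(tcounter.values())), default=""
        ) if tcounter else ""
        length = protein_lengths.get(gene)
        if length is not None and counts and max(counts) > length:
            raise ValueError(
                f"gene {gene}: mutated position {max(counts)} exceeds protein length {length}"
            )
        out[gene] = PositionCounts(
            gene=gene, transcript_id=transcript, counts=counts, protein_length=length
        )
    return out


def cohort_summary(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Per cancer type: number of distinct patients and total mutations."""
    if not records:
        return pd.DataFrame(columns=["cancer_type", "n_patients", "n_mutations"])
    df = pd.DataFrame(
        {"cancer_type": [r.cancer_type for r in records], "patient": [r.patient_id for r in records]}
    )
    out = (
        df.groupby("cancer_type")
        .agg(n_patients=("patient", "nunique"), n_mutations=("patient", "size"))
        .reset_index()
        .sort_values("cancer_type", ignore_index=True)
    )
    return out


def n_distinct_patients(records: Sequence[MutationRecord]) -> int:
    """Cohort size used as the binomial n of the hotspot model."""
    return len({r.patient_id for r in records})


__all__ = [
    "MutationRecord",
    "PositionCounts",
    "CONSEQUENCES",
    "VARIANT_CLASSIFICATION_MAP",
    "normalize_consequence",
    "parse_protein_change",
    "read_maf",
    "write_maf",
    "filter_coding",
    "aggregate_positions",
    "cohort_summary",
    "n_distinct_patients",
]
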