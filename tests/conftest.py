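import numpy as np
import pytest

from hotspotkit.mutation_io import MutationRecord


@pytest.fixture
def toy_records() -> list[MutationRecord]:
    """Five records: three with protein positions, two without."""
    return [
        MutationRecord("pat1", "BRAF", "TX1", 600, "V600E", "missense", "chr7", 140453136, "A", "T", "SKCM"),
        MutationRecord("pat2", "BRAF", "TX1", 600, "V600E", "missense", "chr7", 140453136, "A", "T", "THCA"),
        MutationRecord("pat3", "TP53", "TX2", 175, "R175H", "missense", "chr17", 7578406, "C", "T", "BRCA"),
        MutationRecord("pat1", "BRAF", "TX1", None, None, "splice", "chr7", 140453200, "G", "A", "SKCM"),
        MutationRecord("pat4", "TP53", "TX2", None, None, "other", "chr17", 7578500, "G", "C", "BRCA"),
    ]


@pytest.fixture
def toy_maf(tmp_path):
    """A 3-row MAF file with canonical TCGA-style headers."""
    path = tmp_path / "toy.maf"
    rows = [
        "Hugo_Symbol\tTumor_Sample_Barcode\tTranscript_ID\tProtein_Change\tVariant_Classification\tChromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2\tCancer_Type",
        "BRAF\tpat1\tTX1\tp.V600E\tMissense_Mutation\tchr7\t140453136\tA\tT\tSKCM",
        "TP53\tpat2\tTX2\tp.R175H\tMissense_Mutation\tchr17\t7578406\tC\tT\tBRCA",
        "KRAS\tpat3\tTX3\t\tSilent\tchr12\t25398284\tC\tT\tLUAD",
    ]
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_fasta(path, sequences: dict[str, str]) -> str:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return str(path)
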