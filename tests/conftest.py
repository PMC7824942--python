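import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tcrsimnet.io import CellTCR, ContigRecord


def make_contig(
    barcode="AAAC-1",
    sample_id="S1",
    chain="TRB",
    cdr3="CASSLGQAYEQYF",
    productive=True,
    high_confidence=True,
):
    return ContigRecord(
        barcode=barcode,
        sample_id=sample_id,
        chain=chain,
        cdr3_aa=cdr3,
        productive=productive,
        high_confidence=high_confidence,
    )


def make_cell(barcode, sample_id, alphas=(), betas=()):
    return CellTCR(
        barcode=barcode,
        sample_id=sample_id,
        alpha_chains=[make_contig(barcode, sample_id, "TRA", a) for a in alphas],
        beta_chains=[make_contig(barcode, sample_id, "TRB", b) for b in betas],
    )


@pytest.fixture
def contig_csv(tmp_path):
    """Small 10x-dialect contig table covering the parser edge cases."""
    rows = [
        # barcode, chain, cdr3, productive, high_confidence
        ("AAAC-1", "TRB", "CASSLGQAYEQYF", "True", "True"),
        ("AAAC-1", "TRA", "CAVRDNYQLIW", "True", "True"),
        ("AAAG-1", "TRB", "None", "True", "True"),  # unusable cdr3
        ("AAAG-1", "IGH", "CARGDYW", "True", "True"),  # non-TCR locus
        ("AAAT-1", "TRB", "CASSETQYF", "False", "True"),  # non-productive
    ]
    df = pd.DataFrame(rows, columns=["barcode", "chain", "cdr3", "productive", "high_confidence"])
    path = tmp_path / "filtered_contig_annotations.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def airr_tsv(tmp_path):
    rows = [
        ("AAAC-1", "TRA", "CAVRDNYQLIW", "T"),
        ("AAAC-1", "TRB", "CASSLGQAYEQYF", "T"),
        ("AAAG-1", "TRB", "CASSETQYF", "F"),
    ]
    df = pd.DataFrame(rows, columns=["cell_id", "locus", "junction_aa", "productive"])
    path = tmp_path / "rearrangements.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def metadata_csv(tmp_path):
    df = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3"],
            "diagnosis_group": ["AD", "MCI", "HC"],
            "age": ["71", "68", "66"],
        }
    )
    path = tmp_path / "metadata.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def mcpas_csv(tmp_path):
    """Tiny specificity database in McPAS-TCR column layout."""
    df = pd.DataFrame(
        {
            "CDR3.beta.aa": [
                "CASSLGQAYEQYF",
                "CASSLGQAYEQYF",
                "CASRDWGGEQYF",
                "NA",
                "CSARDLTSGANNEQFF",
            ],
            "Pathology": [
                "Epstein Barr virus (EBV)",
                "Epstein Barr virus (EBV)",
                "Influenza",
                "Influenza",
                "Cytomegalovirus (CMV)",
            ],
            "Antigen.protein": ["EBNA3A", "EBNA3A", "M1", "", "pp65"],
            "T.Cell.Type": ["CD8", "CD8", "CD8", "", "CD8"],
        }
    )
    path = tmp_path / "mcpas.csv"
    df.to_csv(path, index=False)
    return path
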