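import numpy as np
import pandas as pd
import pytest

from leaderscan.catalog import Leader, TranscriptRecord
from leaderscan.simulate import SimulationConfig, simulate_transcriptome


TOY_FASTA = """\
>ENST0001.2
AAACCCATGGGGTTTTAA
>ENST0002.1
GGGCCCAAAATGCCCGGGTAA
>ENST0003.1
ATGAAATTTTAA
"""

TOY_GTF = """\
ENST0001\ttoy\texon\t1\t18\t.\t+\t.\tgene_id "G1"; transcript_id "ENST0001";
ENST0001\ttoy\tCDS\t7\t15\t.\t+\t0\tgene_id "G1"; transcript_id "ENST0001";
ENST0002\ttoy\texon\t1\t21\t.\t+\t.\tgene_id "G2"; transcript_id "ENST0002";
ENST0002\ttoy\tCDS\t10\t18\t.\t+\t0\tgene_id "G2"; transcript_id "ENST0002";
ENST0003\ttoy\texon\t1\t12\t.\t+\t.\tgene_id "G3"; transcript_id "ENST0003";
ENST0003\ttoy\tCDS\t1\t9\t.\t+\t0\tgene_id "G3"; transcript_id "ENST0003";
"""


@pytest.fixture
def toy_inputs(tmp_path):
    """Three-transcript FASTA + GTF + APPRIS/TPM tables on disk."""
    fasta = tmp_path / "toy.fa"
    gtf = tmp_path / "toy.gtf"
    fasta.write_text(TOY_FASTA)
    gtf.write_text(TOY_GTF)
    pd.DataFrame(
        {
            "transcript_id": ["ENST0001", "ENST0002", "ENST0003"],
            "tag": ["PRINCIPAL:1", "PRINCIPAL:2", "ALTERNATIVE:1"],
        }
    ).to_csv(tmp_path / "appris.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "transcript_id": ["ENST0001", "ENST0002", "ENST0003"],
            "tpm": [5.0, 9.0, 3.0],
        }
    ).to_csv(tmp_path / "tpm.tsv", sep="\t", index=False)
    return {
        "fasta": fasta,
        "gtf": gtf,
        "appris": tmp_path / "appris.tsv",
        "tpm": tmp_path / "tpm.tsv",
    }


def make_record(tid="T1", gid="G1", seq="AAACCCATGGGG", cds_start=7, tag="NONE", tpm=1.0):
    return TranscriptRecord(
        transcript_id=tid,
        gene_id=gid,
        sequence=seq,
        cds_start=cds_start,
        appris_tag=tag,
        tpm=tpm,
    )


def make_leader(seq, tid="T1", gid="G1"):
    return Leader(transcript_id=tid, gene_id=gid, sequence=seq)


@pytest.fixture(scope="session")
def small_study():
    """A 300-gene synthetic study shared by stats-level tests."""
    cfg = SimulationConfig(n_genes=300, seed=11)
    return simulate_transcriptome(cfg)


@pytest.fixture(scope="session")
def g4_background(small_study):
    """Per-leader G4 counts/lengths for the small synthetic catalog."""
    from leaderscan.catalog import build_catalog
    from leaderscan.g4 import scan_leader

    _, leaders = build_catalog(small_study.records)
    rows = []
    for ld in leaders:
        if not ld.usable:
            continue
        g_regions, _ = scan_leader(ld.sequence, ld.transcript_id)
        rows.append(
            {
                "transcript_id": ld.transcript_id,
                "g4_count": len(g_regions),
                "length": ld.length,
            }
        )
    return pd.DataFrame(rows)
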