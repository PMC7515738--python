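"""Transcript catalog: representative-isoform selection and 5' leader extraction.

Builds a one-transcript-per-gene catalog from a transcript-level FASTA plus
a GTF annotation carrying per-transcript CDS coordinates (transcript space),
an APPRIS principal-isoform table, and an RNA-seq TPM table.  The
representative for each gene is the APPRIS principal isoform; among several
principals the one with the highest TPM wins.  The 5' leader is the
transcript sequence upstream of the annotated CDS start.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VERSION_RE = re.compile(r"\.\d+$")

APPRIS_PRINCIPAL = "PRINCIPAL"
APPRIS_ALTERNATIVE = "ALTERNATIVE"
APPRIS_NONE = "NONE"

#: leaders with more than this fraction of N are flagged LOW_QUALITY
MAX_N_FRACTION = 0.10


def strip_version(identifier: str) -> str:
    """Drop a trailing ``.N`` version suffix from a Gencode-style id."""
    return _VERSION_RE.sub("", identifier)


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: sequence, CDS start, APPRIS tag and expression.

    ``cds_start`` is the 1-based position of the first CDS base on the
    transcript, or ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int | None
    appris_tag: str = APPRIS_NONE
    tpm: float = 0.0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set("ACGTUN"):
            bad = sorted(set(seq) - set("ACGTUN"))
            raise ValueError(
                f"{self.transcript_id}: non-nucleotide characters {bad}"
            )
        if self.cds_start is not None and not (1 <= self.cds_start <= len(seq)):
            raise ValueError(
                f"{self.transcript_id}: cds_start {self.cds_start} outside "
                f"[1, {len(seq)}]"
            )
        if self.tpm < 0:
            raise ValueError(f"{self.transcript_id}: negative TPM {self.tpm}")
        if self.appris_tag not in (APPRIS_PRINCIPAL, APPRIS_ALTERNATIVE, APPRIS_NONE):
            raise ValueError(f"unknown APPRIS tag {self.appris_tag!r}")


@dataclass(frozen=True)
class Leader:
    """A 5' leader: transcript 5' end up to the base preceding the CDS."""

    transcript_id: str
    gene_id: str
    sequence: str
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def usable(self) -> bool:
        """Whether this leader enters feature-group statistics."""
        return self.length > 0 and not (
            self.flags & {"NON_CODING", "LOW_QUALITY"}
        )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as handle:
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            # Gencode headers join several ids with '|'; the first is the
            # transcript id.
            tid = rec.id.split("|")[0]
            seqs[tid] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def _read_cds_starts(gtf_path: str | Path) -> dict[str, tuple[str, int]]:
    """Map transcript id (version-stripped) -> (gene_id, 1-based CDS start).

    The annotation is consumed in transcript coordinates: each CDS feature's
    ``start`` is the position of the first coding base on its transcript.
    Multiple CDS features per transcript are collapsed to the minimum start.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    out: dict[str, tuple[str, int]] = {}
    for feat in db.features_of_type("CDS"):
        tid = strip_version(feat.attributes["transcript_id"][0])
        gid = strip_version(feat.attributes["gene_id"][0])
        start = int(feat.start)  # gffutils keeps GTF 1-based inclusive
        if tid not in out or start < out[tid][1]:
            out[tid] = (gid, start)
    return out


def _read_two_column_tsv(path: str | Path, value_col: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns or value_col not in df.columns:
        raise ValueError(
            f"{path}: expected columns 'transcript_id' and '{value_col}', "
            f"found {list(df.columns)}"
        )
    key = df["transcript_id"].map(strip_version)
    return pd.Series(df[value_col].values, index=key)


def _normalize_appris(tag: str) -> str:
    tag = str(tag).upper()
    if "PRINCIPAL" in tag:
        return APPRIS_PRINCIPAL
    if "ALTERNATIVE" in tag:
        return APPRIS_ALTERNATIVE
    return APPRIS_NONE


def load_catalog(
    fasta_path: str | Path,
    gtf_path: str | Path,
    appris_path: str | Path | None = None,
    tpm_path: str | Path | None = None,
) -> tuple[list[TranscriptRecord], dict[str, int]]:
    """Join FASTA sequences with annotation, APPRIS tags and TPM values.

    Ids are matched after stripping ``.N`` version suffixes.  Transcripts
    present in the FASTA but absent from the annotation (or vice versa) are
    dropped with a warning.  Returns the records plus a count report with
    keys ``n_fasta``, ``n_annotated``, ``n_matched``, ``n_dropped``.

    Raises ``OSError`` for unreadable files and ``ValueError`` when the two
    inputs share no transcript id at all.
    """
    seqs = _read_fasta(fasta_path)
    cds = _read_cds_starts(gtf_path)
    appris = (
        _read_two_column_tsv(appris_path, "tag").map(_normalize_appris)
        if appris_path is not None
        else pd.Series(dtype=object)
    )
    tpm = (
        _read_two_column_tsv(tpm_path, "tpm").astype(float)
        if tpm_path is not None
        else pd.Series(dtype=float)
    )

    records: list[TranscriptRecord] = []
    dropped = 0
    for raw_tid, seq in seqs.items():
        tid = strip_version(raw_tid)
        if tid not in cds:
            logger.warning("transcript %s has no annotation; dropped", raw_tid)
            dropped += 1
            continue
        gid, cds_start = cds[tid]
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=gid,
                sequence=seq,
                cds_start=cds_start,
                appris_tag=appris.get(tid, APPRIS_NONE),
                tpm=float(tpm.get(tid, 0.0)),
            )
        )
    if not records:
        raise ValueError(
            f"no transcript id shared between {fasta_path} and {gtf_path}"
        )
    report = {
        "n_fasta": len(seqs),
        "n_annotated": len(cds),
        "n_matched": len(records),
        "n_dropped": dropped,
    }
    return records, report


def select_representative(records: Sequence[TranscriptRecord]) -> str:
    """Pick the representative transcript id for one gene.

    A single APPRIS principal isoform wins outright; among several
    principals the highest TPM wins.  Genes without any principal fall back
    to highest TPM.  All remaining ties break on the lexicographically
    smaller transcript id, so the choice is independent of input order.
    """
    if not records:
        raise ValueError("select_representative needs at least one record")
    principals = [r for r in records if r.appris_tag == APPRIS_PRINCIPAL]
    pool = principals if principals else list(records)
    best = min(pool, key=lambda r: (-r.tpm, r.transcript_id))
    return best.transcript_id


def extract_leader(record: TranscriptRecord) -> Leader:
    """Cut the 5' leader: bases 1 .. cds_start-1 of the transcript.

    Non-coding transcripts yield an empty leader flagged ``NON_CODING``;
    a CDS starting at position 1 yields an empty leader flagged ``EMPTY``;
    leaders with more than 10% N are flagged ``LOW_QUALITY`` and excluded
    from feature statistics downstream.
    """
    flags: set[str] = set()
    if record.cds_start is None:
        return Leader(record.transcript_id, record.gene_id, "", frozenset({"NON_CODING"}))
    seq = record.sequence[: record.cds_start - 1]
    if not seq:
        flags.add("EMPTY")
    elif seq.count("N") / len(seq) > MAX_N_FRACTION:
        flags.add("LOW_QUALITY")
    return Leader(record.transcript_id, record.gene_id, seq, frozenset(flags))


def build_catalog(
    records: Iterable[TranscriptRecord],
) -> tuple[dict[str, str], list[Leader]]:
    """Group records by gene, pick representatives, and extract leaders.

    Returns (gene_id -> representative transcript_id, leaders for the
    representatives, in gene-id order).
    """
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    representatives: dict[str, str] = {}
    leaders: list[Leader] = []
    for gid in sorted(by_gene):
        tid = select_representative(by_gene[gid])
        representatives[gid] = tid
        rec = next(r for r in by_gene[gid] if r.transcript_id == tid)
        leaders.append(extract_leader(rec))
    return representatives, leaders


def write_leaders_fasta(leaders: Iterable[Leader], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ld in leaders:
            if ld.length == 0:
                continue
            fh.write(f">{ld.transcript_id} gene={ld.gene_id}\n{ld.sequence}\n")


def read_leaders_fasta(path: str | Path) -> list[Leader]:
    leaders = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            gene = ""
            for part in rec.description.split():
                if part.startswith("gene="):
                    gene = part[5:]
            leaders.append(Leader(rec.id, gene, str(rec.seq).upper()))
    return leaders


def write_catalog_tsv(
    representatives: Mapping[str, str],
    leaders: Iterable[Leader],
    path: str | Path,
) -> None:
    rows = [
        {
            "gene_id": ld.gene_id,
            "transcript_id": ld.transcript_id,
            "leader_length": ld.length,
            "flags": ",".join(sorted(ld.flags)) or ".",
        }
        for ld in leaders
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
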