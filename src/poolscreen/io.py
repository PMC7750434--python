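"""Readers and writers for the interchange formats of the pipeline.

FASTA/FASTQ through Biopython SeqIO (wrapped or unwrapped records, LF or
CRLF, identifiers preserved verbatim); tables as TSV through pandas;
manifests and summaries as JSON with sorted keys (byte-stable output).
All intervals in interchange files are 1-based inclusive; well addresses
use the canonical ``P##R##`` style.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import PoolAssignment, PoolId
from .match import Contig
from .mining import ClusterAnnotation
from .simulate import ReadPair


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqrecords = (
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    )
    SeqIO.write(seqrecords, str(path), "fasta")


def contigs_to_fasta(contigs: Iterable[Contig], path: str | Path) -> None:
    write_fasta(((c.id, c.sequence) for c in contigs), path)


def contigs_from_fasta(path: str | Path) -> list[Contig]:
    """Load contigs, recovering each pool of origin from the id prefix."""
    out = []
    for rid, seq in read_fasta(path):
        pool = PoolId.from_tag(rid.split("|")[0])
        out.append(Contig(id=rid, pool=pool, sequence=seq))
    return out


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    def _rec(rid: str, seq: str, qual: tuple[int, ...]) -> SeqRecord:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = list(qual)
        return rec

    pairs = list(pairs)
    SeqIO.write((_rec(p.id + "/1", p.seq1, p.qual1) for p in pairs), str(r1_path), "fastq")
    SeqIO.write((_rec(p.id + "/2", p.seq2, p.qual2) for p in pairs), str(r2_path), "fastq")


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    return [
        (rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    # round_trip float parsing keeps write->read->write byte-stable
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def hits_to_frame(hits: Iterable) -> pd.DataFrame:
    """Tabular hit layout: query, subject, %identity, lengths, coordinates."""
    rows = [
        {
            "query_id": h.query_id,
            "subject_id": h.subject_id,
            "subject_dimension": h.subject_dimension,
            "identity": round(h.identity, 3),
            "aln_len": h.aln_len,
            "mismatches": h.mismatches,
            "gaps": h.gaps,
            "qstart": h.qstart,
            "qend": h.qend,
            "sstart": h.sstart,
            "send": h.send,
            "strand": h.strand,
            "score": h.score,
            "evalue": h.evalue,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "subject_id",
            "subject_dimension",
            "identity",
            "aln_len",
            "mismatches",
            "gaps",
            "qstart",
            "qend",
            "sstart",
            "send",
            "strand",
            "score",
            "evalue",
        ],
    )


def annotations_to_frame(annotations: Iterable[ClusterAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "contig_id": a.contig_id,
            "start": a.start,
            "end": a.end,
            "class_label": a.class_label,
            "strand": a.strand,
            "orf_index": i,
            "domain_tokens": ";".join(orf),
        }
        for a in annotations
        for i, orf in enumerate(a.orfs)
    ]
    return pd.DataFrame(
        rows,
        columns=["contig_id", "start", "end", "class_label", "strand", "orf_index", "domain_tokens"],
    )


def annotations_from_frame(frame: pd.DataFrame) -> list[ClusterAnnotation]:
    out = []
    for (cid, start, end, cls, strand), grp in frame.groupby(
        ["contig_id", "start", "end", "class_label", "strand"], sort=True
    ):
        orfs = tuple(
            tuple(str(t) for t in str(row.domain_tokens).split(";") if t)
            for row in grp.sort_values("orf_index").itertuples()
        )
        out.append(
            ClusterAnnotation(
                contig_id=str(cid),
                start=int(start),
                end=int(end),
                class_label=str(cls),
                strand=str(strand),
                orfs=orfs,
            )
        )
    return out


def pool_manifest(assignment: PoolAssignment) -> pd.DataFrame:
    rows = [
        {
            "pool_id": pid.tag(),
            "set_index": pid.set_index,
            "dimension": pid.dimension,
            "label": pid.label,
            "n_wells": len(assignment.membership[pid]),
            "wells": ";".join(w.canonical() for w in sorted(assignment.membership[pid])),
        }
        for pid in assignment.pools()
    ]
    return pd.DataFrame(
        rows, columns=["pool_id", "set_index", "dimension", "label", "n_wells", "wells"]
    )


def barcode_map(assignments: Iterable[PoolAssignment]) -> pd.DataFrame:
    """Sequential barcode index per pool (unique within each set)."""
    rows = []
    for assignment in assignments:
        for i, pid in enumerate(assignment.pools(), start=1):
            rows.append(
                {"pool_id": pid.tag(), "set_index": pid.set_index, "barcode_index": i}
            )
    return pd.DataFrame(rows, columns=["pool_id", "set_index", "barcode_index"])


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
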