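"""Readers/writers for the pipeline's on-disk formats.

FASTQ/FASTA go through Biopython; tables are TSV via pandas.  The
translation-table TSV carries one row per star allele:
``allele, core, activity, kind, variants`` with variants as
semicolon-separated HGVS g. strings (``kind`` is ``allele`` or ``deletion``;
the whole-gene deletion allele has no variants).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from amplistar.demux import Read
from amplistar.phasing import HaplogroupConsensus
from amplistar.starcall import TranslationTable, EvidenceFlags
from amplistar.synthetic import StarAlleleDefinition
from amplistar.variants import parse_hgvs


def write_fastq(reads: Iterable[Read], path: str) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quality)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_fastq(path: str) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        reads.append(
            Read(
                id=rec.id,
                sequence=str(rec.seq),
                quality=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_haplogroup_fasta(haplogroups: Iterable[HaplogroupConsensus], path: str) -> None:
    """Headers are ``sample|index|support``."""
    seqs = {f"{h.sample_id}|{h.index}|{h.support}": h.sequence for h in haplogroups}
    write_fasta(seqs, path)


def read_haplogroup_fasta(path: str) -> list[HaplogroupConsensus]:
    out = []
    for name, seq in read_fasta(path).items():
        sample_id, index, support = name.rsplit("|", 2)
        out.append(
            HaplogroupConsensus(
                sample_id=sample_id,
                index=int(index),
                sequence=seq,
                support=int(support),
                member_reads=[f"unrecorded{i}" for i in range(int(support))],
            )
        )
    return out


def write_sample_sheet(barcodes: Mapping[str, str], path: str) -> None:
    pd.DataFrame(
        {"sample_id": list(barcodes), "barcode_seq": list(barcodes.values())}
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["barcode_seq"]))


def write_translation_table(table: TranslationTable, path: str) -> None:
    rows = []
    for a in table.alleles.values():
        rows.append(
            {
                "allele": a.name,
                "core": a.core,
                "activity": a.activity,
                "kind": "deletion" if a.is_deletion else "allele",
                "variants": ";".join(v.hgvs() for v in a.variants),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_translation_table(path: str) -> TranslationTable:
    df = pd.read_csv(path, sep="\t", dtype={"allele": str, "core": str, "variants": str})
    alleles = {}
    for row in df.itertuples(index=False):
        variants = ()
        if isinstance(row.variants, str) and row.variants:
            variants = tuple(parse_hgvs(t) for t in row.variants.split(";"))
        alleles[row.allele] = StarAlleleDefinition(
            name=row.allele,
            core=row.core,
            variants=variants,
            activity=float(row.activity),
            is_deletion=(getattr(row, "kind", "allele") == "deletion"),
        )
    return TranslationTable(alleles)


def write_evidence(evidence: Mapping[str, EvidenceFlags], path: str) -> None:
    pd.DataFrame(
        {
            "sample_id": list(evidence),
            "deletion_assay": [e.deletion_assay for e in evidence.values()],
            "duplication_assay": [e.duplication_assay for e in evidence.values()],
        }
    ).to_csv(path, sep="\t", index=False)


def read_evidence(path: str) -> dict[str, EvidenceFlags]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        row.sample_id: EvidenceFlags(row.deletion_assay, row.duplication_assay)
        for row in df.itertuples(index=False)
    }
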