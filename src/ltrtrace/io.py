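"""File-format helpers: FASTA, BED, GFF3 and the pipeline's TSV artifacts.

All on-disk coordinates are 1-based inclusive (GFF3/TSV) or 0-based half-open
(BED), matching the conventions of those formats; in-memory code uses 0-based
half-open coordinates throughout.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-record) FASTA file into {name: uppercase sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(path, records: dict[str, str], width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    count = SeqIO.write(recs, str(path), "fasta")
    assert count == len(records)


def write_aligned_fasta(path, names: list[str], rows: list[str]) -> None:
    write_fasta(path, dict(zip(names, rows)))


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (chrom, start, end[, name]); coordinates 0-based half-open."""
    df = pd.read_csv(
        str(path), sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"][: 4],
        usecols=[0, 1, 2, 3], engine="python",
    )
    return df


def write_bed(path, rows: list[tuple]) -> None:
    """Write (chrom, start0, end0, name) rows as BED."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def write_tsv(path, df: pd.DataFrame, header_comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", comment="#")


def annotations_to_gff3(annotations, path) -> None:
    """Write element annotations as GFF3: one LTR_retrotransposon feature per
    element with child long_terminal_repeat features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            attrs = [
                f"ID={ann.element_id}",
                f"category={ann.category}",
                f"termini={ann.termini}",
            ]
            if ann.tsd_seq:
                attrs.append(f"tsd={ann.tsd_seq}")
            fh.write(
                "\t".join(
                    [
                        ann.chrom, "ltrtrace", "LTR_retrotransposon",
                        str(ann.start), str(ann.end), ".", ann.strand, ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            for tag, ltr in (("five_prime_LTR", ann.ltr5), ("three_prime_LTR", ann.ltr3)):
                if ltr is None:
                    continue
                fh.write(
                    "\t".join(
                        [
                            ann.chrom, "ltrtrace", "long_terminal_repeat",
                            str(ltr[0]), str(ltr[1]), ".", ann.strand, ".",
                            f"ID={ann.element_id}.{tag};Parent={ann.element_id}",
                        ]
                    )
                    + "\n"
                )


def ensure_artifact(path, producer: str):
    from .errors import MissingArtifactError

    p = Path(path)
    if not p.exists():
        raise MissingArtifactError(p, producer)
    return p
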