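"""Typed readers and writers for the on-disk formats the pipeline touches.

Coordinates are 0-based, end-exclusive throughout, so a gene's length is
simply ``end - start``; GFF3 input (1-based, end-inclusive) is converted
on read. Chromosome "0" is a legal label meaning *unassigned*.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

from Bio import SeqIO

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

_logger = logging.getLogger("genefam")
if not _logger.handlers:  # LEVEL<TAB>stage<TAB>message on stderr
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("%(levelname)s\t%(stage)s\t%(message)s"))
    _logger.addHandler(h)
    _logger.setLevel(logging.INFO)


def log(level: str, stage: str, message: str) -> None:
    _logger.log(getattr(logging, level.upper()), message, extra={"stage": stage})


@dataclass
class SeqRecord:
    """One FASTA record; sequence is upper-case and alphabet-checked."""

    id: str
    description: str
    sequence: str


@dataclass
class GeneModel:
    """A gene: location, strand, exon structure and sequence cross-refs.

    ``start``/``end`` are 0-based end-exclusive; exons are sub-intervals
    of [start, end), sorted and non-overlapping.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_id: str = ""
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.gene_id}: negative start")
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene interval")
            if e <= s:
                raise ValueError(f"{self.gene_id}: degenerate exon ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_alphabet(seq: str, alphabet: str, rec_id: str) -> None:
    allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"record {rec_id}: illegal {alphabet} character {ch!r} at position {pos}")


def read_fasta(path, alphabet: str = "protein") -> list[SeqRecord]:
    """Read FASTA, uppercasing and enforcing the declared alphabet.

    Duplicate ids and illegal characters raise ``ValueError``.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")
    out, seen = [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id}: empty sequence")
        _check_alphabet(seq, alphabet, rec.id)
        out.append(SeqRecord(id=rec.id, description=rec.description, sequence=seq))
    return out


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.description or rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


GENE_TABLE_COLUMNS = ("gene_id", "chromosome", "start", "end", "strand",
                      "exons", "cds_id", "protein_id")


def _format_exons(exons) -> str:
    return ";".join(f"{s}-{e}" for s, e in exons)


def _parse_exons(text: str) -> list[tuple[int, int]]:
    if not text:
        return []
    out = []
    for part in text.split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


def read_gene_table(path) -> list[GeneModel]:
    """Read the TSV gene table (see ``GENE_TABLE_COLUMNS`` header)."""
    genes = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                missing = set(GENE_TABLE_COLUMNS) - set(header)
                if missing:
                    raise ValueError(f"gene table missing columns: {sorted(missing)}")
                continue
            row = dict(zip(header, line.split("\t")))
            genes.append(GeneModel(
                gene_id=row["gene_id"],
                chromosome=row["chromosome"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                exons=_parse_exons(row["exons"]),
                cds_id=row["cds_id"],
                protein_id=row["protein_id"],
            ))
    return genes


def write_gene_table(genes, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write("\t".join([g.gene_id, g.chromosome, str(g.start), str(g.end),
                                g.strand, _format_exons(g.exons), g.cds_id,
                                g.protein_id]) + "\n")


def read_gff3(path) -> list[GeneModel]:
    """Import a GFF3 subset (gene/exon/CDS features) as GeneModels.

    1-based inclusive GFF coordinates become 0-based end-exclusive.
    Exons and CDS are attached to their parent gene by the ``Parent``
    (or ``ID``) attribute.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            s, e = int(start) - 1, int(end)
            if ftype == "gene":
                gid = attr.get("ID", "")
                genes[gid] = {"chromosome": seqid, "start": s, "end": e,
                              "strand": strand, "exons": [], "cds_id": "",
                              "protein_id": ""}
                order.append(gid)
            elif ftype == "exon":
                parent = attr.get("Parent", "")
                if parent in genes:
                    genes[parent]["exons"].append((s, e))
            elif ftype == "CDS":
                parent = attr.get("Parent", "")
                if parent in genes:
                    genes[parent]["cds_id"] = attr.get("ID", genes[parent]["cds_id"])
                    genes[parent]["protein_id"] = attr.get(
                        "protein_id", genes[parent]["protein_id"])
    out = []
    for gid in order:
        d = genes[gid]
        d["exons"].sort()
        out.append(GeneModel(gene_id=gid, **d))
    return out


# Newick I/O lives with the Tree structure; re-exported here because trees
# are one of the pipeline's on-disk formats.
from .tree import read_newick, write_newick  # noqa: E402,F401
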