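"""Promoter extraction and cis-regulatory element counting.

Elements are short IUPAC DNA patterns identified by their database
accessions (e.g. S000415 = ACGTG). Counting is positional: every start
offset is tested, so overlapping occurrences all count, and by default
both strands are scanned (the reverse-complement hits of a palindromic
pattern therefore double-count; forward-only mode is available).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .core_io import GeneModel

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CisElement:
    element_id: str
    pattern: str
    category: str = ""

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"{self.element_id}: empty pattern")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.element_id}: illegal IUPAC letters {sorted(bad)}")


def read_element_library(path) -> list[CisElement]:
    """TSV with columns element_id, pattern, category."""
    out = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            out.append(CisElement(row["element_id"], row["pattern"].upper(),
                                  row.get("category", "")))
    return out


def extract_upstream(gene: GeneModel, contig_seq: str,
                     length: int = 2000) -> tuple[str, bool]:
    """The promoter: ``length`` bases upstream of the transcription start.

    Plus strand: contig[start-length, start); minus strand: the reverse
    complement of contig[end, end+length). Truncated at the contig
    boundary, with the flag set.
    """
    if gene.end > len(contig_seq):
        raise ValueError(f"{gene.gene_id} does not lie on the contig")
    if gene.strand == "+":
        lo = max(0, gene.start - length)
        seq = contig_seq[lo:gene.start]
        truncated = gene.start - length < 0
    else:
        hi = min(len(contig_seq), gene.end + length)
        seq = reverse_complement(contig_seq[gene.end:hi])
        truncated = gene.end + length > len(contig_seq)
    return seq, truncated


def count_matches(seq: str, pattern: str) -> int:
    """Overlapping occurrences of one IUPAC pattern on the given strand."""
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"illegal IUPAC letters in pattern: {sorted(bad)}")
    regex = "".join(IUPAC[ch] for ch in pattern)
    return len(re.findall(f"(?=({regex}))", seq))


def scan_elements(seq: str, elements: list[CisElement],
                  both_strands: bool = True) -> dict[str, int]:
    """Occurrence count per element; forward plus (optionally) reverse-
    complement strand counts summed."""
    counts = {}
    rc = reverse_complement(seq) if both_strands else None
    for el in elements:
        n = count_matches(seq, el.pattern)
        if both_strands:
            n += count_matches(rc, el.pattern)
        counts[el.element_id] = n
    return counts


def scan_promoters(genes: list[GeneModel], contigs: dict[str, str],
                   elements: list[CisElement], length: int = 2000,
                   both_strands: bool = True) -> pd.DataFrame:
    """Per-gene, per-element hit table with a truncation flag."""
    rows = []
    for gene in genes:
        seq, truncated = extract_upstream(gene, contigs[gene.chromosome], length)
        row = {"gene_id": gene.gene_id, "truncated": truncated}
        row.update(scan_elements(seq, elements, both_strands))
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def element_summary(hit_table: pd.DataFrame) -> pd.DataFrame:
    """Totals per element, descending, ties broken by element id."""
    if hit_table.empty:
        raise ValueError("empty hit table")
    cols = [c for c in hit_table.columns if c != "truncated"]
    totals = hit_table[cols].sum()
    out = totals.reset_index()
    out.columns = ["element_id", "total"]
    return out.sort_values(["total", "element_id"],
                           ascending=[False, True]).reset_index(drop=True)
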