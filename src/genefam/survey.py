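"""Family identification and protein characterisation.

Covers the survey half of the pipeline: redundancy reduction of the
candidate protein set, consensus-pattern domain scanning (a transparent
stand-in for a profile-HMM scan; results from an external HMM tool can
be substituted), physico-chemical properties (length, average molecular
weight, isoelectric point), chromosome distribution and intron counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .align import global_align
from .core_io import GeneModel, SeqRecord

# Average (not monoisotopic) residue masses in Da, ProtParam convention.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

# EMBOSS pKa constants: termini plus the seven ionisable side chains.
PKA_EMBOSS = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1,  # acidic (negative above pKa)
    "H": 6.5, "K": 10.8, "R": 12.5,           # basic (positive below pKa)
}


@dataclass
class DomainProfile:
    """IUPAC-like amino-acid consensus; X matches anything."""

    name: str
    consensus: str
    min_score: int

    def __post_init__(self) -> None:
        if len(self.consensus) < 5:
            raise ValueError(f"{self.name}: consensus shorter than 5")
        if self.min_score > len(self.consensus):
            raise ValueError(f"{self.name}: min_score exceeds consensus length")


@dataclass
class DomainHit:
    profile: str
    start: int
    end: int
    matches: int


@dataclass
class ProteinProps:
    protein_id: str
    length_aa: int
    mw_kda: float
    pI: float


def reduce_redundancy(records: list[SeqRecord], identity_cutoff: float = 1.0,
                      ) -> tuple[list[SeqRecord], dict[str, list[str]]]:
    """Greedy redundancy reduction in descending length order.

    A record joins the first kept representative whose global-alignment
    identity with it is at least the cutoff; otherwise it becomes a new
    representative. Output is order-independent given the
    (length desc, id asc) processing order.
    """
    if not 0 < identity_cutoff <= 1:
        raise ValueError("identity cutoff must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    kept: list[SeqRecord] = []
    clusters: dict[str, list[str]] = {}
    for rec in ordered:
        home = None
        for rep in kept:
            if global_align(rep, rec).identity >= identity_cutoff:
                home = rep
                break
        if home is None:
            kept.append(rec)
            clusters[rec.id] = [rec.id]
        else:
            clusters[home.id].append(rec.id)
    return kept, clusters


def scan_domains(protein: SeqRecord, profiles: list[DomainProfile]) -> list[DomainHit]:
    """Sliding-window consensus match count; X in the consensus matches
    anything. Windows reaching ``min_score`` matches are reported, with
    overlapping hits of one profile merged to the best-scoring window
    (leftmost on ties)."""
    seq = protein.sequence
    hits: list[DomainHit] = []
    for prof in profiles:
        L = len(prof.consensus)
        if L > len(seq):
            continue
        raw: list[DomainHit] = []
        for start in range(len(seq) - L + 1):
            matches = sum(1 for a, b in zip(prof.consensus, seq[start:start + L])
                          if a == "X" or a == b)
            if matches >= prof.min_score:
                raw.append(DomainHit(prof.name, start, start + L, matches))
        merged: list[DomainHit] = []
        for hit in raw:  # raw is left-to-right; merge overlapping runs
            if merged and hit.start < merged[-1].end:
                if hit.matches > merged[-1].matches:
                    merged[-1] = hit
            else:
                merged.append(hit)
        hits.extend(merged)
    return hits


def is_family_member(protein: SeqRecord, profiles: list[DomainProfile]) -> bool:
    """Member iff every profile in the family definition hits."""
    found = {h.profile for h in scan_domains(protein, profiles)}
    return all(p.name in found for p in profiles)


def molecular_weight(seq: str) -> float:
    """Average-isotope molecular weight in kDa: residue masses + one water."""
    if not seq:
        raise ValueError("empty sequence has no molecular weight")
    total = WATER_MASS
    for i, aa in enumerate(seq):
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"mass undefined for residue {aa!r} at position {i}") from None
    return total / 1000.0


def _net_charge(seq_counts: Counter, ph: float, pka: dict[str, float]) -> float:
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in ("H", "K", "R"):
        charge += seq_counts[aa] / (1.0 + 10 ** (ph - pka[aa]))
    for aa in ("D", "E", "C", "Y"):
        charge -= seq_counts[aa] / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def isoelectric_point(seq: str, pka: dict[str, float] | None = None,
                      tol: float = 1e-4) -> float:
    """pH of zero net charge by bisection on [0, 14].

    Henderson-Hasselbalch charge model over the termini and the D, E, C,
    Y, H, K, R side chains; composition-only, so the result is invariant
    under permutation of the sequence. Net charge is strictly decreasing
    in pH, so the root exists and is unique.
    """
    if not seq:
        raise ValueError("empty sequence has no isoelectric point")
    pka = PKA_EMBOSS if pka is None else pka
    counts = Counter(seq)
    lo, hi = 0.0, 14.0
    charge = _net_charge(counts, (lo + hi) / 2, pka)
    while abs(charge) >= tol:
        mid = (lo + hi) / 2
        if charge > 0:
            lo = mid
        else:
            hi = mid
        charge = _net_charge(counts, (lo + hi) / 2, pka)
    return (lo + hi) / 2


def protein_properties(protein: SeqRecord) -> ProteinProps:
    return ProteinProps(
        protein_id=protein.id,
        length_aa=len(protein.sequence),
        mw_kda=molecular_weight(protein.sequence),
        pI=isoelectric_point(protein.sequence),
    )


def _round_half_away(x: float) -> int:
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


@dataclass
class ChromosomeDistribution:
    counts: dict[str, int]          # per assigned chromosome label
    percents: dict[str, int]        # nearest-integer % of assigned genes
    unassigned: int                 # chromosome "0" genes, reported apart


def chromosome_distribution(genes: list[GeneModel]) -> ChromosomeDistribution:
    """Counts and whole-number percentages per chromosome.

    Percentages are over the genes with a known chromosome; genes on the
    "0" (unassigned) label are counted separately.
    """
    if not genes:
        raise ValueError("no genes to distribute")
    counts = Counter(g.chromosome for g in genes)
    unassigned = counts.pop("0", 0)
    total = sum(counts.values())
    percents = {chrom: _round_half_away(100.0 * n / total)
                for chrom, n in counts.items()} if total else {}
    return ChromosomeDistribution(counts=dict(counts), percents=percents,
                                  unassigned=unassigned)


def intron_count(gene: GeneModel) -> int:
    if not gene.exons:
        raise ValueError(f"{gene.gene_id}: gene has no exons")
    return len(gene.exons) - 1
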