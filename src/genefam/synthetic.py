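"""Synthetic genomes, duplicated CDS pairs, promoters and Ct tables with
machine-readable ground truth.

The generator emulates the inputs of a genome-wide family survey without
any downloads: a multi-chromosome layout with tandem clusters (members
within the tandem distance cutoff on one chromosome) and segmental
duplicates (on different chromosomes), duplicated CDS pairs evolved at a
chosen dN/dS, promoters whose background is constructed element-free so
planted cis-element counts are exact, and replicate qPCR Ct tables with
planted fold changes and a stable reference gene.

dN/dS is imposed by acceptance-rejection on single-nucleotide proposals
(synonymous proposals always accepted, nonsynonymous with probability
min(omega, 1), stop-creating proposals rejected) rather than a full
codon-model CTMC: transparent and sufficient for estimator-recovery
testing at desk scale. Planted protein domains are frozen during
evolution so membership scanning recovers exactly the planted family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GeneModel, SeqRecord, write_fasta, write_gene_table
from .kaks import SENSE_CODONS, translate_codon
from .promoter import CisElement, reverse_complement, scan_elements
from .survey import DomainProfile, is_family_member

_BASES = "ACGT"

_CODONS_FOR_AA: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _CODONS_FOR_AA.setdefault(translate_codon(_c), []).append(_c)

DEFAULT_PROFILES = [
    DomainProfile("DEXDC", "VLDEADRMLDMGFEPQIRKIV", 19),
    DomainProfile("HELICC", "RGIDVQQVSLVINYDLPTNRE", 19),
]

DEFAULT_ELEMENTS = [
    CisElement("S000415", "ACGTG", "drought"),
    CisElement("S000453", "GAAAAA", "salinity"),
    CisElement("S000030", "CCAAT", "heat"),
]


# ------------------------------------------------------------- sequences

def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_CODONS_FOR_AA)) for _ in range(length))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_CODONS_FOR_AA[aa]) for aa in protein)


def evolve_cds(ancestor: str, omega: float, expected_subs_per_codon: float,
               rng: np.random.Generator,
               frozen_codons: set[int] | None = None) -> tuple[str, int, int]:
    """One descendant of ``ancestor`` under acceptance-rejection dN/dS.

    Proposal events are Poisson with mean ``expected_subs_per_codon`` per
    mutable codon; returns (cds, realized synonymous, realized
    nonsynonymous substitutions).
    """
    frozen = frozen_codons or set()
    n_codons = len(ancestor) // 3
    mutable = [i for i in range(n_codons) if i not in frozen]
    codons = [ancestor[3 * i:3 * i + 3] for i in range(n_codons)]
    n_events = rng.poisson(expected_subs_per_codon * len(mutable)) if mutable else 0
    syn = nonsyn = 0
    for _ in range(n_events):
        ci = mutable[rng.integers(len(mutable))]
        pos = int(rng.integers(3))
        old = codons[ci]
        base = _BASES[int(rng.integers(4))]
        if base == old[pos]:
            continue
        new = old[:pos] + base + old[pos + 1:]
        if translate_codon(new) == "*":
            continue  # stop codons are never created
        if translate_codon(new) == translate_codon(old):
            codons[ci] = new
            syn += 1
        elif rng.random() < min(omega, 1.0):
            codons[ci] = new
            nonsyn += 1
    return "".join(codons), syn, nonsyn


@dataclass
class CodonPairResult:
    cds_a: str
    cds_b: str
    syn_subs: int      # realized synonymous substitutions, both lineages
    nonsyn_subs: int


def simulate_codon_pair(n_codons: int, omega: float,
                        expected_subs_per_codon: float,
                        seed: int) -> CodonPairResult:
    """Two descendant CDS evolved independently from a uniform-sense-codon
    ancestor; exercises the Ka/Ks estimator."""
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10 (too short for estimation)")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    rng = np.random.default_rng(seed)
    ancestor = "".join(SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
                       for _ in range(n_codons))
    cds_a, syn_a, nonsyn_a = evolve_cds(ancestor, omega, expected_subs_per_codon, rng)
    cds_b, syn_b, nonsyn_b = evolve_cds(ancestor, omega, expected_subs_per_codon, rng)
    return CodonPairResult(cds_a=cds_a, cds_b=cds_b,
                           syn_subs=syn_a + syn_b, nonsyn_subs=nonsyn_a + nonsyn_b)


# ------------------------------------------------------------- promoters

def element_free_dna(rng: np.random.Generator, length: int,
                     elements: list[CisElement]) -> str:
    """Random DNA containing zero occurrences of any library element on
    either strand, built left-to-right with suffix repair."""
    max_len = max(len(e.pattern) for e in elements) if elements else 1
    out: list[str] = []

    def suffix_clean() -> bool:
        tail = "".join(out[-2 * max_len:])
        window = tail[-(2 * max_len):]
        return not any(
            scan_elements(window, [e], both_strands=True)[e.element_id]
            for e in elements)

    while len(out) < length:
        out.append(_BASES[int(rng.integers(4))])
        tries = 0
        while not suffix_clean():
            out[-1] = _BASES[int(rng.integers(4))]
            tries += 1
            if tries > 12:  # rare livelock: back up a step
                out.pop()
                if out:
                    out.pop()
                break
    return "".join(out[:length])


def plant_elements(background: str, planted: dict[str, int],
                   elements: list[CisElement], rng: np.random.Generator,
                   max_tries: int = 50) -> tuple[str, dict[int, str]]:
    """Insert exactly the requested element copies into an element-free
    background; re-draws positions until a both-strand scan of the result
    equals the planted counts exactly."""
    lib = {e.element_id: e for e in elements}
    for _ in range(max_tries):
        seq = list(background)
        positions: dict[int, str] = {}
        ok = True
        for el_id, count in planted.items():
            pattern = lib[el_id].pattern
            for _c in range(count):
                placed = False
                for _t in range(200):
                    pos = int(rng.integers(0, len(seq) - len(pattern)))
                    overlap = any(
                        pos < q + len(lib[e].pattern) and q < pos + len(pattern)
                        for q, e in positions.items())
                    if not overlap:
                        seq[pos:pos + len(pattern)] = list(pattern)
                        positions[pos] = el_id
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        result = "".join(seq)
        counts = scan_elements(result, elements, both_strands=True)
        expected = {e.element_id: planted.get(e.element_id, 0) for e in elements}
        if counts == expected:
            return result, positions
    raise RuntimeError("could not plant elements without junction artefacts")


# ---------------------------------------------------------------- family

@dataclass
class FamilyConfig:
    """Layout and evolutionary parameters of the synthetic family."""

    n_chromosomes: int = 4
    chromosome_length: int = 120_000
    n_tandem_clusters: int = 2
    tandem_cluster_size: int = 3
    n_segmental_pairs: int = 2
    n_decoys: int = 3
    protein_length: int = 220
    omega: float = 0.2
    subs_per_codon: float = 0.04
    tandem_spacing: int = 3_000
    upstream_length: int = 2_000
    profiles: list[DomainProfile] = field(default_factory=lambda: list(DEFAULT_PROFILES))
    elements: list[CisElement] = field(default_factory=lambda: list(DEFAULT_ELEMENTS))
    max_planted_per_element: int = 3


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    pair_truth: list[dict]                      # gene_a, gene_b, true_class, true_omega, syn/nonsyn subs
    element_truth: dict[str, dict[str, int]]    # gene -> element -> planted count
    expression_truth: dict[str, dict[str, float]]  # gene -> condition label -> fold change
    seed: int


@dataclass
class FamilyData:
    chromosomes: dict[str, str]
    genes: list[GeneModel]
    proteins: list[SeqRecord]
    cds: list[SeqRecord]
    truth: SyntheticTruth


def _make_member_protein(cfg: FamilyConfig, rng: np.random.Generator
                         ) -> tuple[str, set[int]]:
    """Random protein with every profile consensus embedded; returns the
    protein and the frozen codon indices covering the domains."""
    total_dom = sum(len(p.consensus) for p in cfg.profiles)
    spare = cfg.protein_length - total_dom
    if spare < len(cfg.profiles) + 1:
        raise ValueError("protein_length too short for the domain layout")
    gaps = len(cfg.profiles) + 1
    cuts = sorted(rng.integers(1, spare, size=gaps - 1).tolist())
    seg_lens = [c for c in np.diff([0] + cuts + [spare])]
    parts, frozen = [], set()
    offset = 0
    for i, prof in enumerate(cfg.profiles):
        filler = random_protein(rng, int(seg_lens[i]))
        parts.append(filler)
        offset += len(filler)
        frozen.update(range(offset, offset + len(prof.consensus)))
        parts.append(prof.consensus)
        offset += len(prof.consensus)
    parts.append(random_protein(rng, int(seg_lens[-1])))
    return "".join(parts), frozen


def _make_decoy(cfg: FamilyConfig, rng: np.random.Generator) -> str:
    while True:
        candidate = random_protein(rng, cfg.protein_length)
        rec = SeqRecord("decoy", "decoy", candidate)
        if not is_family_member(rec, cfg.profiles):
            return candidate


def simulate_family(cfg: FamilyConfig, seed: int) -> FamilyData:
    """Generate the synthetic family, genome and truth file.

    Tandem-cluster members sit within the tandem cutoff on one
    chromosome; segmental partners go to different chromosomes. Every
    family member's protein contains the planted domain consensus;
    decoys lack it. Promoter backgrounds are element-free by
    construction, then exactly the planted element copies are inserted.
    """
    rng = np.random.default_rng(seed)
    gene_size = 3 * cfg.protein_length + 400  # coding + intron padding
    slot = cfg.upstream_length + gene_size + cfg.tandem_spacing

    # ---- plan gene placement
    placements: list[dict] = []   # chromosome, start, kind, group
    cursors = {str(c + 1): 2_500 for c in range(cfg.n_chromosomes)}

    def place(chrom: str, kind: str, group: int) -> dict:
        start = cursors[chrom] + cfg.upstream_length
        if start + gene_size + cfg.upstream_length > cfg.chromosome_length:
            raise ValueError("planted layout does not fit the chromosome lengths")
        cursors[chrom] = start + gene_size + cfg.tandem_spacing
        p = {"chromosome": chrom, "start": start, "kind": kind, "group": group}
        placements.append(p)
        return p

    chrom_cycle = [str(c + 1) for c in range(cfg.n_chromosomes)]
    for t in range(cfg.n_tandem_clusters):
        chrom = chrom_cycle[t % cfg.n_chromosomes]
        for _m in range(cfg.tandem_cluster_size):
            place(chrom, "tandem", t)
    for s in range(cfg.n_segmental_pairs):
        c1 = chrom_cycle[s % cfg.n_chromosomes]
        c2 = chrom_cycle[(s + 1) % cfg.n_chromosomes]
        if c1 == c2:
            raise ValueError("need >= 2 chromosomes for segmental pairs")
        place(c1, "segmental", cfg.n_tandem_clusters + s)
        place(c2, "segmental", cfg.n_tandem_clusters + s)
    for d in range(cfg.n_decoys):
        place(chrom_cycle[d % cfg.n_chromosomes], "decoy", -1)

    # ---- sequences per group (shared ancestor within a group)
    genes: list[GeneModel] = []
    proteins: list[SeqRecord] = []
    cds_records: list[SeqRecord] = []
    pair_truth: list[dict] = []
    realized: dict[str, tuple[int, int]] = {}
    by_group: dict[int, list[int]] = {}
    for idx, p in enumerate(placements):
        by_group.setdefault(p["group"] if p["kind"] != "decoy" else -(idx + 100),
                            []).append(idx)

    gene_ids = {}
    counter = 0
    for group, members in sorted(by_group.items()):
        if placements[members[0]]["kind"] == "decoy":
            counter += 1
            gid = f"GF{counter:03d}"
            gene_ids[members[0]] = gid
            protein = _make_decoy(cfg, rng)
            cds = reverse_translate(protein, rng)
            proteins.append(SeqRecord(gid + "_P", gid + "_P", protein))
            cds_records.append(SeqRecord(gid + "_C", gid + "_C", cds))
            realized[gid] = (0, 0)
            continue
        ancestor_prot, frozen = _make_member_protein(cfg, rng)
        ancestor_cds = reverse_translate(ancestor_prot, rng)
        descendants = []
        for m in members:
            counter += 1
            gid = f"GF{counter:03d}"
            gene_ids[m] = gid
            cds, syn, nonsyn = evolve_cds(ancestor_cds, cfg.omega,
                                          cfg.subs_per_codon, rng, frozen)
            protein = "".join(translate_codon(cds[3 * i:3 * i + 3])
                              for i in range(len(cds) // 3))
            proteins.append(SeqRecord(gid + "_P", gid + "_P", protein))
            cds_records.append(SeqRecord(gid + "_C", gid + "_C", cds))
            realized[gid] = (syn, nonsyn)
            descendants.append(gid)
        kind = placements[members[0]]["kind"]
        for i in range(len(descendants)):
            for j in range(i + 1, len(descendants)):
                a, b = sorted((descendants[i], descendants[j]))
                pair_truth.append({
                    "gene_a": a, "gene_b": b, "true_class": kind,
                    "true_omega": cfg.omega,
                    "syn_subs": realized[a][0] + realized[b][0],
                    "nonsyn_subs": realized[a][1] + realized[b][1],
                })

    # ---- gene models with exon structure
    for idx, p in enumerate(placements):
        gid = gene_ids[idx]
        cds_len = 3 * cfg.protein_length
        n_exons = int(rng.integers(1, 5))
        strand = "+" if rng.random() < 0.5 else "-"
        start = p["start"]
        end = start + gene_size
        bounds = sorted(rng.choice(np.arange(1, cds_len), size=n_exons - 1,
                                   replace=False).tolist()) if n_exons > 1 else []
        pieces = np.diff([0] + bounds + [cds_len])
        intron = (gene_size - cds_len) // max(1, n_exons - 1) if n_exons > 1 else 0
        exons, cursor = [], start
        for k, piece in enumerate(pieces):
            exons.append((cursor, cursor + int(piece)))
            cursor += int(piece) + (intron if k < n_exons - 1 else 0)
        genes.append(GeneModel(
            gene_id=gid, chromosome=p["chromosome"], start=start, end=end,
            strand=strand, exons=exons, cds_id=gid + "_C", protein_id=gid + "_P"))

    # ---- genome: random background, element-free promoters, planted copies
    chromosomes = {}
    for c in range(cfg.n_chromosomes):
        name = str(c + 1)
        arr = rng.integers(0, 4, size=cfg.chromosome_length)
        chromosomes[name] = "".join(_BASES[i] for i in arr)

    element_truth: dict[str, dict[str, int]] = {}
    for gene in genes:
        planted = {e.element_id: int(rng.integers(0, cfg.max_planted_per_element + 1))
                   for e in cfg.elements}
        element_truth[gene.gene_id] = planted
        background = element_free_dna(rng, cfg.upstream_length, cfg.elements)
        window, _pos = plant_elements(background, planted, cfg.elements, rng)
        contig = chromosomes[gene.chromosome]
        if gene.strand == "+":
            lo = gene.start - cfg.upstream_length
            chromosomes[gene.chromosome] = contig[:lo] + window + contig[gene.start:]
        else:
            # upstream of a minus-strand gene is downstream in contig
            # coordinates; store the reverse complement so the extracted
            # (reverse-complemented) promoter equals the planted window.
            hi = gene.end + cfg.upstream_length
            chromosomes[gene.chromosome] = (contig[:gene.end]
                                            + reverse_complement(window)
                                            + contig[hi:])

    # ---- planted expression truth for the family members
    conditions = ["drought/60", "drought/30", "salt/100", "salt/200"]
    expression_truth = {}
    member_ids = sorted({p["gene_a"] for p in pair_truth}
                        | {p["gene_b"] for p in pair_truth})
    for gid in member_ids:
        expression_truth[gid] = {
            cond: float(np.round(2.0 ** rng.uniform(-2, 2), 3))
            for cond in conditions}

    truth = SyntheticTruth(pair_truth=pair_truth, element_truth=element_truth,
                           expression_truth=expression_truth, seed=seed)
    return FamilyData(chromosomes=chromosomes, genes=genes, proteins=proteins,
                      cds=cds_records, truth=truth)


def write_family(data: FamilyData, outdir) -> None:
    """Emit genome FASTA, gene table, protein/CDS FASTA and truth TSVs."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([SeqRecord(n, n, s) for n, s in sorted(data.chromosomes.items())],
                outdir / "genome.fasta")
    write_gene_table(data.genes, outdir / "genes.tsv")
    write_fasta(data.proteins, outdir / "proteins.fasta")
    write_fasta(data.cds, outdir / "cds.fasta")
    with open(outdir / "truth_pairs.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\ttrue_class\ttrue_omega\tsyn_subs\tnonsyn_subs\n")
        for p in data.truth.pair_truth:
            fh.write(f"{p['gene_a']}\t{p['gene_b']}\t{p['true_class']}"
                     f"\t{p['true_omega']}\t{p['syn_subs']}\t{p['nonsyn_subs']}\n")
    with open(outdir / "truth_elements.tsv", "w") as fh:
        fh.write("gene_id\telement_id\tcount\n")
        for gid, counts in sorted(data.truth.element_truth.items()):
            for el, n in sorted(counts.items()):
                fh.write(f"{gid}\t{el}\t{n}\n")
    with open(outdir / "truth_expression.tsv", "w") as fh:
        fh.write("gene\tcondition\tfold_change\n")
        for gid, conds in sorted(data.truth.expression_truth.items()):
            for cond, fc in sorted(conds.items()):
                fh.write(f"{gid}\t{cond}\t{fc}\n")
    with open(outdir / "truth_seed.txt", "w") as fh:
        fh.write(str(data.truth.seed) + "\n")


# --------------------------------------------------------------- qPCR Ct

@dataclass
class CtDesign:
    """Conditions of one stress series; exactly one level is the control."""

    stress: str
    levels: list[str]
    control_level: str

    def __post_init__(self) -> None:
        if self.control_level not in self.levels:
            raise ValueError(f"control level {self.control_level!r} not in levels")


def simulate_ct_table(designs: list[CtDesign],
                      true_fc: dict[str, dict[tuple[str, str], float]],
                      ref_gene: str = "Actin7", noise_sd: float = 0.2,
                      n_reps: int = 3, seed: int = 0,
                      cultivar: str = "cv1", tissue: str = "leaf",
                      ref_ct: float = 15.0,
                      target_base_ct: float = 22.0) -> pd.DataFrame:
    """Replicate Ct observations with planted fold changes.

    The reference gene's Ct is constant in expectation across conditions;
    a target's treated Ct is its control Ct minus log2(fold change), plus
    Gaussian noise per replicate.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not designs:
        raise ValueError("no stress designs given")
    rng = np.random.default_rng(seed)
    rows = []
    for design in designs:
        for gene, fcs in true_fc.items():
            for level in design.levels:
                if level == design.control_level:
                    shift = 0.0
                else:
                    fc = fcs.get((design.stress, level), 1.0)
                    if fc <= 0:
                        raise ValueError(f"fold change must be positive ({gene})")
                    shift = -np.log2(fc)
                for rep in range(1, n_reps + 1):
                    rows.append({
                        "gene": gene, "cultivar": cultivar, "tissue": tissue,
                        "stress": design.stress, "level": level,
                        "is_control": level == design.control_level,
                        "replicate": rep,
                        "ct": target_base_ct + shift
                        + (rng.normal(0, noise_sd) if noise_sd else 0.0),
                    })
        for level in design.levels:
            for rep in range(1, n_reps + 1):
                rows.append({
                    "gene": ref_gene, "cultivar": cultivar, "tissue": tissue,
                    "stress": design.stress, "level": level,
                    "is_control": level == design.control_level,
                    "replicate": rep,
                    "ct": ref_ct + (rng.normal(0, noise_sd) if noise_sd else 0.0),
                })
    return pd.DataFrame(rows)
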