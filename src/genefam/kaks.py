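"""Paralog calling, tandem/segmental classification, Nei-Gojobori Ka/Ks
and molecular-clock divergence dating.

The Ka/Ks estimator is Nei & Gojobori's (1986) counting method with the
Jukes-Cantor correction: each codon contributes synonymous and
nonsynonymous *sites* via its nine single-nucleotide neighbours (s + n =
3 exactly), and each differing codon pair contributes *differences*
averaged with equal weight over all minimal mutational pathways that
avoid stop codons. Mutational neighbours that are stop codons count as
nonsynonymous sites; a codon pair whose every pathway passes through a
stop is skipped and logged.

Divergence times follow the molecular clock T = Ks / (2 * lambda) with
lambda the synonymous substitution rate per site per year (default
6.5e-9), reported both in years and in millions of years.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .align import PairwiseAlignment, evalue_proxy, global_align
from .core_io import GeneModel, SeqRecord, log

_BASES = "ACGT"

_STANDARD_CODE = {}


def _build_code():
    from Bio.Data.CodonTable import standard_dna_table
    for codon, aa in standard_dna_table.forward_table.items():
        _STANDARD_CODE[codon] = aa
    for codon in standard_dna_table.stop_codons:
        _STANDARD_CODE[codon] = "*"


_build_code()

SENSE_CODONS = sorted(c for c, aa in _STANDARD_CODE.items() if aa != "*")


def translate_codon(codon: str) -> str:
    try:
        return _STANDARD_CODE[codon]
    except KeyError:
        raise ValueError(f"not a standard-code codon: {codon!r}") from None


def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one sense codon.

    Each of the nine single-nucleotide neighbours contributes 1/3 to the
    synonymous count if it encodes the same amino acid, else (including
    stop neighbours) 1/3 to the nonsynonymous count, so s + n = 3.
    """
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site decomposition")
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1:]
            if translate_codon(neighbour) == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) step counts over all minimal
    stop-free mutational pathways between two sense codons.

    Returns None if every pathway passes through a stop codon.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = nonsyn_total = 0.0
    valid = 0
    for order in itertools.permutations(diff_pos):
        current = codon_a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if translate_codon(nxt) == "*":
                ok = False
                break
            if translate_codon(nxt) == translate_codon(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if ok:
            valid += 1
            syn_total += syn
            nonsyn_total += nonsyn
    if valid == 0:
        return None
    return syn_total / valid, nonsyn_total / valid


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    omega: float | None  # None = undefined (Ks == 0 < Ka)
    n_codons: int
    skipped_codons: int = 0


def _jukes_cantor(p: float, kind: str) -> float:
    if p >= 0.75:
        raise ValueError(f"Jukes-Cantor correction undefined: p{kind} = {p:.4f} >= 3/4")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86_kaks(codon_alignment: list[tuple[str, str]]) -> KaKsResult:
    """Nei-Gojobori Ka/Ks over comparable codon columns.

    ``codon_alignment`` holds (codon_a, codon_b) pairs of sense codons
    (gap and ambiguous columns already excluded, e.g. by
    ``thread_codon_alignment``).
    """
    if not codon_alignment:
        raise ValueError("need at least one comparable codon column")
    S = N = Sd = Nd = 0.0
    used = skipped = 0
    for ca, cb in codon_alignment:
        diffs = pathway_differences(ca, cb)
        if diffs is None:
            skipped += 1
            log("INFO", "kaks", f"codon pair {ca}/{cb} has no stop-free pathway; skipped")
            continue
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += diffs[0]
        Nd += diffs[1]
        used += 1
    if used == 0:
        raise ValueError("no usable codon columns (all pairs stop-blocked)")
    pS, pN = Sd / S, Nd / N
    Ks, Ka = _jukes_cantor(pS, "S"), _jukes_cantor(pN, "N")
    if Ks == 0.0:
        omega = 0.0 if Ka == 0.0 else None
    else:
        omega = Ka / Ks
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
                      omega=omega, n_codons=used, skipped_codons=skipped)


def thread_codon_alignment(aligned_a: str, aligned_b: str,
                           cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Expand a gapped protein alignment to codon columns.

    Each protein column becomes one codon column; columns with a gap on
    either side, an ambiguous base, or a stop codon are excluded from
    the returned comparable pairs. The CDSs must translate to their
    ungapped proteins under the standard code.
    """
    for name, aligned, cds in (("a", aligned_a, cds_a), ("b", aligned_b, cds_b)):
        protein = aligned.replace("-", "")
        if len(cds) != 3 * len(protein):
            raise ValueError(
                f"cds_{name} length {len(cds)} is not 3x protein length {len(protein)}")
        for i, aa in enumerate(protein):
            codon = cds[3 * i:3 * i + 3]
            if set(codon) <= set(_BASES):
                trans = translate_codon(codon)
                if trans != aa and aa != "X":
                    raise ValueError(
                        f"cds_{name} codon {i} ({codon}) translates to {trans}, "
                        f"protein has {aa}")
    pairs: list[tuple[str, str]] = []
    ia = ib = 0
    for col_a, col_b in zip(aligned_a, aligned_b):
        codon_a = cds_a[3 * ia:3 * ia + 3] if col_a != "-" else None
        codon_b = cds_b[3 * ib:3 * ib + 3] if col_b != "-" else None
        if col_a != "-":
            ia += 1
        if col_b != "-":
            ib += 1
        if codon_a is None or codon_b is None:
            continue
        if not (set(codon_a) <= set(_BASES)) or not (set(codon_b) <= set(_BASES)):
            continue
        if translate_codon(codon_a) == "*" or translate_codon(codon_b) == "*":
            continue
        pairs.append((codon_a, codon_b))
    return pairs


def divergence_time(ks: float, clock_rate: float = 6.5e-9) -> tuple[float, float]:
    """Molecular-clock dating: T = Ks / (2 * lambda), in (years, Mya)."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if clock_rate <= 0:
        raise ValueError("clock rate must be positive")
    t_years = ks / (2.0 * clock_rate)
    return t_years, t_years / 1e6


@dataclass
class ParalogPair:
    gene_a: str
    gene_b: str
    identity: float
    evalue: float
    score: float
    dup_class: str | None = None  # tandem | segmental
    kaks: KaKsResult | None = None
    t_years: float | None = None
    t_mya: float | None = None


def call_paralog_pairs(proteins: list[SeqRecord], min_identity: float = 0.80,
                       max_evalue: float = 1e-10, gap_open: float = 10.0,
                       gap_extend: float = 1.0, ka_lambda: float = 0.267,
                       ka_k: float = 0.041) -> list[ParalogPair]:
    """All-vs-all global alignment; keep pairs passing both the identity
    and e-value cutoffs. Each unordered pair appears once, lexicographic."""
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    recs = sorted(proteins, key=lambda r: r.id)
    n_comparisons = len(recs) * (len(recs) - 1) // 2
    pairs = []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            aln = global_align(recs[i], recs[j], gap_open=gap_open,
                               gap_extend=gap_extend)
            ev = evalue_proxy(aln.score, len(recs[i].sequence),
                              len(recs[j].sequence), n_comparisons,
                              ka_lambda, ka_k)
            if aln.identity >= min_identity and ev <= max_evalue:
                pairs.append(ParalogPair(
                    gene_a=recs[i].id, gene_b=recs[j].id,
                    identity=aln.identity, evalue=ev, score=aln.score))
    return pairs


def nearest_edge_distance(a: GeneModel, b: GeneModel) -> int:
    """Gap between two gene intervals on the same chromosome (0 if they
    touch or overlap)."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def classify_duplication(gene_a: GeneModel, gene_b: GeneModel,
                         tandem_cutoff: int = 5_000_000) -> str:
    """Tandem if same (known) chromosome and nearest-edge distance is at
    most the cutoff; otherwise segmental. Pairs on different chromosomes
    or involving an unassigned ("0") location are segmental."""
    same_chrom = (gene_a.chromosome == gene_b.chromosome
                  and gene_a.chromosome != "0")
    if same_chrom and nearest_edge_distance(gene_a, gene_b) <= tandem_cutoff:
        return "tandem"
    return "segmental"


def reciprocal_best_hits(proteome_a: list[SeqRecord],
                         proteome_b: list[SeqRecord],
                         gap_open: float = 10.0,
                         gap_extend: float = 1.0) -> list[tuple[str, str]]:
    """Ortholog pairing: (a, b) kept iff each is the other's best-scoring
    hit; score ties broken lexicographically (and logged)."""
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    scores: dict[tuple[str, str], float] = {}
    for ra in proteome_a:
        for rb in proteome_b:
            scores[(ra.id, rb.id)] = global_align(ra, rb, gap_open=gap_open,
                                                  gap_extend=gap_extend).score

    def best(options: list[tuple[float, str]], who: str) -> str:
        options.sort(key=lambda t: (-t[0], t[1]))
        if len(options) > 1 and options[0][0] == options[1][0]:
            log("INFO", "rbh", f"score tie for {who}; picked {options[0][1]}")
        return options[0][1]

    best_in_b = {ra.id: best([(scores[(ra.id, rb.id)], rb.id) for rb in proteome_b], ra.id)
                 for ra in proteome_a}
    best_in_a = {rb.id: best([(scores[(ra.id, rb.id)], ra.id) for ra in proteome_a], rb.id)
                 for rb in proteome_b}
    return sorted((a, b) for a, b in best_in_b.items() if best_in_a[b] == a)


def analyze_duplications(proteins: list[SeqRecord], cds: list[SeqRecord],
                         genes: list[GeneModel], min_identity: float = 0.80,
                         max_evalue: float = 1e-10,
                         tandem_cutoff: int = 5_000_000,
                         clock_rate: float = 6.5e-9,
                         gap_open: float = 10.0,
                         gap_extend: float = 1.0) -> list[ParalogPair]:
    """Full duplication survey: call pairs, classify, Ka/Ks, date.

    Proteins, CDSs and gene models are joined by the gene table's
    ``protein_id``/``cds_id`` cross-references (falling back to the gene
    id itself).
    """
    prot_by_id = {r.id: r for r in proteins}
    cds_by_id = {r.id: r for r in cds}
    gene_for_prot: dict[str, GeneModel] = {}
    for g in genes:
        gene_for_prot[g.protein_id or g.gene_id] = g
    pairs = call_paralog_pairs(proteins, min_identity, max_evalue,
                               gap_open, gap_extend)
    for pair in pairs:
        ga, gb = gene_for_prot[pair.gene_a], gene_for_prot[pair.gene_b]
        pair.dup_class = classify_duplication(ga, gb, tandem_cutoff)
        aln = global_align(prot_by_id[pair.gene_a], prot_by_id[pair.gene_b],
                           gap_open=gap_open, gap_extend=gap_extend)
        codon_aln = thread_codon_alignment(
            aln.aligned_a, aln.aligned_b,
            cds_by_id[ga.cds_id or ga.gene_id].sequence,
            cds_by_id[gb.cds_id or gb.gene_id].sequence)
        try:
            pair.kaks = ng86_kaks(codon_aln)
        except ValueError as exc:
            log("WARNING", "kaks", f"{pair.gene_a}/{pair.gene_b}: {exc}")
            continue
        pair.t_years, pair.t_mya = divergence_time(pair.kaks.Ks, clock_rate)
    return pairs


PAIR_TABLE_COLUMNS = ("gene_1", "chr_1", "start_1", "end_1", "gene_2", "chr_2",
                      "start_2", "end_2", "evalue", "dup_class", "ka_ks", "ka",
                      "ks", "t_years")


def write_pair_table(pairs: list[ParalogPair], genes: list[GeneModel], path,
                     comment: str | None = None) -> None:
    gene_for_prot = {g.protein_id or g.gene_id: g for g in genes}
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(PAIR_TABLE_COLUMNS) + "\n")
        for p in pairs:
            ga, gb = gene_for_prot[p.gene_a], gene_for_prot[p.gene_b]
            omega = "" if p.kaks is None or p.kaks.omega is None else f"{p.kaks.omega:.4f}"
            ka = "" if p.kaks is None else f"{p.kaks.Ka:.6f}"
            ks = "" if p.kaks is None else f"{p.kaks.Ks:.6f}"
            ty = "" if p.t_years is None else f"{p.t_years:.1f}"
            fh.write("\t".join([
                p.gene_a, ga.chromosome, str(ga.start), str(ga.end),
                p.gene_b, gb.chromosome, str(gb.start), str(gb.end),
                f"{p.evalue:.3g}", p.dup_class or "", omega, ka, ks, ty]) + "\n")
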