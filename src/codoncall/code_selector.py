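"""Automatic selection of the optimal translation table for a genome.

The genome is annotated independently under each candidate code
(default 11, 4, 15) with the same self-training gene caller, and an
alternative code is chosen only when it improves the annotation
decisively on two axes at once: coding density must rise by at least
``density_gain_min`` percentage points over table 11, and median gene
length must rise by a factor of at least ``length_gain_min``.  A genome
genuinely using a reassigned stop fragments badly under table 11 —
genes break at every in-frame occurrence of the repurposed codon — so
true reassignment produces gains far above these margins, while a
standard-code genome shows essentially none.  The decision rule is this
package's own; suppressor-tRNA evidence is reported alongside but never
required, since many reassigned genomes carry no detectable suppressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genetic_codes import get_code
from .metrics import GenomeStats, summarize_genome
from .orf_engine import (
    DEFAULT_MAX_OVERLAP,
    DEFAULT_MIN_LEN,
    DEFAULT_START_BONUS,
    DEFAULT_STARTS,
    DEFAULT_TRAIN_MIN_LEN,
    Gene,
    enumerate_orfs,
    score_candidates,
    select_genes,
    train_composition,
)
from .trna_scan import find_trnas

DEFAULT_TABLES = (11, 4, 15)

# Junction window duplicated when a genome is treated as circular.
CIRCULAR_WINDOW = 3000


@dataclass(frozen=True)
class AnnotationParams:
    """Tunables for the full annotate-and-compare pipeline."""

    min_len: int = DEFAULT_MIN_LEN
    train_min_len: int = DEFAULT_TRAIN_MIN_LEN
    pseudocount: float = 1.0
    max_overlap: int = DEFAULT_MAX_OVERLAP
    starts: tuple[str, ...] = DEFAULT_STARTS
    start_bonus: tuple[tuple[str, float], ...] = tuple(DEFAULT_START_BONUS.items())
    density_gain_min: float = 10.0   # percentage points over table 11
    length_gain_min: float = 1.2     # median-length ratio over table 11
    circular: bool = False


@dataclass
class PerCodeStats:
    n_genes: int
    median_gene_len: float
    coding_density: float
    total_score: float


@dataclass
class CodeComparison:
    genome_id: str
    per_code: dict[int, PerCodeStats]
    chosen_table: int
    decision_reason: str
    trna_support: bool = False
    host_table: int | None = None  # metadata passthrough (e.g. table-4 hosts)
    genes: dict[int, list[Gene]] = field(default_factory=dict, repr=False)
    stats: dict[int, GenomeStats] = field(default_factory=dict, repr=False)


def _as_records(genome) -> list[tuple[str, str]]:
    if isinstance(genome, str):
        return [("contig_1", genome)]
    if isinstance(genome, tuple) and len(genome) == 2:
        return [genome]
    return list(genome)


def annotate_under_code(
    genome,
    table_id: int,
    params: AnnotationParams | None = None,
    genome_id: str = "genome",
) -> tuple[list[Gene], GenomeStats]:
    """Full gene-calling pipeline under one translation table.

    ``genome`` may be a bare sequence, an (id, sequence) pair, or a list
    of such pairs (a multi-record FASTA is treated as one genome).
    Deterministic: enumerate candidate ORFs, self-train the composition
    model per contig, score, and select by dynamic programming.
    """
    params = params or AnnotationParams()
    records = _as_records(genome)
    if not records:
        raise ValueError("empty genome")
    code = get_code(table_id)
    bonus = dict(params.start_bonus)

    all_genes: list[Gene] = []
    total_len = 0
    for contig_id, seq in records:
        total_len += len(seq)
        work_seq = seq
        if params.circular:
            work_seq = seq + seq[: min(CIRCULAR_WINDOW, len(seq))]
        cands = enumerate_orfs(
            work_seq, code, min_len=params.min_len, starts=params.starts,
            contig_id=contig_id,
        )
        if not cands:
            continue
        model = train_composition(
            work_seq, code, train_min_len=params.train_min_len,
            pseudocount=params.pseudocount, starts=params.starts,
            start_bonus=bonus,
        )
        score_candidates(cands, work_seq, model)
        if params.circular:
            # drop pure duplicates living entirely in the appended window
            cands = [c for c in cands if c.start < len(seq)]
        genes = select_genes(
            cands, max_overlap=params.max_overlap, contig=work_seq,
            code=code, id_prefix=contig_id,
        )
        if params.circular:
            seen = set()
            dedup = []
            for g in genes:
                key = (g.start % len(seq), g.end % len(seq), g.strand)
                if key not in seen:
                    seen.add(key)
                    dedup.append(g)
            genes = dedup
        all_genes.extend(genes)

    stats = summarize_genome(all_genes, total_len, genome_id=genome_id)
    return all_genes, stats


def choose_code(
    genome,
    candidate_tables: tuple[int, ...] = DEFAULT_TABLES,
    params: AnnotationParams | None = None,
    genome_id: str = "genome",
    scan_trna: bool = True,
    host_table: int | None = None,
) -> CodeComparison:
    """Annotate under every candidate table and pick the best code.

    Table 11 must be among the candidates and is the conservative
    default: an alternative wins only if it clears both the density and
    the length margin; among several qualifying alternatives the one
    with the highest coding density wins.  Exact ties keep table 11.
    """
    params = params or AnnotationParams()
    if 11 not in candidate_tables:
        raise ValueError("candidate tables must include table 11")
    records = _as_records(genome)

    per_code: dict[int, PerCodeStats] = {}
    genes_by: dict[int, list[Gene]] = {}
    stats_by: dict[int, GenomeStats] = {}
    for t in candidate_tables:
        genes, stats = annotate_under_code(records, t, params, genome_id=genome_id)
        genes_by[t] = genes
        stats_by[t] = stats
        per_code[t] = PerCodeStats(
            n_genes=stats.n_genes,
            median_gene_len=stats.median_gene_len,
            coding_density=stats.coding_density,
            total_score=sum(g.score for g in genes),
        )

    base = per_code[11]
    qualifying: list[tuple[float, int]] = []
    for t in candidate_tables:
        if t == 11:
            continue
        alt = per_code[t]
        gain = alt.coding_density - base.coding_density
        if base.median_gene_len > 0:
            ratio = alt.median_gene_len / base.median_gene_len
        else:
            ratio = float("inf") if alt.median_gene_len > 0 else 1.0
        if gain >= params.density_gain_min and ratio >= params.length_gain_min:
            qualifying.append((alt.coding_density, -t))

    if qualifying:
        density, neg_t = max(qualifying)
        chosen = -neg_t
        alt = per_code[chosen]
        gain = alt.coding_density - base.coding_density
        ratio = (
            alt.median_gene_len / base.median_gene_len
            if base.median_gene_len > 0 else float("inf")
        )
        reason = (
            f"table {chosen}: coding density {alt.coding_density:.1f}% "
            f"(+{gain:.1f} points over table 11, threshold "
            f"{params.density_gain_min:.0f}) and median gene length "
            f"{alt.median_gene_len:.0f} bp ({ratio:.2f}x, threshold "
            f"{params.length_gain_min:.2f}x)"
        )
    else:
        chosen = 11
        reason = (
            "no alternative table cleared both the density and the "
            "length margin; keeping the standard code (table 11)"
        )

    trna_support = False
    if scan_trna and chosen != 11:
        wanted = {15: "amber", 4: "opal"}.get(chosen)
        for contig_id, seq in records:
            if any(
                h.suppressor_class == wanted
                for h in find_trnas(seq, contig_id=contig_id)
            ):
                trna_support = True
                break

    return CodeComparison(
        genome_id=genome_id, per_code=per_code, chosen_table=chosen,
        decision_reason=reason, trna_support=trna_support,
        host_table=host_table, genes=genes_by, stats=stats_by,
    )
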