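"""ORF enumeration, composition scoring and DP gene selection.

Each operation is checked against an independent brute-force oracle
written from the documented semantics: a naive six-frame scanner, a
per-window re-scorer, and exhaustive subset search for gene selection.
"""

import itertools

import numpy as np
import pytest

from codoncall._seq import revcomp
from codoncall.genetic_codes import get_code, translate
from codoncall.orf_engine import (
    OrfCandidate,
    enumerate_orfs,
    score_candidates,
    score_orf,
    select_genes,
    train_composition,
)

from conftest import random_dna


# ---------------------------------------------------------------- oracles

def naive_orf_scan(seq, code, min_len, starts=("ATG", "GTG", "TTG")):
    """Brute-force start->stop ORF scan (complete ORFs only)."""
    found = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, L - 2, 3)]
            last_stop = -1
            for j, c in enumerate(codons):
                if c in code.stop_codons:
                    for k in range(last_stop + 1, j):
                        if codons[k] in starts:
                            a, b = frame + 3 * k, frame + 3 * (j + 1)
                            if b - a >= min_len:
                                if strand == "-":
                                    a, b = L - b, L - a
                                found.add((a, b, strand))
                    last_stop = j
    return found


def brute_force_best(cands, max_overlap):
    """Exhaustive search over all subsets, applying the documented
    semantics: within a stop-anchored family the start is chosen by
    score (then earlier start, then longer), and the chosen genes must
    have pairwise overlap <= max_overlap."""
    def fam(o):
        return (o.strand, o.frame, o.end if o.strand == "+" else o.start)

    by_fam = {}
    for o in cands:
        cur = by_fam.get(fam(o))
        rank = (o.score, -o.start, o.end - o.start)
        if cur is None or rank > (cur.score, -cur.start, cur.end - cur.start):
            by_fam[fam(o)] = o
    pool = list(by_fam.values())

    best = 0.0
    for r in range(1, len(pool) + 1):
        for sub in itertools.combinations(pool, r):
            ok = True
            for a, b in itertools.combinations(sub, 2):
                if min(a.end, b.end) - max(a.start, b.start) > max_overlap:
                    ok = False
                    break
            if ok:
                best = max(best, sum(o.score for o in sub))
    return best


# ------------------------------------------------------------ enumeration

def test_stop_honours_genetic_code():
    seq = "ATGAAATAGAAATAA"
    spans11 = {(o.start, o.end) for o in
               enumerate_orfs(seq, get_code(11), min_len=6) if o.strand == "+"}
    assert (0, 9) in spans11
    spans15 = {(o.start, o.end) for o in
               enumerate_orfs(seq, get_code(15), min_len=6) if o.strand == "+"}
    assert (0, 15) in spans15
    assert not any(e == 9 for _, e in spans15)


def test_minus_strand_protein_matches_revcomp():
    gene = "ATGGCTGAACATAAACGCTTTTGGTAA"
    seq = "CCAC" + revcomp(gene) + "GGT"
    orfs = [o for o in enumerate_orfs(seq, get_code(11), min_len=12)
            if o.strand == "-" and o.has_start and o.has_stop]
    assert any(
        translate(revcomp(seq[o.start:o.end])[:-3], get_code(11))
        == translate(gene[:-3], get_code(11))
        for o in orfs
    )


@pytest.mark.parametrize("table", [11, 15])
def test_enumeration_matches_naive_scanner(table):
    rng = np.random.default_rng(42)
    seq = random_dna(rng, 10000)
    code = get_code(table)
    got = {(o.start, o.end, o.strand)
           for o in enumerate_orfs(seq, code, min_len=90)
           if o.has_start and o.has_stop}
    assert got == naive_orf_scan(seq, code, 90)


def test_short_contig_yields_empty():
    assert enumerate_orfs("ATGAAA", get_code(11), min_len=90) == []


def test_edge_open_orfs_flagged():
    # no stop anywhere: everything is edge-open on the 3' side
    seq = "ATG" + "GCT" * 40
    orfs = enumerate_orfs(seq, get_code(11), min_len=90)
    plus = [o for o in orfs if o.strand == "+" and o.start == 0]
    assert plus and not plus[0].has_stop


def test_determinism():
    rng = np.random.default_rng(3)
    seq = random_dna(rng, 5000)
    a = enumerate_orfs(seq, get_code(11))
    b = enumerate_orfs(seq, get_code(11))
    assert [(o.start, o.end, o.strand) for o in a] == \
           [(o.start, o.end, o.strand) for o in b]


def test_strand_symmetry():
    """Annotating the reverse complement mirrors the ORF set."""
    rng = np.random.default_rng(11)
    seq = random_dna(rng, 4000)
    L = len(seq)
    fwd = {(o.start, o.end, o.strand) for o in enumerate_orfs(seq, get_code(11))}
    rev = {(L - o.end, L - o.start, "+" if o.strand == "-" else "-")
           for o in enumerate_orfs(revcomp(seq), get_code(11))}
    assert fwd == rev


def test_code_monotonicity_small():
    """Removing TAG from the stop set can only lengthen/merge ORFs."""
    rng = np.random.default_rng(5)
    for _ in range(10):
        seq = random_dna(rng, 3000)
        orfs11 = [o for o in enumerate_orfs(seq, get_code(11), min_len=30)]
        orfs15 = enumerate_orfs(seq, get_code(15), min_len=30)
        for o in orfs11:
            assert any(
                p.strand == o.strand and p.frame == o.frame
                and p.start <= o.start and p.end >= o.end
                for p in orfs15
            ), (o.start, o.end, o.strand)


# --------------------------------------------------------------- training

def test_training_on_own_gene_gives_positive_logodds(table15_genome):
    g = table15_genome
    model = train_composition(g.sequence, get_code(15))
    assert model.trained_on > 0
    # mean log-odds over a long truth gene's own dicodons is positive
    gene = max(g.truth_genes, key=lambda t: t.end - t.start)
    sub = g.sequence[gene.start:gene.end]
    if gene.strand == "-":
        sub = revcomp(sub)
    vals = [model.logodds_of(sub[i:i + 6]) for i in range(0, len(sub) - 8, 3)]
    assert np.mean(vals) > 0


def test_training_on_random_sequence_is_uninformative():
    """On unstructured sequence the model should carry little signal."""
    rng = np.random.default_rng(1)
    means = []
    for _ in range(20):
        seq = random_dna(rng, 20000)
        model = train_composition(seq, get_code(11))
        means.append(np.abs(model.hexamer_logodds).mean())
    assert np.mean(means) < 0.5


def test_zero_pseudocount_rejected():
    # one long gene cannot cover all 4096 dicodons, so a zero
    # pseudocount would leave -inf log-odds and must be refused
    rng = np.random.default_rng(2)
    seq = "ATG" + "GATCCTGAAGCAATT" * 30 + "TAA" + random_dna(rng, 500)
    with pytest.raises(ValueError, match="pseudocount"):
        train_composition(seq, get_code(11), pseudocount=0.0)


def test_no_training_orfs_falls_back_to_uniform():
    model = train_composition("ACGT" * 60, get_code(11), train_min_len=3000)
    assert model.trained_on == 0
    assert np.all(model.hexamer_logodds == 0.0)


# ---------------------------------------------------------------- scoring

def test_single_dicodon_score():
    model = train_composition(random_dna(np.random.default_rng(7), 5000),
                              get_code(11))
    seq = "ATGGCTTAA" + "C"
    orf = OrfCandidate("c", 0, 9, "+", 0, True, True, "ATG")
    expected = model.logodds_of("ATGGCT") + model.start_bonus["ATG"]
    assert score_orf(orf, seq, model) == pytest.approx(expected)


def test_vectorised_scoring_agrees_with_rescorer():
    """score_candidates must equal the simple per-window re-scorer."""
    rng = np.random.default_rng(9)
    seq = random_dna(rng, 8000)
    code = get_code(11)
    model = train_composition(seq, code)
    cands = enumerate_orfs(seq, code, min_len=90)[:50]
    score_candidates(cands, seq, model)
    fast = [o.score for o in cands]
    slow = [score_orf(OrfCandidate(o.contig_id, o.start, o.end, o.strand,
                                   o.frame, o.has_start, o.has_stop,
                                   o.start_codon), seq, model)
            for o in cands]
    assert fast == pytest.approx(slow, abs=1e-9)


# -------------------------------------------------------------- selection

def _cand(start, end, score, strand="+", frame=0):
    return OrfCandidate("c", start, end, strand, frame, True, True,
                        "ATG", score)


def test_selection_example_prefers_total_score():
    a = _cand(0, 300, 10.0)
    b = _cand(150, 450, 12.0, frame=0)
    c = _cand(500, 800, 5.0)
    got = select_genes([a, b, c], max_overlap=0)
    assert [(g.start, g.end) for g in got] == [(150, 450), (500, 800)]
    assert sum(g.score for g in got) == pytest.approx(17.0)


def test_non_overlapping_all_kept():
    cands = [_cand(i * 400, i * 400 + 300, 1.0) for i in range(5)]
    assert len(select_genes(cands, max_overlap=0)) == 5


def test_negative_scores_excluded():
    got = select_genes([_cand(0, 90, -1.0), _cand(100, 190, 2.0)])
    assert [(g.start, g.end) for g in got] == [(100, 190)]


def test_dp_matches_exhaustive_search():
    """200 random instances of <= 12 candidates: DP total equals the
    exhaustive-search optimum."""
    rng = np.random.default_rng(123)
    for _ in range(200):
        n = int(rng.integers(1, 13))
        max_overlap = int(rng.choice([0, 15, 30]))
        cands = []
        for k in range(n):
            s = int(rng.integers(0, 300)) * 3
            length = int(rng.integers(max_overlap // 3 + 1, 60)) * 3
            strand = "+" if rng.random() < 0.5 else "-"
            cands.append(
                OrfCandidate("c", s, s + length, strand, s % 3, True, True,
                             "ATG", float(rng.normal(2, 3)))
            )
        got = select_genes(list(cands), max_overlap=max_overlap)
        assert sum(g.score for g in got) == pytest.approx(
            brute_force_best(cands, max_overlap), abs=1e-9
        )


def test_selected_genes_carry_protein(table15_genome):
    g = table15_genome
    code = get_code(15)
    cands = enumerate_orfs(g.sequence, code)
    model = train_composition(g.sequence, code)
    score_candidates(cands, g.sequence, model)
    genes = select_genes(cands, contig=g.sequence, code=code)
    assert genes
    for gene in genes[:5]:
        expected = (gene.end - gene.start) // 3 - (1 if gene.has_stop else 0)
        assert len(gene.protein) == expected
        assert "*" not in gene.protein
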