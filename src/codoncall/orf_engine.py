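"""Code-aware ORF enumeration, composition scoring and gene selection.

The engine is a deliberately simple, self-contained gene caller in the
Prodigal tradition: candidate ORFs are enumerated in all six frames
under a chosen genetic code, scored with a hexamer (in-frame dicodon)
log-odds model trained on the genome itself, and a final non-conflicting
gene set is chosen by exact weighted interval scheduling.  Because the
stop set comes from the genetic code, annotating the same genome under
different translation tables yields directly comparable gene
complements — the contrast that drives code selection.

No ribosome-binding-site model is included; composition plus dynamic
programming is sufficient for measuring the effect of stop-codon
reassignment, which is this package's purpose.

Coordinates are 0-based half-open on the forward strand throughout;
``end - start`` is always divisible by 3 and includes the stop codon
when ``has_stop``.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np

from ._seq import (
    codon_codes,
    codon_to_code,
    encode,
    hexamer_codes,
    hexamer_to_code,
    normalize,
    revcomp,
)
from .genetic_codes import GeneticCode, translate

logger = logging.getLogger(__name__)

DEFAULT_STARTS = ("ATG", "GTG", "TTG")
DEFAULT_START_BONUS = {"ATG": 1.0, "GTG": 0.5, "TTG": 0.25}
DEFAULT_MIN_LEN = 90
DEFAULT_TRAIN_MIN_LEN = 300
DEFAULT_MAX_OVERLAP = 30


@dataclass
class OrfCandidate:
    """A candidate open reading frame.

    ``start``/``end`` are forward-strand 0-based half-open; ``frame`` is
    the reading frame (0..2) on the coding strand.  ``has_start`` /
    ``has_stop`` are False for ORFs running off a contig edge.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    has_start: bool = True
    has_stop: bool = True
    start_codon: str | None = None
    score: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Gene(OrfCandidate):
    gene_id: str = ""
    protein: str = ""


@dataclass
class CompositionModel:
    """Self-trained coding-composition model.

    ``hexamer_logodds`` maps each of the 4096 in-frame dicodons (indexed
    by base-4 code) to log(coding frequency / genome background
    frequency), pseudocounted so every value is finite.
    """

    hexamer_logodds: np.ndarray
    start_bonus: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_START_BONUS)
    )
    trained_on: int = 0

    def logodds_of(self, hexamer: str) -> float:
        return float(self.hexamer_logodds[hexamer_to_code(hexamer)])


def enumerate_orfs(
    contig: str,
    code: GeneticCode,
    min_len: int = DEFAULT_MIN_LEN,
    starts: tuple[str, ...] = DEFAULT_STARTS,
    include_edge: bool = True,
    contig_id: str = "contig",
) -> list[OrfCandidate]:
    """Enumerate ORF candidates in six frames under ``code``.

    For every stop-anchored segment, one candidate is emitted per
    permitted start codon with span length >= ``min_len`` (the span
    includes the stop codon).  With ``include_edge``, ORFs truncated by
    a contig edge (missing start and/or stop) are also emitted, flagged
    accordingly.  Candidates are returned sorted by (start, longest
    first, strand) and the result is fully deterministic.
    """
    seq = normalize(contig)
    L = len(seq)
    if min_len % 3:
        raise ValueError("min_len must be divisible by 3")
    if L < min_len:
        return []

    stop_codes = np.array(sorted(codon_to_code(c) for c in code.stop_codons))
    start_codes = np.array(sorted(codon_to_code(c) for c in starts))
    out: list[OrfCandidate] = []

    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        enc = encode(s)
        for frame in range(3):
            codes = codon_codes(enc, frame)
            n = len(codes)
            if n == 0:
                continue
            stop_mask = np.isin(codes, stop_codes)
            start_mask = np.isin(codes, start_codes)
            stop_idx = np.flatnonzero(stop_mask)

            def emit(seg_a: int, seg_b: int, stop_i: int | None):
                # seg_a..seg_b-1: codon indices available for starts;
                # stop_i: codon index of the terminating stop, if any.
                if stop_i is not None:
                    span_end = frame + 3 * (stop_i + 1)
                    has_stop = True
                else:
                    span_end = frame + 3 * seg_b
                    has_stop = False
                    if not include_edge:
                        return
                first = True
                for ci in np.flatnonzero(start_mask[seg_a:seg_b]) + seg_a:
                    pos = frame + 3 * int(ci)
                    if span_end - pos < min_len:
                        break  # later starts are even shorter
                    out.append(
                        _to_forward(
                            contig_id, L, strand, frame, pos, span_end,
                            True, has_stop, s[pos : pos + 3],
                        )
                    )
                    if ci == seg_a:
                        first = False
                # 5'-edge-open ORF: segment begins at the contig edge with
                # no preceding stop and no start codon at the very first codon.
                if include_edge and seg_a == 0 and first:
                    pos = frame
                    if span_end - pos >= min_len and span_end > pos:
                        out.append(
                            _to_forward(
                                contig_id, L, strand, frame, pos, span_end,
                                False, has_stop, None,
                            )
                        )

            seg_a = 0
            for si in stop_idx:
                emit(seg_a, int(si), int(si))
                seg_a = int(si) + 1
            if seg_a < n:
                emit(seg_a, n, None)

    out.sort(key=lambda o: (o.start, -(o.end - o.start), o.strand))
    return out


def _to_forward(contig_id, L, strand, frame, pos, span_end, has_start,
                has_stop, start_codon) -> OrfCandidate:
    if strand == "+":
        start, end = pos, span_end
    else:
        start, end = L - span_end, L - pos
    return OrfCandidate(
        contig_id=contig_id, start=start, end=end, strand=strand,
        frame=frame, has_start=has_start, has_stop=has_stop,
        start_codon=start_codon,
    )


def _family_key(o: OrfCandidate):
    # ORFs sharing a stop anchor (3' end on the coding strand) form one family.
    return (o.strand, o.frame, o.end if o.strand == "+" else o.start)


def _coding_span(o: OrfCandidate, L: int) -> tuple[int, int]:
    """Coding span (stop excluded) in coding-strand coordinates."""
    trim = 3 if o.has_stop else 0
    if o.strand == "+":
        return o.start, o.end - trim
    return L - o.end, L - o.start - trim


def train_composition(
    contig: str,
    code: GeneticCode,
    train_min_len: int = DEFAULT_TRAIN_MIN_LEN,
    pseudocount: float = 1.0,
    starts: tuple[str, ...] = DEFAULT_STARTS,
    start_bonus: dict[str, float] | None = None,
) -> CompositionModel:
    """Train the hexamer model on the genome's own long ORFs.

    Training ORFs are the maximal (longest-start) variant of every ORF
    family of length >= ``train_min_len`` under ``code``.  Log-odds are
    log of the pseudocounted in-frame dicodon frequency over the
    pseudocounted genome-wide (both strands) 6-mer frequency.  If no ORF
    reaches ``train_min_len`` an uninformative all-zeros model is
    returned with a warning.
    """
    seq = normalize(contig)
    L = len(seq)
    enc_f = encode(seq)
    enc_r = encode(revcomp(seq))
    hex_f = hexamer_codes(enc_f)
    hex_r = hexamer_codes(enc_r)

    orfs = enumerate_orfs(seq, code, min_len=train_min_len, starts=starts)
    best: dict[tuple, OrfCandidate] = {}
    for o in orfs:
        key = _family_key(o)
        cur = best.get(key)
        if cur is None or o.length > cur.length:
            best[key] = o
    training = list(best.values())

    bonus = dict(DEFAULT_START_BONUS if start_bonus is None else start_bonus)
    if not training:
        logger.warning(
            "no ORF >= %d nt for composition training; using uniform model",
            train_min_len,
        )
        return CompositionModel(np.zeros(4096), bonus, 0)

    counts = np.zeros(4096, dtype=np.float64)
    for o in training:
        s0, e0 = _coding_span(o, L)
        hx = hex_f if o.strand == "+" else hex_r
        idx = np.arange(s0, e0 - 5, 3)
        if idx.size:
            h = hx[idx]
            h = h[h >= 0]
            counts += np.bincount(h, minlength=4096)

    bg = np.bincount(hex_f[hex_f >= 0], minlength=4096).astype(np.float64)
    bg += np.bincount(hex_r[hex_r >= 0], minlength=4096)

    if pseudocount <= 0:
        if (counts == 0).any() or (bg == 0).any():
            raise ValueError(
                "pseudocount must be positive: some 6-mers are unobserved"
            )
        pseudocount = 0.0
    p_cod = (counts + pseudocount) / (counts.sum() + pseudocount * 4096)
    p_bg = (bg + pseudocount) / (bg.sum() + pseudocount * 4096)
    return CompositionModel(np.log(p_cod / p_bg), bonus, len(training))


def score_orf(orf: OrfCandidate, contig: str, model: CompositionModel) -> float:
    """Score one ORF: sum of in-frame dicodon log-odds over the coding
    span (stop excluded, windows every 3 nt) plus the start bonus."""
    seq = normalize(contig)
    cod_s, cod_e = _coding_span(orf, len(seq))
    s = seq if orf.strand == "+" else revcomp(seq)
    total = 0.0
    for i in range(cod_s, cod_e - 5, 3):
        hexamer = s[i : i + 6]
        if set(hexamer) <= set("ACGT"):
            total += model.logodds_of(hexamer)
    if orf.has_start and orf.start_codon in model.start_bonus:
        total += model.start_bonus[orf.start_codon]
    orf.score = total
    return total


def score_candidates(
    candidates: list[OrfCandidate], contig: str, model: CompositionModel
) -> list[OrfCandidate]:
    """Vectorised scoring of many candidates on one contig.

    Equivalent to calling :func:`score_orf` on each candidate, via
    stride-3 prefix sums of the per-position hexamer log-odds.
    """
    seq = normalize(contig)
    L = len(seq)
    prefix = {}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        hx = hexamer_codes(encode(s))
        vals = np.zeros(L, dtype=np.float64)
        if len(hx):
            v = np.where(hx >= 0, model.hexamer_logodds[np.clip(hx, 0, None)], 0.0)
            vals[: len(hx)] = v
        pref = vals.copy()
        for r in range(3):
            pref[r::3] = np.cumsum(vals[r::3])
        prefix[strand] = pref

    for o in candidates:
        s0, e0 = _coding_span(o, L)
        last = e0 - 6
        if last < s0:
            total = 0.0
        else:
            pref = prefix[o.strand]
            total = pref[last] - (pref[s0 - 3] if s0 >= 3 else 0.0)
        if o.has_start and o.start_codon in model.start_bonus:
            total += model.start_bonus[o.start_codon]
        o.score = float(total)
    return candidates


def select_genes(
    candidates: list[OrfCandidate],
    max_overlap: int = DEFAULT_MAX_OVERLAP,
    contig: str | None = None,
    code: GeneticCode | None = None,
    id_prefix: str = "gene",
) -> list[Gene]:
    """Select a maximum-score compatible gene set.

    At most one candidate per stop-anchored family (the best-scoring
    start), pairwise overlap at most ``max_overlap`` nt on any strand.
    Solved exactly by weighted interval scheduling over candidates
    sorted by end; for intervals sorted by end the consecutive-overlap
    constraint implies the pairwise one, which makes the DP exact
    provided every candidate is longer than ``max_overlap`` (guaranteed
    in the pipeline, where min_len 90 > max_overlap 30; violated input
    is rejected).  Ties are broken toward (earlier start, longer ORF,
    lexicographic id) for determinism.

    When ``contig`` and ``code`` are given, proteins are attached
    (translated on the coding strand, stop excluded).
    """
    if not candidates:
        return []
    if any(o.length <= max_overlap for o in candidates):
        raise ValueError("candidates must be longer than max_overlap")

    best: dict[tuple, OrfCandidate] = {}
    for o in candidates:
        key = _family_key(o)
        cur = best.get(key)
        if cur is None or (o.score, -o.start, o.length) > (
            cur.score, -cur.start, cur.length
        ):
            best[key] = o
    cands = sorted(best.values(), key=lambda o: (o.end, o.start, o.strand))

    ends = [o.end for o in cands]
    n = len(cands)
    dp = [0.0] * (n + 1)
    take = [False] * (n + 1)
    prev = [0] * (n + 1)
    for j in range(1, n + 1):
        o = cands[j - 1]
        i = bisect.bisect_right(ends, o.start + max_overlap, 0, j - 1)
        with_o = dp[i] + o.score
        if with_o > dp[j - 1] + 1e-12:
            dp[j] = with_o
            take[j] = True
            prev[j] = i
        else:
            dp[j] = dp[j - 1]

    chosen: list[OrfCandidate] = []
    j = n
    while j > 0:
        if take[j]:
            chosen.append(cands[j - 1])
            j = prev[j]
        else:
            j -= 1
    chosen.sort(key=lambda o: (o.start, o.end, o.strand))

    genes: list[Gene] = []
    seq = normalize(contig) if contig is not None else None
    for k, o in enumerate(chosen, 1):
        protein = ""
        if seq is not None and code is not None:
            sub = seq[o.start : o.end]
            if o.strand == "-":
                sub = revcomp(sub)
            if o.has_stop:
                sub = sub[:-3]
            protein = translate(sub, code)
        genes.append(
            Gene(
                contig_id=o.contig_id, start=o.start, end=o.end,
                strand=o.strand, frame=o.frame, has_start=o.has_start,
                has_stop=o.has_stop, start_codon=o.start_codon,
                score=o.score, gene_id=f"{id_prefix}_{k:04d}", protein=protein,
            )
        )
    return genes
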