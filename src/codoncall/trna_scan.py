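"""Detection and classification of suppressor tRNAs.

A suppressor tRNA carries an anticodon complementary to a stop codon
(Sup-CTA reads the amber stop TAG, Sup-TCA the opal stop TGA, Sup-TTA
the ochre stop TAA) and is corroborating evidence for stop-codon
reassignment.  The internal detector is a recall-oriented cloverleaf
heuristic — it looks for a paired anticodon stem-loop nested inside a
60-100 nt window with acceptor-stem complementarity — and is not a
covariance-model search; externally produced tRNA annotations (GFF3)
take precedence when available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._seq import normalize, revcomp

logger = logging.getLogger(__name__)

_STEM = 5          # anticodon stem length (bp)
_LOOP = 7          # anticodon loop length (nt)
_ARM = 2 * _STEM + _LOOP
_MIN_LEN, _MAX_LEN = 60, 100
_ACCEPTOR = 7      # acceptor stem length (bp)
_MIN_ACCEPTOR_MATCH = 6

_CLASS_BY_CODON = {"TAG": "amber", "TGA": "opal", "TAA": "ochre"}

_PAIR = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class TrnaHit:
    contig_id: str
    start: int
    end: int
    strand: str
    anticodon: str
    decoded_codon: str
    suppressor_class: str
    source: str = "internal"


def classify_anticodon(anticodon: str) -> str:
    """Suppressor class of an anticodon: amber/opal/ochre if its decoded
    codon (reverse complement) is TAG/TGA/TAA, else ``none``."""
    anticodon = normalize(anticodon)
    if len(anticodon) != 3 or not set(anticodon) <= set("ACGT"):
        raise ValueError(f"anticodon must be an ACGT 3-mer, got {anticodon!r}")
    return _CLASS_BY_CODON.get(revcomp(anticodon), "none")


def _hit(contig_id, L, strand, s, e, anticodon) -> TrnaHit:
    if strand == "-":
        s, e = L - e, L - s
    decoded = revcomp(anticodon)
    return TrnaHit(
        contig_id=contig_id, start=s, end=e, strand=strand,
        anticodon=anticodon, decoded_codon=decoded,
        suppressor_class=_CLASS_BY_CODON.get(decoded, "none"),
        source="internal",
    )


def _acceptor_matches(seq: str, s: int, e: int) -> int:
    """Complementary base pairs between the first and last 7 nt of a
    putative tRNA spanning [s, e)."""
    n = 0
    for k in range(_ACCEPTOR):
        if (seq[s + k], seq[e - 1 - k]) in _PAIR:
            n += 1
    return n


def find_trnas(contig: str, contig_id: str = "contig") -> list[TrnaHit]:
    """Scan both strands for tRNA-like loci.

    Signature: a 5-bp anticodon stem whose two halves are reverse
    complements, flanking a 7-nt loop with the anticodon at loop
    positions 3-5, embedded in a 60-100 nt window whose terminal 7-mers
    pair with >= 6/7 complementarity (acceptor stem).  For each stem the
    best window is kept (most acceptor pairs, then leftmost, then
    shortest).  Deterministic; both orientations are reported
    independently.
    """
    seq = normalize(contig)
    L = len(seq)
    hits: list[TrnaHit] = []
    seen: set[tuple] = set()
    for strand, s_seq in (("+", seq), ("-", revcomp(seq))):
        for i in range(0, L - _ARM + 1):
            stem5 = s_seq[i : i + _STEM]
            if not set(stem5) <= set("ACGT"):
                continue
            if s_seq[i + _STEM + _LOOP : i + _ARM] != revcomp(stem5):
                continue
            anticodon = s_seq[i + _STEM + 2 : i + _STEM + 5]
            if not set(anticodon) <= set("ACGT"):
                continue
            # Best window: most acceptor pairs, then closest to the
            # canonical cloverleaf geometry (arm at +26 of a 76-nt body).
            best = None  # (-matches, |s - (i-26)|, |len - 76|, s, length)
            for s0 in range(max(0, i - 40), i - 15):
                for length in range(_MIN_LEN, _MAX_LEN + 1):
                    e0 = s0 + length
                    if e0 > L or e0 < i + _ARM + _ACCEPTOR:
                        continue
                    m = _acceptor_matches(s_seq, s0, e0)
                    if m >= _MIN_ACCEPTOR_MATCH:
                        key = (-m, abs(s0 - (i - 26)), abs(length - 76),
                               s0, length)
                        if best is None or key < best:
                            best = key
            if best is not None:
                s0, length = best[3], best[4]
                h = _hit(contig_id, L, strand, s0, s0 + length, anticodon)
                dedupe = (h.start, h.end, h.strand, h.anticodon)
                if dedupe not in seen:
                    seen.add(dedupe)
                    hits.append(h)
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def ingest_trna_gff(gff3_path: str, genome: dict[str, str]) -> list[TrnaHit]:
    """Read tRNA features from a GFF3 file produced by an external
    detector (tRNAscan-SE / ARAGORN style).

    The anticodon is taken from an ``anticodon=`` attribute when
    present; otherwise the internal stem-loop heuristic is applied to
    the feature's sequence.  Features whose anticodon cannot be resolved
    are kept with class ``none`` and a warning.
    """
    hits: list[TrnaHit] = []
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{gff3_path}:{lineno}: expected 9 tab-separated columns"
                )
            seqid, _, ftype, start_s, end_s, _, strand, _, attrs = cols
            if ftype.lower() != "trna":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{gff3_path}:{lineno}: non-integer coordinates"
                ) from None
            if seqid not in genome:
                raise ValueError(f"{gff3_path}:{lineno}: unknown contig {seqid!r}")
            L = len(genome[seqid])
            if not (1 <= start1 <= end1 <= L):
                raise ValueError(
                    f"{gff3_path}:{lineno}: coordinates outside contig"
                )
            start, end = start1 - 1, end1
            attr_map = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attr_map[k.strip().lower()] = v.strip()
            anticodon = attr_map.get("anticodon", "").upper()
            if anticodon and set(anticodon) <= set("ACGT") and len(anticodon) == 3:
                decoded = revcomp(anticodon)
                hits.append(
                    TrnaHit(
                        contig_id=seqid, start=start, end=end,
                        strand=strand if strand in "+-" else "+",
                        anticodon=anticodon, decoded_codon=decoded,
                        suppressor_class=_CLASS_BY_CODON.get(decoded, "none"),
                        source="external",
                    )
                )
                continue
            sub = genome[seqid][start:end]
            inner = find_trnas(sub, contig_id=seqid)
            if inner:
                h = inner[0]
                hits.append(
                    TrnaHit(
                        contig_id=seqid, start=start, end=end,
                        strand=strand if strand in "+-" else h.strand,
                        anticodon=h.anticodon, decoded_codon=h.decoded_codon,
                        suppressor_class=h.suppressor_class, source="external",
                    )
                )
            else:
                logger.warning(
                    "%s:%d: tRNA feature without resolvable anticodon",
                    gff3_path, lineno,
                )
                hits.append(
                    TrnaHit(
                        contig_id=seqid, start=start, end=end,
                        strand=strand if strand in "+-" else "+",
                        anticodon="NNN", decoded_codon="NNN",
                        suppressor_class="none", source="external",
                    )
                )
    return hits
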