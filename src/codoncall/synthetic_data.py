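"""Phage-like synthetic genomes with known truth.

The generator emulates the coding statistics of real phage genomes —
dense, mostly non-overlapping protein-coding genes giving a truth
coding density near 90%, genome-specific codon usage, log-normal gene
lengths — under a chosen translation table.  For alternative-code
genomes it plants the reassigned codon (TAG under table 15, TGA under
table 4) inside genes at a configurable per-codon rate, which is what
fragments gene calls made under the wrong (standard) code.  Optionally
a synthetic suppressor tRNA gene is inserted in an intergenic gap.

It emulates coding statistics only: no promoters, terminators, repeats,
operon structure or realistic gene content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import revcomp
from .genetic_codes import GeneticCode, get_code, translate
from .orf_engine import Gene
from .trna_scan import TrnaHit, classify_anticodon

# 12-nt cassette holding the universal stop TAA in all three frames of
# both strands (TAA at offsets 1,5,9; TTA -> minus-strand TAA at 0,4,8).
# Seeded through intergenic spacers so that spurious ORFs are interrupted
# under every candidate translation table.
STOP_CASSETTE = "TTAATTAATTAA"

# Synthetic 76-nt tRNA scaffold: 7-bp acceptor stem, D-arm region,
# 5-bp anticodon stem + 7-nt loop (anticodon at loop positions 3-5),
# T-arm with the TTCGA loop motif, 3' acceptor strand.  {AC} is replaced
# by the requested anticodon.
_TRNA_5 = "GCGGGAA" + "TAGCTCAGTTGGTAGAGCA" + "CTGGA" + "CT"
_TRNA_3 = "AA" + "TCCAG" + "GTGGGGTCGTGGGTTCGAATCCCACG" + "TTCCCGC"
TRNA_LENGTH = 76

# Approximate amino-acid frequencies of phage proteomes (fractions;
# normalised at use).  Q and W matter most here: they host the
# reassigned codons under tables 15 and 4.
_AA_FREQ = {
    "A": 7.0, "R": 4.8, "N": 4.6, "D": 5.6, "C": 1.1, "Q": 4.0, "E": 6.2,
    "G": 7.0, "H": 2.0, "I": 6.4, "L": 9.0, "K": 6.8, "M": 2.4, "F": 4.1,
    "P": 4.0, "S": 6.4, "T": 5.6, "W": 1.2, "Y": 3.3, "V": 6.9,
}

_START_CODONS = ("ATG", "GTG", "TTG")
_START_P = (0.80, 0.15, 0.05)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Generation parameters; defaults give a ~30 kb genome with truth
    coding density in the ~90% regime typical of phages."""

    n_genes: int = 45
    gene_len_median: float = 600.0   # bp, stop codon included
    gene_len_sigma: float = 0.5      # log-normal shape
    gene_len_min: int = 90
    gene_len_max: int = 6000
    intergenic_mean: float = 50.0    # geometric mean spacer, bp
    gc_content: float = 0.45         # intergenic GC
    table_id: int = 11
    reassigned_codon_rate: float | None = None  # resolved: 0 for table 11, else 0.03
    plant_suppressor_trna: bool = False
    minus_strand_frac: float = 0.3
    seed: int = 0

    def resolved_rate(self) -> float:
        if self.table_id == 11:
            if self.reassigned_codon_rate:
                raise ValueError("table 11 genomes cannot plant reassigned codons")
            return 0.0
        return 0.03 if self.reassigned_codon_rate is None else self.reassigned_codon_rate


@dataclass
class SyntheticGenome:
    genome_id: str
    sequence: str
    truth_genes: list[Gene]
    truth_trnas: list[TrnaHit]
    spec: SyntheticGenomeSpec = field(repr=False, default=None)


def trna_sequence(anticodon: str) -> str:
    """The 76-nt synthetic suppressor/ordinary tRNA for an anticodon."""
    classify_anticodon(anticodon)  # validates the 3-mer
    seq = _TRNA_5 + anticodon.upper() + _TRNA_3
    assert len(seq) == TRNA_LENGTH
    return seq


def _codon_preferences(rng: np.random.Generator, code: GeneticCode) -> dict:
    """Genome-specific codon usage: Dirichlet-sampled preference over the
    synonymous codons of each amino acid.  Codons that are stops under
    the generating code are excluded; the reassigned codon is reserved
    for explicit planting so TAG/TGA counts inside genes are controlled."""
    syn: dict[str, list[str]] = {}
    for codon, aa in code.codon_map.items():
        if aa == "*" or codon in code.reassignments:
            continue
        syn.setdefault(aa, []).append(codon)
    prefs = {}
    for aa in sorted(syn):
        codons = sorted(syn[aa])
        w = rng.dirichlet(np.full(len(codons), 0.5))
        prefs[aa] = (codons, w)
    return prefs


def _spacer(rng: np.random.Generator, length: int, gc: float) -> str:
    """GC-matched random intergenic sequence with stop cassettes overlaid
    so every ~78-nt window interrupts ORFs in all six frames."""
    if length <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chars = np.array(list("ACGT"))
    seq = list(chars[rng.choice(4, size=length, p=p)])
    cas = len(STOP_CASSETTE)
    if length >= cas + 1:
        offsets = list(range(1, length - cas + 1, 66)) or [(length - cas) // 2]
        for off in offsets:
            seq[off : off + cas] = STOP_CASSETTE
    return "".join(seq)


def _gene_sequence(
    rng: np.random.Generator,
    n_codons: int,
    code: GeneticCode,
    prefs: dict,
    aa_letters: list[str],
    aa_p: np.ndarray,
    rate: float,
) -> str:
    """One gene: start codon, internal codons, stop codon.  Each internal
    position is the reassigned codon with probability ``rate``; otherwise
    an amino acid is drawn and encoded by the genome's codon usage."""
    start = _START_CODONS[rng.choice(3, p=_START_P)]
    reassigned = sorted(code.reassignments)
    parts = [start]
    n_internal = n_codons - 2
    planted = rng.random(n_internal) < rate if rate > 0 else np.zeros(n_internal, bool)
    aas = rng.choice(len(aa_letters), size=n_internal, p=aa_p)
    for k in range(n_internal):
        if planted[k]:
            parts.append(reassigned[0])
        else:
            codons, w = prefs[aa_letters[aas[k]]]
            parts.append(codons[rng.choice(len(codons), p=w)])
    stops = sorted(code.stop_codons)
    stop_w = np.array([{"TAA": 0.6, "TAG": 0.2, "TGA": 0.2}[s] for s in stops])
    parts.append(stops[rng.choice(len(stops), p=stop_w / stop_w.sum())])
    return "".join(parts)


def generate_genome(spec: SyntheticGenomeSpec, genome_id: str | None = None) -> SyntheticGenome:
    """Generate one genome; byte-identical for a fixed spec (seeded)."""
    code = get_code(spec.table_id)
    rate = spec.resolved_rate()
    if spec.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(spec.seed)
    genome_id = genome_id or f"synth_t{spec.table_id}_s{spec.seed}"

    prefs = _codon_preferences(rng, code)
    aa_letters = sorted(_AA_FREQ)
    aa_p = np.array([_AA_FREQ[a] for a in aa_letters])
    aa_p = aa_p / aa_p.sum()

    mu = math.log(spec.gene_len_median)
    lens = np.exp(rng.normal(mu, spec.gene_len_sigma, size=spec.n_genes))
    lens = np.clip(lens, spec.gene_len_min, spec.gene_len_max)
    lens = (np.round(lens / 3).astype(int) * 3)
    lens = np.clip(lens, spec.gene_len_min, spec.gene_len_max)

    p_geo = 1.0 / max(spec.intergenic_mean, 1.0)
    spacers = rng.geometric(p_geo, size=spec.n_genes + 1)
    if spec.plant_suppressor_trna:
        # guarantee an intergenic gap able to host the 76-nt tRNA
        mid = len(spacers) // 2
        spacers[mid] = max(spacers[mid], 150)

    parts: list[str] = []
    genes: list[Gene] = []
    pos = 0
    for k in range(spec.n_genes):
        sp = _spacer(rng, int(spacers[k]), spec.gc_content)
        parts.append(sp)
        pos += len(sp)
        gene_nt = _gene_sequence(
            rng, lens[k] // 3, code, prefs, aa_letters, aa_p, rate
        )
        strand = "-" if rng.random() < spec.minus_strand_frac else "+"
        placed = gene_nt if strand == "+" else revcomp(gene_nt)
        start, end = pos, pos + len(gene_nt)
        genes.append(
            Gene(
                contig_id=genome_id, start=start, end=end, strand=strand,
                frame=(start if strand == "+" else 0) % 3,
                has_start=True, has_stop=True, start_codon=gene_nt[:3],
                gene_id=f"{genome_id}_t{k + 1:04d}",
                protein=translate(gene_nt[:-3], code),
            )
        )
        parts.append(placed)
        pos = end
    parts.append(_spacer(rng, int(spacers[-1]), spec.gc_content))

    genome = SyntheticGenome(
        genome_id=genome_id,
        sequence="".join(parts),
        truth_genes=genes,
        truth_trnas=[],
        spec=spec,
    )
    if spec.plant_suppressor_trna:
        anticodon = {15: "CTA", 4: "TCA"}.get(spec.table_id, "CTA")
        genome = plant_trna(genome, anticodon)
    return genome


def plant_trna(genome: SyntheticGenome, anticodon: str) -> SyntheticGenome:
    """Insert a 76-nt synthetic tRNA into the first intergenic gap of at
    least 100 nt; downstream truth coordinates shift by +76."""
    trna = trna_sequence(anticodon)
    feats = sorted(genome.truth_genes, key=lambda g: g.start)
    gaps: list[tuple[int, int]] = []
    prev = 0
    for g in feats:
        gaps.append((prev, g.start))
        prev = max(prev, g.end)
    gaps.append((prev, len(genome.sequence)))
    insert_at = None
    for a, b in gaps:
        if b - a >= 100:
            insert_at = a + (b - a - TRNA_LENGTH) // 2
            break
    if insert_at is None:
        raise ValueError("no intergenic gap >= 100 nt to host the tRNA")

    seq = genome.sequence[:insert_at] + trna + genome.sequence[insert_at:]
    shifted = []
    for g in feats:
        if g.start >= insert_at:
            g = replace(g, start=g.start + TRNA_LENGTH, end=g.end + TRNA_LENGTH)
        shifted.append(g)
    trnas = [
        replace(t, start=t.start + TRNA_LENGTH, end=t.end + TRNA_LENGTH)
        if t.start >= insert_at else t
        for t in genome.truth_trnas
    ]
    trnas.append(
        TrnaHit(
            contig_id=genome.genome_id, start=insert_at,
            end=insert_at + TRNA_LENGTH, strand="+",
            anticodon=anticodon.upper(),
            decoded_codon=revcomp(anticodon.upper()),
            suppressor_class=classify_anticodon(anticodon),
            source="internal",
        )
    )
    return SyntheticGenome(
        genome_id=genome.genome_id, sequence=seq, truth_genes=shifted,
        truth_trnas=sorted(trnas, key=lambda t: t.start), spec=genome.spec,
    )


def generate_cohort(
    n: int,
    template: SyntheticGenomeSpec,
    seed: int,
    out_dir: str | None = None,
) -> list[SyntheticGenome]:
    """n genomes from a spec template with per-genome seeds seed+i.

    With ``out_dir``, writes a multi-record FASTA, a truth GFF3 and a
    truth TSV for downstream runs.
    """
    genomes = [
        generate_genome(
            replace(template, seed=seed + i),
            genome_id=f"synth_t{template.table_id}_{i:03d}",
        )
        for i in range(n)
    ]
    if out_dir is not None:
        from . import io as ccio  # local import to avoid a cycle

        ccio.write_cohort(genomes, out_dir)
    return genomes
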