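"""FASTA / GFF3 / FAA / FFN / TSV readers and writers plus run manifests.

GFF3 output is version-3 conformant: ``##gff-version 3`` header,
``##sequence-region`` pragmas, 1-based inclusive coordinates, CDS
features carrying a ``transl_table`` attribute, tRNA features carrying
``anticodon``.  Internal coordinates are 0-based half-open and are
converted only at this boundary.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import normalize, revcomp
from .orf_engine import Gene
from .trna_scan import TrnaHit

_IUPAC = set("ACGTNRYSWKMBDHVU")


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a run byte-identically."""

    inputs: list[str] = dataclasses.field(default_factory=list)
    candidate_tables: tuple[int, ...] = (11, 4, 15)
    min_len: int = 90
    train_min_len: int = 300
    pseudocount: float = 1.0
    max_overlap: int = 30
    density_gain_min: float = 10.0
    length_gain_min: float = 1.2
    circular: bool = False
    paired_tests: bool = False
    significance: float = 1e-10
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def write_manifest(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "run_manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-record) FASTA into (id, uppercase DNA) pairs.

    Rejects empty files, duplicate record ids, and non-IUPAC characters
    (reported with record and position).
    """
    records: list[tuple[str, str]] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize(str(rec.seq))
        bad = next((i for i, ch in enumerate(seq) if ch not in _IUPAC), None)
        if bad is not None:
            raise ValueError(
                f"non-IUPAC character {seq[bad]!r} at position {bad + 1} "
                f"of record {rec.id!r}"
            )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60):
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def _gff_escape(v: str) -> str:
    return re.sub(r"[;=&,\t\n]", lambda m: "%%%02X" % ord(m.group()), str(v))


def write_gff3(
    genes: Sequence[Gene],
    trnas: Sequence[TrnaHit],
    contig_lengths: dict[str, int],
    path: str | Path,
    table_id: int,
    source: str = "codoncall",
):
    """Write CDS (+ optional tRNA) features; deterministic order."""
    lines = ["##gff-version 3"]
    for cid in contig_lengths:
        lines.append(f"##sequence-region {cid} 1 {contig_lengths[cid]}")
    feats = [("CDS", g) for g in genes] + [("tRNA", t) for t in trnas]
    feats.sort(key=lambda ft: (ft[1].contig_id, ft[1].start, ft[1].end, ft[0]))
    for ftype, f in feats:
        L = contig_lengths[f.contig_id]
        start1 = f.start + 1
        end1 = min(f.end, L)  # wrap-around genes are clipped at the origin
        if ftype == "CDS":
            attrs = (
                f"ID={_gff_escape(f.gene_id)};transl_table={table_id};"
                f"partial={'0' if f.has_start else '1'}"
                f"{'0' if f.has_stop else '1'}"
            )
            score = f"{f.score:.3f}"
        else:
            attrs = (
                f"ID=trna_{f.start + 1};anticodon={f.anticodon};"
                f"suppressor_class={f.suppressor_class};source_tag={f.source}"
            )
            score = "."
        lines.append(
            "\t".join(
                [
                    f.contig_id, source, ftype, str(start1), str(end1),
                    score, f.strand, "0" if ftype == "CDS" else ".", attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_genes(path: str | Path) -> list[Gene]:
    """Read CDS features back into Gene records (round-trip support)."""
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            seqid, _, ftype, s1, e1, score, strand, _, attrs = cols
            if ftype != "CDS":
                continue
            amap = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            partial = amap.get("partial", "00")
            genes.append(
                Gene(
                    contig_id=seqid, start=int(s1) - 1, end=int(e1),
                    strand=strand, frame=(int(s1) - 1) % 3,
                    has_start=partial[0] == "0",
                    has_stop=len(partial) > 1 and partial[1] == "0",
                    score=float(score) if score != "." else 0.0,
                    gene_id=amap.get("ID", ""),
                )
            )
    return genes


def write_faa(genes: Sequence[Gene], path: str | Path, genome_id: str = ""):
    """Protein FASTA; headers ``<genome>_<gene_id> # start # end # strand``
    with 1-based inclusive coordinates and strand as 1/-1."""
    with open(path, "w") as fh:
        for g in genes:
            name = f"{genome_id}_{g.gene_id}" if genome_id else g.gene_id
            strand = 1 if g.strand == "+" else -1
            fh.write(f">{name} # {g.start + 1} # {g.end} # {strand}\n")
            for i in range(0, len(g.protein), 60):
                fh.write(g.protein[i : i + 60] + "\n")


def write_ffn(
    genes: Sequence[Gene],
    contigs: dict[str, str],
    path: str | Path,
    genome_id: str = "",
):
    """Nucleotide FASTA of gene sequences (coding strand, stop included)."""
    with open(path, "w") as fh:
        for g in genes:
            sub = contigs[g.contig_id][g.start : g.end]
            if g.strand == "-":
                sub = revcomp(sub)
            name = f"{genome_id}_{g.gene_id}" if genome_id else g.gene_id
            strand = 1 if g.strand == "+" else -1
            fh.write(f">{name} # {g.start + 1} # {g.end} # {strand}\n")
            for i in range(0, len(sub), 60):
                fh.write(sub[i : i + 60] + "\n")


def write_tsv(frame: pd.DataFrame, path: str | Path):
    frame.to_csv(path, sep="\t", index=False)


def read_functions_tsv(path: str | Path) -> dict[str, str]:
    """Per-gene function table: columns gene_id, product."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "product" not in df.columns:
        raise ValueError("function table needs 'gene_id' and 'product' columns")
    return dict(zip(df["gene_id"], df["product"].fillna("")))


def write_cohort(genomes, out_dir: str | Path):
    """FASTA + truth GFF3 + truth TSV for a synthetic cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(((g.genome_id, g.sequence) for g in genomes), out / "genomes.fasta")
    rows = []
    for g in genomes:
        write_gff3(
            g.truth_genes, g.truth_trnas, {g.genome_id: len(g.sequence)},
            out / f"{g.genome_id}.truth.gff3", table_id=g.spec.table_id,
            source="codoncall-simulate",
        )
        for t in g.truth_genes:
            rows.append(
                {
                    "genome_id": g.genome_id, "gene_id": t.gene_id,
                    "start": t.start, "end": t.end, "strand": t.strand,
                    "table_id": g.spec.table_id,
                }
            )
    write_tsv(pd.DataFrame(rows), out / "truth_genes.tsv")
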