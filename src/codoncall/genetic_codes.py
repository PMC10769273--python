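"""Translation tables and nucleotide-to-protein translation.

Supports the standard bacterial/archaeal/plastid code (NCBI table 11)
and the two stop-codon reassignments observed in phages:

* table 15 — TAG is reassigned to glutamine (Q); stops are TAA, TGA;
* table 4  — TGA is reassigned to tryptophan (W); stops are TAA, TAG.

Arbitrary single-codon reassignments can be registered as custom codes,
e.g. for lineages where the amino acid encoded by the repurposed stop is
not yet known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from ._seq import normalize

STOP = "*"

# Amino acids for the 64 codons in TCAG order (first base slowest), the
# standard representation of the standard genetic code.  Table 11 shares
# this codon->amino-acid assignment (it differs from table 1 only in the
# set of permitted initiation codons).
_AA_TCAG = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"


def _standard_codon_map() -> dict[str, str]:
    out: dict[str, str] = {}
    k = 0
    for b1 in "TCAG":
        for b2 in "TCAG":
            for b3 in "TCAG":
                out[b1 + b2 + b3] = _AA_TCAG[k]
                k += 1
    return out


@dataclass(frozen=True)
class GeneticCode:
    """An immutable translation table.

    Attributes
    ----------
    table_id
        Numeric label (11, 4, 15, or a user-registered id).
    codon_map
        Mapping of all 64 DNA codons to a one-letter amino acid, with
        ``"*"`` marking stop codons.
    stop_codons
        Codons mapped to stop.
    reassignments
        Codons that are stops under table 11 but sense codons here,
        mapped to the amino acid they encode.
    """

    table_id: int
    codon_map: Mapping[str, str]
    stop_codons: frozenset[str]
    reassignments: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.codon_map) != 64:
            raise ValueError("codon_map must cover all 64 codons")
        stops = frozenset(c for c, aa in self.codon_map.items() if aa == STOP)
        if stops != self.stop_codons:
            raise ValueError("stop_codons inconsistent with codon_map")
        if set(self.reassignments) & self.stop_codons:
            raise ValueError("reassigned codons cannot also be stops")

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


def _make_code(table_id: int, reassignments: Mapping[str, str]) -> GeneticCode:
    cmap = _standard_codon_map()
    for codon, aa in reassignments.items():
        if cmap.get(codon) != STOP:
            raise ValueError(f"{codon} is not a stop codon under table 11")
        if len(aa) != 1 or aa == STOP:
            raise ValueError("reassignment target must be one amino acid letter")
        cmap[codon] = aa
    return GeneticCode(
        table_id=table_id,
        codon_map=MappingProxyType(cmap),
        stop_codons=frozenset(c for c, a in cmap.items() if a == STOP),
        reassignments=MappingProxyType(dict(reassignments)),
    )


_REGISTRY: dict[int, GeneticCode] = {
    11: _make_code(11, {}),
    4: _make_code(4, {"TGA": "W"}),
    15: _make_code(15, {"TAG": "Q"}),
}


def get_code(table_id: int) -> GeneticCode:
    """Return the translation table for ``table_id``.

    Raises
    ------
    ValueError
        If the table is neither built in (11, 4, 15) nor registered.
    """
    try:
        return _REGISTRY[table_id]
    except KeyError:
        raise ValueError(f"unsupported translation table: {table_id}") from None


def register_code(table_id: int, reassignments: Mapping[str, str]) -> GeneticCode:
    """Register a custom code as table 11 plus single-codon reassignments.

    Covers lineages whose repurposed stop encodes an amino acid that may
    not be one of the two known cases (e.g. an unknown residue can be
    registered as ``X``).
    """
    if table_id in (11, 4, 15):
        raise ValueError("built-in tables cannot be redefined")
    code = _make_code(table_id, reassignments)
    _REGISTRY[table_id] = code
    return code


def translate(seq: str, code: GeneticCode, to_stop: bool = False) -> str:
    """Translate an in-frame DNA sequence under ``code``.

    Codons containing any non-ACGT base translate to ``X``.  Stops are
    rendered ``*`` unless ``to_stop``, in which case translation halts
    before the first stop.
    """
    seq = normalize(seq)
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not divisible by 3")
    cmap = code.codon_map
    out = []
    for i in range(0, len(seq), 3):
        aa = cmap.get(seq[i : i + 3], "X")
        if aa == STOP and to_stop:
            break
        out.append(aa)
    return "".join(out)
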