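"""Standard genetic code tables and degeneracy machinery.

Everything downstream (GC4/GC3S, Wright's effective number of codons, RSCU,
the stratified dinucleotide null) is driven by the synonymous-substitution
structure of the code: for every sense codon and codon position we
pre-compute the set of nucleotides that leave the encoded amino acid
unchanged with the other two positions held fixed. The size of that set is
the position's degeneracy class (onefold .. fourfold); third positions of
the eight four-codon boxes (including the fourfold halves of Leu, Ser and
Arg) make up the 32-codon fourfold set used for GC4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, Mapping, Tuple

from Bio.Data import CodonTable

NUCLEOTIDES = ("A", "C", "G", "T")
STOP = "*"

#: Amino acids encoded by AT-rich codons vs GC-rich codons ("GC pressure"
#: diagnostics): Phe, Tyr, Met, Ile, Asn, Lys vs Gly, Ala, Arg, Pro.
FYMINK = frozenset("FYMINK")
GARP = frozenset("GARP")

#: Sixfold families are handled per codon box everywhere except ENc class
#: averaging, where Leu/Ser/Arg form their own class of weight 3.
SIXFOLD_AA = frozenset("LSR")


class StopCodonError(ValueError):
    """Raised when a degeneracy query names a stop codon."""


@dataclass(frozen=True)
class GeneticCode:
    """The standard nuclear genetic code with derived degeneracy sets.

    Attributes
    ----------
    codon_to_aa
        All 64 trinucleotides mapped to one-letter amino acids; stops map
        to ``"*"``.
    stop_set
        The three stop codons.
    syn_nt_sets
        ``(codon, position)`` (position 1-based) to the frozenset of
        nucleotides at that position that preserve the amino acid with the
        other two positions fixed. Defined for sense codons only.
    third_pos_degeneracy
        Sense codon to its third-position degeneracy class in {1, 2, 3, 4}.
    fourfold_third_set
        The 32 sense codons whose third position is fourfold degenerate.
    gc3s_eligible_set
        The 59 sense codons used for GC3S (all but ATG and TGG).
    """

    codon_to_aa: Mapping[str, str]
    stop_set: FrozenSet[str]
    syn_nt_sets: Mapping[Tuple[str, int], FrozenSet[str]]
    third_pos_degeneracy: Mapping[str, int]
    fourfold_third_set: FrozenSet[str]
    gc3s_eligible_set: FrozenSet[str]
    sense_codons: Tuple[str, ...] = field(default=())

    @property
    def amino_acids(self) -> Tuple[str, ...]:
        return tuple(sorted({aa for aa in self.codon_to_aa.values() if aa != STOP}))

    def synonyms(self, aa: str) -> Tuple[str, ...]:
        """All sense codons encoding ``aa``, in lexicographic order."""
        return tuple(
            c for c in self.sense_codons if self.codon_to_aa[c] == aa
        )

    def family_size(self, aa: str) -> int:
        return len(self.synonyms(aa))

    def translate(self, cds: str) -> str:
        """Translate an in-frame CDS; unknown/N codons become ``X``."""
        out = []
        for i in range(0, len(cds) - len(cds) % 3, 3):
            out.append(self.codon_to_aa.get(cds[i : i + 3], "X"))
        return "".join(out)


def position_degeneracy(code: GeneticCode, codon: str, position: int) -> int:
    """Number of synonymous nucleotides at ``position`` (1-based) of ``codon``.

    The count includes the codon's own nucleotide, so values lie in
    {1, 2, 3, 4}; e.g. (GGA, 3) -> 4 (Gly box), (ATA, 3) -> 3 (Ile box),
    (TTA, 1) -> 2 (T/C both give Leu with TA fixed).
    """
    codon = codon.upper()
    if codon in code.stop_set:
        raise StopCodonError(f"degeneracy undefined for stop codon {codon}")
    if codon not in code.codon_to_aa:
        raise KeyError(f"not a codon: {codon!r}")
    if position not in (1, 2, 3):
        raise ValueError("position must be 1, 2 or 3")
    return len(code.syn_nt_sets[(codon, position)])


@lru_cache(maxsize=1)
def build_standard_code() -> GeneticCode:
    """Build the standard nuclear code with all derived sets populated."""
    table = CodonTable.unambiguous_dna_by_id[1]
    codon_to_aa: Dict[str, str] = dict(table.forward_table)
    for stop in table.stop_codons:
        codon_to_aa[stop] = STOP
    stop_set = frozenset(table.stop_codons)
    sense = tuple(sorted(c for c in codon_to_aa if c not in stop_set))

    syn_nt_sets: Dict[Tuple[str, int], FrozenSet[str]] = {}
    for codon in sense:
        aa = codon_to_aa[codon]
        for pos in (1, 2, 3):
            allowed = frozenset(
                nt
                for nt in NUCLEOTIDES
                if codon_to_aa.get(codon[: pos - 1] + nt + codon[pos:]) == aa
            )
            syn_nt_sets[(codon, pos)] = allowed

    third_deg = {c: len(syn_nt_sets[(c, 3)]) for c in sense}
    fourfold = frozenset(c for c, d in third_deg.items() if d == 4)
    gc3s_eligible = frozenset(c for c in sense if c not in ("ATG", "TGG"))

    return GeneticCode(
        codon_to_aa=codon_to_aa,
        stop_set=stop_set,
        syn_nt_sets=syn_nt_sets,
        third_pos_degeneracy=third_deg,
        fourfold_third_set=fourfold,
        gc3s_eligible_set=gc3s_eligible,
        sense_codons=sense,
    )


def dump_code_tsv(code: GeneticCode) -> str:
    """Render the degeneracy tables as TSV text for audit."""
    lines = ["codon\taa\tdeg1\tdeg2\tdeg3\tfourfold_third\tgc3s_eligible"]
    for codon in code.sense_codons:
        lines.append(
            "\t".join(
                [
                    codon,
                    code.codon_to_aa[codon],
                    str(position_degeneracy(code, codon, 1)),
                    str(position_degeneracy(code, codon, 2)),
                    str(position_degeneracy(code, codon, 3)),
                    str(int(codon in code.fourfold_third_set)),
                    str(int(codon in code.gc3s_eligible_set)),
                ]
            )
        )
    return "\n".join(lines) + "\n"
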