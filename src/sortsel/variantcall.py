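"""Translation, reference alignment by the equal-length rule, variant calling.

Merged reads are translated with the standard genetic code and compared to
the reference protein position by position. Because the library carries only
substitutions, sequences whose translated length differs from the reference
are discarded rather than gap-aligned; stop codons and ambiguous residues
(from N bases) are discard reasons of their own. Each retained read becomes
a :class:`VariantKey` — the ordered list of amino acid substitutions
relative to the reference, named in canonical residue numbers (index +
``numbering_offset``) so that the binding loop of the bundled Kunitz-domain
reference spans residues 11–18.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqIO import parse as seqio_parse

__all__ = [
    "ReferenceProtein",
    "Substitution",
    "VariantKey",
    "PARENT_KEY",
    "Untranslatable",
    "DiscardRead",
    "translate",
    "call_variant",
    "count_variants",
    "count_merged_reads",
    "CountResult",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

#: canonical name of the unmutated parent
PARENT_KEY = "parent"


class Untranslatable(ValueError):
    """DNA cannot be translated (bad length or ambiguous codon)."""


class DiscardRead(ValueError):
    """Read rejected during variant calling; ``reason`` names why."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def translate(dna: str) -> str:
    """Translate DNA with the standard code; stops become '*'.

    Codons containing N translate to 'X' (the read is discarded downstream
    as ``ambiguous_residue``). Length not divisible by three, or characters
    outside ACGTN, are errors.
    """
    dna = dna.upper()
    if re.search(r"[^ACGTN]", dna):
        raise ValueError("DNA contains characters outside ACGTN")
    if len(dna) % 3 != 0:
        raise Untranslatable(f"length {len(dna)} not divisible by 3")
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        out.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(out)


@dataclass(frozen=True)
class ReferenceProtein:
    """Reference coding sequence with canonical residue numbering."""

    dna: str
    numbering_offset: int = 0
    loop_positions: frozenset[int] = frozenset()

    @property
    def protein(self) -> str:
        return translate(self.dna)

    def __post_init__(self) -> None:
        prot = self.protein
        if "*" in prot or "X" in prot:
            raise ValueError("reference ORF contains a stop or ambiguous codon")

    def canonical_position(self, index: int) -> int:
        return index + self.numbering_offset

    def index_of(self, canonical_position: int) -> int:
        idx = canonical_position - self.numbering_offset
        if not 0 <= idx < len(self.protein):
            raise ValueError(f"canonical position {canonical_position} outside reference")
        return idx

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        numbering_offset: int = 0,
        loop_positions: Iterable[int] = (),
    ) -> "ReferenceProtein":
        record = next(seqio_parse(str(path), "fasta"))
        return cls(
            dna=str(record.seq).upper(),
            numbering_offset=numbering_offset,
            loop_positions=frozenset(loop_positions),
        )

    @classmethod
    def default(cls) -> "ReferenceProtein":
        """Bundled synthetic Kunitz-domain parent ORF.

        A synthetic stand-in: a 57-residue Kunitz (BPTI-fold) sequence whose
        binding loop at canonical residues 11–18 carries Thr-11, invariant
        Cys-14 and Gly-17. Canonical numbering = index + 3. Loop positions
        exclude the invariant cysteine.
        """
        path = resources.files("sortsel.data") / "appi3m_synthetic.fasta"
        with resources.as_file(path) as p:
            return cls.from_fasta(p, numbering_offset=3,
                                  loop_positions={11, 12, 13, 15, 16, 17, 18})


@dataclass(frozen=True, order=True)
class Substitution:
    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise ValueError("substitution must change the residue")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{aa!r} is not a standard amino acid")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class VariantKey:
    """Ordered substitution list; ``n_mut == 0`` is the unmutated parent."""

    substitutions: tuple[Substitution, ...] = ()

    def __post_init__(self) -> None:
        positions = [s.position for s in self.substitutions]
        if positions != sorted(set(positions)):
            raise ValueError("substitution positions must be strictly increasing")

    @property
    def n_mut(self) -> int:
        return len(self.substitutions)

    def __str__(self) -> str:
        if not self.substitutions:
            return PARENT_KEY
        return "/".join(str(s) for s in self.substitutions)

    @classmethod
    def from_string(cls, text: str) -> "VariantKey":
        text = text.strip()
        if text in (PARENT_KEY, "", "WT"):
            return cls()
        subs = []
        for token in text.split("/"):
            m = _SUB_RE.match(token)
            if not m:
                raise ValueError(f"cannot parse substitution {token!r}")
            subs.append(Substitution(int(m.group(2)), m.group(1), m.group(3)))
        return cls(tuple(subs))

    def apply_to(self, ref: ReferenceProtein) -> str:
        """Rebuild the full protein carrying these substitutions."""
        prot = list(ref.protein)
        for s in self.substitutions:
            idx = ref.index_of(s.position)
            if prot[idx] != s.wt_aa:
                raise ValueError(f"{s}: reference has {prot[idx]} at {s.position}")
            prot[idx] = s.mut_aa
        return "".join(prot)


def call_variant(merged_protein: str, ref: ReferenceProtein) -> VariantKey:
    """Positional comparison against the reference (equal-length rule).

    Raises :class:`DiscardRead` with reason ``length_mismatch``,
    ``stop_codon`` or ``ambiguous_residue``.
    """
    if len(merged_protein) != len(ref.protein):
        raise DiscardRead("length_mismatch")
    if "*" in merged_protein:
        raise DiscardRead("stop_codon")
    if "X" in merged_protein:
        raise DiscardRead("ambiguous_residue")
    subs = tuple(
        Substitution(ref.canonical_position(i), wt, mut)
        for i, (wt, mut) in enumerate(zip(ref.protein, merged_protein))
        if wt != mut
    )
    return VariantKey(subs)


@dataclass
class CountResult:
    """Per-variant read counts and a tally of discarded reads by reason."""

    counts: Counter = field(default_factory=Counter)  # str(VariantKey) -> reads
    n_mut: dict = field(default_factory=dict)  # str(VariantKey) -> n_mut
    discards: Counter = field(default_factory=Counter)  # reason -> reads

    @property
    def n_reads_counted(self) -> int:
        return sum(self.counts.values())

    @property
    def n_reads_discarded(self) -> int:
        return sum(self.discards.values())

    def to_frame(self, library_id: str = "library") -> pd.DataFrame:
        rows = [
            {"variant_key": k, "n_mut": self.n_mut[k], "library_id": library_id,
             "reads": n}
            for k, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["variant_key", "n_mut", "library_id", "reads"])


def count_variants(variants: Iterable[VariantKey]) -> CountResult:
    """Exact multiset count of already-called variants."""
    result = CountResult()
    for v in variants:
        key = str(v)
        result.counts[key] += 1
        result.n_mut[key] = v.n_mut
    return result


def count_merged_reads(dna_seqs: Iterable[str], ref: ReferenceProtein) -> CountResult:
    """Translate and call each merged DNA sequence, tallying discards."""
    result = CountResult()
    for dna in dna_seqs:
        try:
            protein = translate(dna)
        except Untranslatable:
            result.discards["length_mismatch"] += 1
            continue
        try:
            v = call_variant(protein, ref)
        except DiscardRead as e:
            result.discards[e.reason] += 1
            continue
        key = str(v)
        result.counts[key] += 1
        result.n_mut[key] = v.n_mut
    return result
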