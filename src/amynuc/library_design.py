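"""Mutagenesis library designs: degenerate codons, variant spaces, parameter counts.

A library design fixes which positions of the wild-type sequence are mutable,
which amino acids each position may take, and the maximum number of
simultaneous substitutions. Double-mutant libraries (NNK scans) have
``max_order=2``; combinatorial libraries (DTS hydrophobic scans) allow every
mutable position to vary at once, so their genotype space is the full product
of per-position alphabets.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from amynuc.constants import AB42, COMB1_POSITIONS, COMB2_POSITIONS

__all__ = [
    "CodonScheme",
    "LibraryDesign",
    "Mutation",
    "Variant",
    "VariantSpace",
    "count_model_parameters",
    "count_variant_space",
    "enumerate_variants",
    "expand_degenerate_codon",
    "oligo_pool_nucleotide_space",
    "paper_designs",
]

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")

#: the 15 standard IUPAC nucleotide symbols ('X' is a non-standard extension)
_IUPAC_SYMBOLS = frozenset("ACGTRYSWKMBDHVN")


class Mutation(NamedTuple):
    """A single amino-acid substitution, e.g. I32M."""

    position: int
    wt: str
    mut: str

    def __str__(self) -> str:  # "I32M"
        return f"{self.wt}{self.position}{self.mut}"

    @classmethod
    def parse(cls, text: str) -> "Mutation":
        m = _MUTATION_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse mutation identifier {text!r}")
        return cls(int(m.group(2)), m.group(1), m.group(3))


class Variant(NamedTuple):
    """A genotype: full amino-acid sequence plus its substitutions vs WT."""

    sequence: str
    mutations: tuple[Mutation, ...]

    @property
    def order(self) -> int:
        return len(self.mutations)

    @property
    def mutation_str(self) -> str:
        return ",".join(str(m) for m in self.mutations)


def parse_mutation_str(text: str) -> tuple[Mutation, ...]:
    """Parse a comma-separated mutation string; '' or 'WT' means no mutations."""
    text = (text or "").strip()
    if text in ("", "WT"):
        return ()
    return tuple(Mutation.parse(t) for t in text.split(","))


@dataclass(frozen=True)
class CodonScheme:
    """A degenerate codon and its expansion under the standard genetic code."""

    code: str
    codons: frozenset[str]
    amino_acids: frozenset[str]
    includes_stop: bool


def expand_degenerate_codon(code: str) -> CodonScheme:
    """Expand a 3-letter IUPAC degenerate codon into concrete codons and residues.

    Stop codons are flagged via ``includes_stop`` and excluded from
    ``amino_acids`` (library accounting counts amino-acid variants only).
    """
    code = code.upper().strip()
    if len(code) != 3:
        raise ValueError(f"degenerate codon must have 3 symbols, got {code!r}")
    expansions = []
    for sym in code:
        if sym not in _IUPAC_SYMBOLS:
            raise ValueError(f"invalid IUPAC nucleotide symbol {sym!r} in {code!r}")
        expansions.append(ambiguous_dna_values[sym])
    codons = frozenset("".join(c) for c in itertools.product(*expansions))
    translations = {str(Seq(c).translate()) for c in codons}
    return CodonScheme(
        code=code,
        codons=codons,
        amino_acids=frozenset(translations - {"*"}),
        includes_stop="*" in translations,
    )


@dataclass(frozen=True)
class LibraryDesign:
    """A mutagenesis library over a fixed wild-type sequence.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"cterm"``.
    sequence:
        Wild-type amino-acid sequence; positions are 1-based.
    mutable_positions:
        Ordered 1-based positions that may be substituted.
    allowed:
        Per-position full amino-acid alphabet (WT included where encoded).
    max_order:
        Maximum simultaneous substitutions (2 for double-mutant scans; equal
        to ``len(mutable_positions)`` for combinatorial designs).
    scheme:
        Degenerate-codon scheme used to build the library, if any.
    """

    name: str
    sequence: str
    mutable_positions: tuple[int, ...]
    allowed: Mapping[int, frozenset[str]] = field(repr=False)
    max_order: int
    scheme: CodonScheme | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for p in self.mutable_positions:
            if not 1 <= p <= n:
                raise ValueError(f"mutable position {p} outside 1..{n}")
        if len(set(self.mutable_positions)) != len(self.mutable_positions):
            raise ValueError("duplicate mutable positions")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")

    @classmethod
    def from_scheme(
        cls,
        name: str,
        positions: Iterable[int],
        code: str = "NNK",
        sequence: str = AB42,
        max_order: int = 2,
    ) -> "LibraryDesign":
        scheme = expand_degenerate_codon(code)
        positions = tuple(positions)
        allowed = {p: scheme.amino_acids for p in positions}
        return cls(name, sequence, positions, allowed, max_order, scheme)

    def wt_residue(self, position: int) -> str:
        return self.sequence[position - 1]

    def alternatives(self, position: int) -> frozenset[str]:
        """Non-WT amino acids allowed at ``position``."""
        return self.allowed[position] - {self.wt_residue(position)}

    @property
    def is_combinatorial(self) -> bool:
        return self.max_order == len(self.mutable_positions)


@dataclass(frozen=True)
class VariantSpace:
    singles: int
    doubles: int
    total_genotypes: int


def count_variant_space(design: LibraryDesign) -> VariantSpace:
    """Closed-form variant-space sizes for a design.

    ``singles``/``doubles`` count amino-acid variants with exactly one/two
    non-WT substitutions. For combinatorial designs ``total_genotypes`` is the
    product of per-position alphabet sizes (WT included); otherwise it is
    1 + singles + doubles.
    """
    alts = {p: len(design.alternatives(p)) for p in design.mutable_positions}
    singles = sum(alts.values())
    doubles = 0
    if design.max_order >= 2:
        doubles = sum(
            alts[p] * alts[q]
            for p, q in itertools.combinations(design.mutable_positions, 2)
        )
    if design.is_combinatorial:
        total = math.prod(len(design.allowed[p]) for p in design.mutable_positions)
    else:
        total = 1 + singles + doubles
    return VariantSpace(singles=singles, doubles=doubles, total_genotypes=total)


def oligo_pool_nucleotide_space(design: LibraryDesign) -> int:
    """Unique nucleotide sequences in a two-degenerate-codon oligo pool.

    One oligo per unordered pair of mutable positions, each carrying the
    design's degenerate codon at both positions (e.g. 105 oligos x 32^2 = 107,520
    for a 15-position NNK double-mutant pool).
    """
    if design.scheme is None:
        raise ValueError("design has no degenerate-codon scheme")
    n_codons = len(design.scheme.codons)
    n_pairs = math.comb(len(design.mutable_positions), 2)
    return n_pairs * n_codons * n_codons


@dataclass(frozen=True)
class ParameterCount:
    first_order: int
    pairs: int
    couplings: int
    genotype_space: int
    compression_first_order: int
    compression_with_couplings: int


def count_model_parameters(
    designs: Sequence[LibraryDesign], order: int = 2
) -> ParameterCount:
    """Count distinct energy-model parameters implied by joint designs.

    First-order terms are distinct (position, non-WT amino acid) pairs across
    designs; coupling terms exist for every unordered position pair co-mutable
    within at least one design. The genotype space uses the
    alternatives-per-site convention (product of per-position non-WT
    alternative counts, combined across designs by inclusion-exclusion), which
    for the two joint hydrophobic combinatorial designs gives
    4^8 + 4^6 - 4^3 genotypes.
    """
    if not designs:
        raise ValueError("no designs given")
    wt = designs[0].sequence
    for d in designs:
        if d.sequence != wt:
            raise ValueError(
                f"designs must share a WT sequence; {d.name!r} differs"
            )

    terms: set[tuple[int, str]] = set()
    pair_alts: dict[frozenset[int], int] = {}
    for d in designs:
        for p in d.mutable_positions:
            terms.update((p, a) for a in d.alternatives(p))
    # union of alternatives per position, across designs
    alt_union: dict[int, set[str]] = {}
    for d in designs:
        for p in d.mutable_positions:
            alt_union.setdefault(p, set()).update(d.alternatives(p))
    pairs: set[frozenset[int]] = set()
    for d in designs:
        if d.max_order >= 2:
            for p, q in itertools.combinations(d.mutable_positions, 2):
                pairs.add(frozenset((p, q)))
    couplings = sum(
        len(alt_union[p]) * len(alt_union[q]) for p, q in (tuple(pr) for pr in pairs)
    )

    # inclusion-exclusion over design subsets; a subset's intersection covers
    # genotypes mutable only at positions shared by all its designs
    genotypes = 0
    for r in range(1, len(designs) + 1):
        for subset in itertools.combinations(designs, r):
            shared = set(subset[0].mutable_positions)
            for d in subset[1:]:
                shared &= set(d.mutable_positions)
            alt_inter: dict[int, set[str]] = {}
            for p in shared:
                sets = [set(d.alternatives(p)) for d in subset]
                alt_inter[p] = set.intersection(*sets)
            size = math.prod(len(alt_inter[p]) for p in shared) if shared else 1
            if not shared and r > 1:
                size = 1  # only the all-WT genotype is shared
            genotypes += (-1) ** (r + 1) * size
    first_order = len(terms)
    return ParameterCount(
        first_order=first_order,
        pairs=len(pairs),
        couplings=couplings if order >= 2 else 0,
        genotype_space=genotypes,
        compression_first_order=round(genotypes / first_order),
        compression_with_couplings=round(genotypes / (first_order + couplings))
        if couplings
        else 0,
    )


def enumerate_variants(
    design: LibraryDesign,
    up_to_order: int,
    include_wt: bool | None = None,
    cap: int = 2_000_000,
) -> list[Variant]:
    """Materialize all variants of order 1..``up_to_order`` as explicit sequences.

    ``include_wt`` defaults to True for combinatorial designs (whose genotype
    space conventionally includes the all-WT sequence, e.g. 5^6 = 15,625) and
    for ``up_to_order=0``; otherwise False. Raises if the closed-form count
    exceeds ``cap``.
    """
    k_max = min(up_to_order, len(design.mutable_positions), design.max_order)
    if up_to_order == 0:
        k_max = 0
    if include_wt is None:
        include_wt = design.is_combinatorial or up_to_order == 0

    alts = {p: sorted(design.alternatives(p)) for p in design.mutable_positions}
    expected = int(include_wt)
    for k in range(1, k_max + 1):
        for combo in itertools.combinations(design.mutable_positions, k):
            expected += math.prod(len(alts[p]) for p in combo)
    if expected > cap:
        raise ValueError(
            f"enumeration of {expected} variants exceeds cap {cap}; raise cap"
        )

    out: list[Variant] = []
    if include_wt:
        out.append(Variant(design.sequence, ()))
    seq = list(design.sequence)
    for k in range(1, k_max + 1):
        for combo in itertools.combinations(design.mutable_positions, k):
            for aas in itertools.product(*(alts[p] for p in combo)):
                s = seq.copy()
                muts = []
                for p, a in zip(combo, aas):
                    s[p - 1] = a
                    muts.append(Mutation(p, design.wt_residue(p), a))
                out.append(Variant("".join(s), tuple(muts)))
    return out


def paper_designs(sequence: str = AB42) -> dict[str, LibraryDesign]:
    """The five Abeta42 library designs used throughout the package.

    Three NNK double-mutant scans (shallow: full sequence; N-terminal:
    residues 1-28; C-terminal: residues 28-42) and two DTS combinatorial
    hydrophobic libraries over 8 and 6 positions.
    """
    return {
        "shallow": LibraryDesign.from_scheme(
            "shallow", range(1, 43), "NNK", sequence, max_order=2
        ),
        "nterm": LibraryDesign.from_scheme(
            "nterm", range(1, 29), "NNK", sequence, max_order=2
        ),
        "cterm": LibraryDesign.from_scheme(
            "cterm", range(28, 43), "NNK", sequence, max_order=2
        ),
        "comb1": LibraryDesign.from_scheme(
            "comb1", COMB1_POSITIONS, "DTS", sequence, max_order=len(COMB1_POSITIONS)
        ),
        "comb2": LibraryDesign.from_scheme(
            "comb2", COMB2_POSITIONS, "DTS", sequence, max_order=len(COMB2_POSITIONS)
        ),
    }
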