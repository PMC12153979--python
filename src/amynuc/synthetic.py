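"""Synthetic ground truth for every downstream stage.

Generates additive-plus-coupling activation-energy landscapes, pushes them
through the bounded sigmoid growth-rate map, simulates multinomial
input/output sequencing counts for pooled selections, and writes surrogate
fibril-stability tables and minimal PDB structure fixtures. All randomness is
driven by explicit seeds.

The selection model collapses the assay into one effective growth round:
output frequencies are proportional to input frequencies times exp(GR). This
is the log-linear form the enrichment analysis assumes, so at high depth the
estimated growth rates converge to the landscape's noise-free values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3

from amynuc.constants import AB42, APR2
from amynuc.library_design import LibraryDesign, Mutation, Variant

__all__ = [
    "GroundTruthLandscape",
    "build_pdb",
    "generate_fixture_structure",
    "generate_stability_table",
    "growth_rate_from_energy",
    "sample_landscape",
    "serpentine_fixture",
    "simulate_selection",
]


def _canon_pair(a: Mutation, b: Mutation) -> tuple[str, str]:
    key = tuple(sorted((str(a), str(b)), key=lambda s: (Mutation.parse(s).position, s)))
    return key  # type: ignore[return-value]


@dataclass
class GroundTruthLandscape:
    """True energy landscape: additive terms, sparse couplings, sigmoid map.

    ``first_order`` maps mutation identifiers ("I32M") to activation-energy
    changes (kcal/mol; positive slows nucleation); ``couplings`` maps
    canonical mutation-pair keys to coupling energies. The observable is
    GR = g(phi) - g(0) with g(phi) = L + (U-L)/(1+exp(s*phi)), a decreasing
    sigmoid: higher activation energy means slower nucleation, slower growth.
    """

    first_order: dict[str, float]
    couplings: dict[tuple[str, str], float] = field(default_factory=dict)
    sigmoid: tuple[float, float, float] = (-4.0, 0.0, 1.0)  # (L, U, scale)
    temperature: float = 303.0

    def __post_init__(self) -> None:
        L, U, s = self.sigmoid
        if not L < U:
            raise ValueError(f"sigmoid bounds must satisfy L < U, got {L} >= {U}")
        if s <= 0:
            raise ValueError("sigmoid scale must be positive")

    def trait(self, mutations: Iterable[Mutation]) -> float:
        """Additive trait phi: sum of first-order terms plus applicable couplings."""
        muts = tuple(mutations)
        phi = 0.0
        for m in muts:
            key = str(m)
            if key not in self.first_order:
                raise KeyError(f"unknown mutation {key!r}")
            phi += self.first_order[key]
        for a, b in itertools.combinations(muts, 2):
            phi += self.couplings.get(_canon_pair(a, b), 0.0)
        return phi

    def _g(self, phi: np.ndarray | float) -> np.ndarray | float:
        L, U, s = self.sigmoid
        return L + (U - L) / (1.0 + np.exp(s * np.asarray(phi, dtype=float)))

    def growth_rate(self, mutations: Iterable[Mutation]) -> float:
        """Noise-free relative growth rate, centered so WT (phi=0) maps to 0."""
        return float(self._g(self.trait(mutations)) - self._g(0.0))

    def growth_rates(self, variants: Sequence[Variant]) -> np.ndarray:
        phi = np.array([self.trait(v.mutations) for v in variants])
        return np.asarray(self._g(phi) - self._g(0.0))

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        fo = pd.DataFrame(
            {"mutation": list(self.first_order), "ddg_act": list(self.first_order.values())}
        )
        cp = pd.DataFrame(
            [(a, b, v) for (a, b), v in self.couplings.items()],
            columns=["mut1", "mut2", "dddg_act"],
        )
        return fo, cp


def growth_rate_from_energy(
    landscape: GroundTruthLandscape, variant: Variant | Iterable[Mutation]
) -> float:
    """Noise-free relative growth rate of a variant under a true landscape."""
    muts = variant.mutations if isinstance(variant, Variant) else variant
    return landscape.growth_rate(muts)


def sample_landscape(
    designs: Sequence[LibraryDesign] | LibraryDesign,
    coupling_density: float = 0.1,
    seed: int = 0,
    frac_increase: float = 0.72,
    frac_decrease: float = 0.14,
    increase_scale: float = 0.6,
    decrease_scale: float = 0.25,
    coupling_scale: float = 0.6,
    sigmoid: tuple[float, float, float] = (-4.0, 0.0, 1.0),
) -> GroundTruthLandscape:
    """Draw a reproducible ground-truth landscape for the given designs.

    First-order effects come from a mixture mirroring the observed sign split:
    most substitutions raise the activation energy (gamma-distributed,
    mean ``2*increase_scale``), a minority lower it, and the remainder sit
    near zero. Couplings are placed on each co-mutable mutation pair with
    probability ``coupling_density`` and have heavy-tailed (Student-t, df=3)
    magnitudes so that most are small but a few are strong.
    """
    if not 0.0 <= coupling_density <= 1.0:
        raise ValueError("coupling_density must be in [0, 1]")
    if isinstance(designs, LibraryDesign):
        designs = [designs]
    rng = np.random.default_rng(seed)

    terms: dict[str, float] = {}
    for d in designs:
        for p in d.mutable_positions:
            wt = d.wt_residue(p)
            for a in sorted(d.alternatives(p)):
                key = str(Mutation(p, wt, a))
                if key in terms:
                    continue
                u = rng.uniform()
                if u < frac_increase:
                    terms[key] = float(rng.gamma(2.0, increase_scale))
                elif u < frac_increase + frac_decrease:
                    terms[key] = float(-rng.gamma(2.0, decrease_scale))
                else:
                    terms[key] = float(rng.normal(0.0, 0.05))

    couplings: dict[tuple[str, str], float] = {}
    seen_pairs: set[tuple[str, str]] = set()
    for d in designs:
        if d.max_order < 2:
            continue
        for p, q in itertools.combinations(d.mutable_positions, 2):
            for a in sorted(d.alternatives(p)):
                for b in sorted(d.alternatives(q)):
                    key = _canon_pair(
                        Mutation(p, d.wt_residue(p), a), Mutation(q, d.wt_residue(q), b)
                    )
                    if key in seen_pairs:
                        continue
                    seen_pairs.add(key)
                    if coupling_density > 0 and rng.uniform() < coupling_density:
                        couplings[key] = float(rng.standard_t(3) * coupling_scale)
    return GroundTruthLandscape(terms, couplings, sigmoid)


def simulate_selection(
    landscape: GroundTruthLandscape,
    variants: Sequence[Variant],
    depth: int,
    replicates: int = 3,
    overdispersion: float = 0.0,
    seed: int = 0,
    n_wt_synonyms: int = 0,
    composition_sigma: float = 0.5,
) -> pd.DataFrame:
    """Simulate input/output sequencing counts for a pooled selection.

    The library composition is a single log-normal draw shared by all
    replicates (one physical library); per-replicate input counts are
    multinomial at ``depth`` reads, and output counts are multinomial with
    weights proportional to composition times exp(GR) (optionally jittered by
    per-variant, per-replicate log-normal overdispersion). ``n_wt_synonyms``
    appends synonymous-WT entries (GR = 0) used downstream for centering.

    Returns a count table with columns ``variant``, ``mutations``,
    ``is_wt_synonym``, ``true_gr`` and ``input{r}``/``output{r}`` per replicate.
    """
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)

    names = [v.mutation_str or "WT" for v in variants]
    gr = landscape.growth_rates(variants)
    is_syn = [v.order == 0 for v in variants]
    for i in range(n_wt_synonyms):
        names.append(f"WTsyn{i + 1}")
        gr = np.append(gr, 0.0)
        is_syn.append(True)
    n = len(names)

    comp = rng.lognormal(mean=0.0, sigma=composition_sigma, size=n)
    comp /= comp.sum()

    rows: dict[str, np.ndarray] = {}
    for r in range(1, replicates + 1):
        rows[f"input{r}"] = rng.multinomial(depth, comp)
        w = comp * np.exp(gr)
        if overdispersion > 0:
            w = w * rng.lognormal(0.0, overdispersion, size=n)
        w /= w.sum()
        rows[f"output{r}"] = rng.multinomial(depth, w)

    df = pd.DataFrame(
        {
            "variant": names,
            "mutations": [nm if not syn else ("" if nm == "WT" else "") for nm, syn in zip(names, is_syn)],
            "is_wt_synonym": is_syn,
            "true_gr": gr,
            **rows,
        }
    )
    df.loc[~df["is_wt_synonym"], "mutations"] = df.loc[~df["is_wt_synonym"], "variant"]
    return df


def generate_stability_table(
    ddg_act: Mapping[str, float],
    structures: Sequence[tuple[str, int]] = (("FIX1", 4),),
    region: tuple[int, int] = APR2,
    correlation: float = 1.0,
    seed: int = 0,
    noise_loc: float = 2.0,
    noise_scale: float = 1.5,
) -> pd.DataFrame:
    """Surrogate per-mutation fibril-stability table (stands in for predicted
    assembly energies from a structure-based force field).

    Inside ``region`` the per-monomer stability change equals
    ``correlation * ddg_act + sqrt(1-correlation^2) * noise``, so with
    ``correlation=1`` the downstream activation/stability ratio is exactly 1
    there; outside the region values are independent of the activation
    energies. Assembly values are per-monomer times the chain count.
    """
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    recs = []
    for struct, n_chains in structures:
        for key, act in ddg_act.items():
            pos = Mutation.parse(key).position
            noise = rng.normal(noise_loc, noise_scale)
            if region[0] <= pos <= region[1]:
                per_monomer = correlation * act + math.sqrt(1 - correlation**2) * noise
            else:
                per_monomer = noise
            recs.append(
                {
                    "structure": struct,
                    "mutation": key,
                    "assembly_ddg": per_monomer * n_chains,
                    "n_chains": n_chains,
                }
            )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# PDB structure fixtures
# ---------------------------------------------------------------------------

#: atoms emitted per residue in fixtures: backbone N/CA/C/O plus one
#: side-chain pseudo-atom (CB) except glycine (CA only).
_BACKBONE_OFFSETS = {
    "N": (-1.2, -0.6, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.2, -0.6, 0.0),
    "O": (1.2, -1.8, 0.0),
}


@dataclass(frozen=True)
class AtomSpec:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass(frozen=True)
class ResidueSpec:
    chain: str
    number: int
    aa: str  # one-letter
    atoms: tuple[AtomSpec, ...]


def build_pdb(residues: Sequence[ResidueSpec], structure_id: str = "FIX1") -> str:
    """Render residue specifications as minimal PDB-format text."""
    if not residues:
        raise ValueError("no residues given")
    seen: set[tuple[str, int]] = set()
    lines = [f"HEADER    SYNTHETIC FIXTURE {structure_id}"]
    serial = 1
    for res in residues:
        key = (res.chain, res.number)
        if key in seen:
            raise ValueError(f"duplicate residue {key}")
        seen.add(key)
        resname = protein_letters_1to3[res.aa].upper()
        if not res.atoms:
            raise ValueError(f"residue {key} has no atoms")
        for atom in res.atoms:
            x, y, z = atom.xyz
            if not all(math.isfinite(c) for c in (x, y, z)):
                raise ValueError(f"non-finite coordinate in residue {key}")
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:4s} {resname:3s} {res.chain}"
                f"{res.number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _residue_at(
    chain: str, number: int, aa: str, ca: tuple[float, float, float], sc_up: float = 1.6
) -> ResidueSpec:
    cx, cy, cz = ca
    atoms = [
        AtomSpec(n, "O" if n == "O" else ("N" if n == "N" else "C"),
                 (cx + dx, cy + dy, cz + dz))
        for n, (dx, dy, dz) in _BACKBONE_OFFSETS.items()
    ]
    if aa != "G":
        atoms.append(AtomSpec("CB", "C", (cx, cy, cz + sc_up)))
        atoms.append(AtomSpec("CG", "C", (cx, cy, cz + sc_up + 1.4)))
    return ResidueSpec(chain, number, aa, tuple(atoms))


def generate_fixture_structure(
    residues: Sequence[ResidueSpec] | None = None,
    *,
    sequence: str | None = None,
    ca_coords: Mapping[int, tuple[float, float, float]] | None = None,
    chain: str = "A",
    structure_id: str = "FIX1",
) -> str:
    """Build PDB text from explicit residue specs, or from a sequence plus
    per-position CA coordinates (backbone and a CB/CG side-chain stub are
    placed automatically; glycine gets CA only)."""
    if residues is None:
        if sequence is None or ca_coords is None:
            raise ValueError("provide residues, or sequence plus ca_coords")
        residues = [
            _residue_at(chain, pos, sequence[pos - 1], xyz)
            for pos, xyz in sorted(ca_coords.items())
        ]
    return build_pdb(residues, structure_id)


def serpentine_fixture(
    sequence: str = AB42,
    row_length: int = 10,
    col_spacing: float = 4.8,
    row_spacing: float = 7.5,
    chains: Sequence[str] = ("A",),
    chain_offset: float = 20.0,
    structure_id: str = "FIX1",
) -> str:
    """An idealized serpentine (snaking) fold used as a fibril-like fixture.

    Residues run along rows of ``row_length`` positions, reversing direction
    each row, so sequence neighbours and vertical cross-row neighbours form
    side-chain contacts while everything else is well separated. Additional
    chains are stacked along z at ``chain_offset`` to emulate facing filaments
    for dimer-mode distance analysis.
    """
    residues: list[ResidueSpec] = []
    for ci, ch in enumerate(chains):
        z0 = ci * chain_offset
        for i, aa in enumerate(sequence):
            row, col = divmod(i, row_length)
            if row % 2 == 1:
                col = row_length - 1 - col
            ca = (col * col_spacing, row * row_spacing, z0)
            residues.append(_residue_at(ch, i + 1, aa, ca))
    return build_pdb(residues, structure_id)


def stability_table_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Attach per-monomer values to a stability table frame."""
    out = df.copy()
    out["per_monomer_ddg"] = out["assembly_ddg"] / out["n_chains"]
    return out
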