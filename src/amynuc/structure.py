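"""Fibril structure parsing and minimal side-chain heavy-atom distances.

The structural comparator for energetic couplings is scHA_min: for two
residues, the minimum Euclidean distance over all pairs of heavy (non-
hydrogen) side-chain atoms, one from each residue. Side chain means every
heavy atom beyond and including C-beta; glycine, having no side chain,
contributes its C-alpha. Distances are computed within one chain (monomer
mode) or across two facing chains (dimer mode, minimized over both
assignments of positions to chains).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

__all__ = [
    "DistanceMatrix",
    "StructureModel",
    "contact_map",
    "distance_matrix",
    "parse_structure",
    "schamin_distance",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass
class ResidueAtoms:
    position: int
    resname: str
    sidechain: np.ndarray  # (n_atoms, 3) designated heavy atoms
    flagged: bool = False  # missing side-chain atoms


@dataclass
class StructureModel:
    structure_id: str
    chains: dict[str, dict[int, ResidueAtoms]]
    flagged: list[tuple[str, int]] = field(default_factory=list)

    def chain(self, chain_id: str) -> dict[int, ResidueAtoms]:
        if chain_id not in self.chains:
            raise KeyError(
                f"chain {chain_id!r} not in structure {self.structure_id!r}; "
                f"available: {sorted(self.chains)}"
            )
        return self.chains[chain_id]


def parse_structure(
    source: str | Path,
    chains: list[str] | None = None,
    offset: int = 0,
    structure_id: str = "structure",
) -> StructureModel:
    """Parse PDB text or a PDB file into per-residue side-chain atom sets.

    ``offset`` is added to deposited residue numbers to align them to the
    1-based WT numbering (deposited fibril structures often start
    mid-sequence). Hydrogens are excluded; for disordered atoms the parser's
    selected (highest-occupancy) conformer is used. Residues without any
    designated atom are flagged rather than dropped silently.
    """
    text = str(source)
    if "\n" in text or text.lstrip().startswith(("HEADER", "ATOM", "MODEL")):
        handle: io.StringIO | str = io.StringIO(text)
    else:
        handle = str(Path(source))
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(structure_id, handle)
    model = next(structure.get_models())

    available = [c.id for c in model]
    wanted = chains if chains is not None else available
    out: dict[str, dict[int, ResidueAtoms]] = {}
    flagged: list[tuple[str, int]] = []
    for cid in wanted:
        if cid not in available:
            raise KeyError(
                f"chain {cid!r} not found in {structure_id!r}; available chains: {available}"
            )
        residues: dict[int, ResidueAtoms] = {}
        for res in model[cid]:
            if res.id[0] != " ":  # skip hetero/water
                continue
            pos = res.id[1] + offset
            resname = res.get_resname().strip()
            coords = []
            for atom in res:
                if atom.element == "H" or atom.get_name().startswith("H"):
                    continue
                name = atom.get_name()
                if resname == "GLY":
                    if name == "CA":
                        coords.append(atom.get_coord())
                elif name not in _BACKBONE:
                    coords.append(atom.get_coord())
            is_flagged = len(coords) == 0
            if is_flagged:
                flagged.append((cid, pos))
            residues[pos] = ResidueAtoms(
                position=pos,
                resname=resname,
                sidechain=np.array(coords, dtype=float).reshape(-1, 3),
                flagged=is_flagged,
            )
        out[cid] = residues
    return StructureModel(structure_id=structure_id, chains=out, flagged=flagged)


def schamin_distance(res_i: ResidueAtoms, res_j: ResidueAtoms) -> float:
    """Minimal side-chain heavy-atom distance between two residues (angstrom)."""
    if res_i.sidechain.size == 0 or res_j.sidechain.size == 0:
        raise ValueError(
            f"residue {res_i.position} or {res_j.position} has no designated atoms"
        )
    return float(cdist(res_i.sidechain, res_j.sidechain).min())


@dataclass
class DistanceMatrix:
    structure_id: str
    mode: str  # "monomer" | "dimer"
    positions: list[int]
    values: np.ndarray  # square, symmetric

    def get(self, i: int, j: int) -> float:
        a, b = self.positions.index(i), self.positions.index(j)
        return float(self.values[a, b])

    def to_long(self) -> pd.DataFrame:
        rows = []
        for a, i in enumerate(self.positions):
            for b, j in enumerate(self.positions):
                if b <= a:
                    continue
                rows.append(
                    {
                        "pos_i": i,
                        "pos_j": j,
                        "schamin": float(self.values[a, b]),
                        "mode": self.mode,
                        "structure": self.structure_id,
                    }
                )
        return pd.DataFrame(rows)


def distance_matrix(
    model: StructureModel,
    mode: str = "monomer",
    chain: str | None = None,
    chain_pair: tuple[str, str] | None = None,
) -> DistanceMatrix:
    """All-vs-all scHA_min for one chain (monomer) or two facing chains (dimer).

    In dimer mode the entry for positions (i, j) is the minimum over both
    cross-chain assignments, min(d(A_i, B_j), d(B_i, A_j)); the diagonal is
    the cross-chain self distance, so it need not be zero.
    """
    if mode == "monomer":
        if chain is None:
            if len(model.chains) != 1:
                raise ValueError("monomer mode needs a single chain; pass chain=")
            chain = next(iter(model.chains))
        residues = model.chain(chain)
        positions = sorted(p for p, r in residues.items() if not r.flagged)
        n = len(positions)
        vals = np.zeros((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                d = schamin_distance(residues[positions[a]], residues[positions[b]])
                vals[a, b] = vals[b, a] = d
        return DistanceMatrix(model.structure_id, "monomer", positions, vals)
    if mode == "dimer":
        if chain_pair is None:
            if len(model.chains) != 2:
                raise ValueError("dimer mode needs two chains; pass chain_pair=")
            chain_pair = tuple(sorted(model.chains))  # type: ignore[assignment]
        ca, cb = chain_pair
        ra, rb = model.chain(ca), model.chain(cb)
        positions = sorted(
            p
            for p in set(ra) & set(rb)
            if not ra[p].flagged and not rb[p].flagged
        )
        n = len(positions)
        vals = np.zeros((n, n))
        for a in range(n):
            for b in range(a, n):
                i, j = positions[a], positions[b]
                d = min(
                    schamin_distance(ra[i], rb[j]),
                    schamin_distance(rb[i], ra[j]),
                )
                vals[a, b] = vals[b, a] = d
        return DistanceMatrix(model.structure_id, "dimer", positions, vals)
    raise ValueError(f"unknown mode {mode!r}; expected 'monomer' or 'dimer'")


def contact_map(matrix: DistanceMatrix, threshold: float = 8.0) -> pd.DataFrame:
    """Boolean contact table: contact iff scHA_min strictly below ``threshold``."""
    df = matrix.to_long()
    df["contact"] = df["schamin"] < threshold
    df["threshold"] = threshold
    return df
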