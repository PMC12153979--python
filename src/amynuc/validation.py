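"""End-to-end recovery experiments on synthetic ground truth.

These are the package's self-checks: simulate selections from a known
landscape under the library designs, run the full inference chain, and
measure how well the known energies come back. They are used by the test
suite and the reproduction script; sizes are scaled (all singles plus a
random subset of doubles per scan; a few thousand combinatorial genotypes)
so a run takes minutes on one CPU.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from amynuc.energy_model import add_reference_variant, fit_energy_model
from amynuc.enrichment import process_counts
from amynuc.library_design import Mutation, enumerate_variants, paper_designs
from amynuc.couplings import correlate_with_distance, interaction_scores, top_pairs
from amynuc.structure import distance_matrix, parse_structure
from amynuc.synthetic import (
    _canon_pair,
    sample_landscape,
    serpentine_fixture,
    simulate_selection,
)

__all__ = [
    "combinatorial_recovery",
    "double_mutant_recovery",
    "structure_pipeline_check",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def double_mutant_recovery(
    seed: int = 0,
    doubles_per_library: Sequence[int] = (2000, 1200, 1200),
    reads_per_variant: int = 150,
    replicates: int = 3,
    folds: int = 10,
) -> dict:
    """First-order recovery across the three double-mutant scan designs.

    Simulates the shallow, N-terminal and C-terminal scans (all singles plus
    a random subset of doubles each) from one additive landscape, runs
    counts -> growth rates -> joint sigmoid fit, and reports the Pearson
    correlation between fitted and true first-order terms.
    """
    designs = paper_designs()
    scans = [designs["shallow"], designs["nterm"], designs["cterm"]]
    seeds = _child_seeds(seed, 2 * len(scans) + 1)
    landscape = sample_landscape(scans, coupling_density=0.0, seed=seeds[0])

    frames = []
    rng = np.random.default_rng(seeds[1])
    for i, (design, n_doubles) in enumerate(zip(scans, doubles_per_library)):
        singles = [v for v in enumerate_variants(design, 1)]
        doubles = [v for v in enumerate_variants(design, 2) if v.order == 2]
        if len(doubles) > n_doubles:
            idx = rng.choice(len(doubles), size=n_doubles, replace=False)
            doubles = [doubles[j] for j in sorted(idx)]
        variants = enumerate_variants(design, 0) + singles + doubles
        counts = simulate_selection(
            landscape,
            variants,
            depth=reads_per_variant * len(variants),
            replicates=replicates,
            seed=seeds[2 + i],
            n_wt_synonyms=3,
        )
        growth = process_counts(counts)
        frames.append(growth[["variant", "mutations", "is_wt_synonym", "gr", "sigma"]])
    table = pd.concat(frames, ignore_index=True)

    model, report = fit_energy_model(table, order=1, folds=folds, seed=seeds[-1])
    common = [k for k in model.first_order if k in landscape.first_order]
    est = np.array([model.first_order[k] for k in common])
    true = np.array([landscape.first_order[k] for k in common])
    r = float(pearsonr(est, true).statistic)
    return {
        "pearson_r": r,
        "n_terms": len(common),
        "n_variants": int(report.n_variants),
        "cv_r2": float(report.r2),
        "model": model,
        "landscape": landscape,
    }


def combinatorial_recovery(
    seed: int = 0,
    n_genotypes: int = 3000,
    n_planted: int = 5,
    coupling_magnitude: tuple[float, float] = (1.2, 2.0),
    reads_per_variant: int = 150,
    replicates: int = 3,
    folds: int = 10,
) -> dict:
    """Coupling recovery and order-1 vs order-2 CV comparison on a
    combinatorial library.

    Plants ``n_planted`` strong couplings (|value| above 1 kcal/mol, random
    signs) on distinct position pairs of the 6-position combinatorial design,
    simulates a random subset of genotypes, and fits both model orders. With
    ``n_planted=0`` the same experiment measures the null behaviour (the
    order-2 model should not beat order-1 out of sample).
    """
    design = paper_designs()["comb2"]
    seeds = _child_seeds(seed, 4)
    landscape = sample_landscape(
        design,
        coupling_density=0.0,
        seed=seeds[0],
        frac_increase=0.6,
        frac_decrease=0.25,
        increase_scale=0.35,
    )
    rng = np.random.default_rng(seeds[1])
    positions = design.mutable_positions
    pos_pairs = list(itertools.combinations(positions, 2))
    chosen = rng.choice(len(pos_pairs), size=n_planted, replace=False) if n_planted else []
    for pi in chosen:
        p, q = pos_pairs[pi]
        a = str(rng.choice(sorted(design.alternatives(p))))
        b = str(rng.choice(sorted(design.alternatives(q))))
        key = _canon_pair(
            Mutation(p, design.wt_residue(p), a), Mutation(q, design.wt_residue(q), b)
        )
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        landscape.couplings[key] = float(sign * rng.uniform(*coupling_magnitude))

    variants = [v for v in enumerate_variants(design, design.max_order) if v.order > 0]
    idx = rng.choice(len(variants), size=min(n_genotypes, len(variants)), replace=False)
    variants = [variants[i] for i in sorted(idx)]
    counts = simulate_selection(
        landscape,
        variants,
        depth=reads_per_variant * len(variants),
        replicates=replicates,
        seed=seeds[2],
    )
    growth = process_counts(counts, reference=str(counts["variant"].iloc[0]), center=False)
    growth = add_reference_variant(growth)

    m1, r1 = fit_energy_model(growth, order=1, folds=folds, seed=seeds[3])
    m2, r2 = fit_energy_model(growth, order=2, folds=folds, seed=seeds[3])

    signs_ok = []
    est_planted = []
    true_planted = []
    for key, tv in landscape.couplings.items():
        ev = m2.couplings.get(key)
        if ev is None:
            signs_ok.append(False)
            continue
        est_planted.append(ev)
        true_planted.append(tv)
        signs_ok.append(np.sign(ev) == np.sign(tv))
    return {
        "r2_order1": float(r1.r2),
        "r2_order2": float(r2.r2),
        "n_planted": int(n_planted),
        "sign_agreement": float(np.mean(signs_ok)) if signs_ok else float("nan"),
        "planted_true": true_planted,
        "planted_est": est_planted,
        "n_genotypes": len(growth),
        "model_order2": m2,
        "landscape": landscape,
    }


def structure_pipeline_check(
    seed: int = 0,
    strong_magnitude: tuple[float, float] = (1.5, 2.5),
    contact_magnitude: tuple[float, float] = (0.5, 0.8),
    background_sd: float = 0.0,
    n_strong: int = 4,
    percentile: float = 90.0,
) -> dict:
    """Structure pipeline property: couplings planted only on side-chain
    contacts of a fixture structure must light up in the distance analysis.

    Builds the serpentine fibril-like fixture, computes scHA_min among the 40
    co-mutable position pairs of the joint combinatorial designs, plants
    strong couplings on the ``n_strong`` closest contact pairs and moderate
    ones on the remaining sub-8-angstrom contacts (16 couplings per pair,
    random signs; near-zero background elsewhere), then checks the
    interaction-score / inverse-distance rank correlation and the top-pair
    extraction.
    """
    rng = np.random.default_rng(seed)
    designs = paper_designs()
    comb1, comb2 = designs["comb1"], designs["comb2"]

    pdb = serpentine_fixture(chains=("A",))
    struct = parse_structure(pdb, chains=["A"], structure_id="FIX1")
    dm = distance_matrix(struct, mode="monomer", chain="A")

    pair_alts: dict[tuple[int, int], tuple] = {}
    for design in (comb1, comb2):
        for p, q in itertools.combinations(design.mutable_positions, 2):
            key = (min(p, q), max(p, q))
            if key not in pair_alts:
                pair_alts[key] = (
                    sorted(design.alternatives(key[0])),
                    sorted(design.alternatives(key[1])),
                )
    pairs = sorted(pair_alts)
    dists = {pr: dm.get(*pr) for pr in pairs}
    contacts = sorted((pr for pr in pairs if dists[pr] < 8.0), key=lambda pr: dists[pr])
    strong = contacts[:n_strong]

    wt = comb1.sequence
    couplings: dict[tuple[str, str], float] = {}
    for pr in pairs:
        alts_i, alts_j = pair_alts[pr]
        if pr in strong:
            lo, hi = strong_magnitude
        elif pr in contacts:
            lo, hi = contact_magnitude
        else:
            lo = hi = None
        for a in alts_i:
            for b in alts_j:
                key = _canon_pair(
                    Mutation(pr[0], wt[pr[0] - 1], a), Mutation(pr[1], wt[pr[1] - 1], b)
                )
                if lo is None:
                    couplings[key] = float(rng.normal(0.0, background_sd))
                else:
                    sign = 1.0 if rng.uniform() < 0.5 else -1.0
                    couplings[key] = float(sign * rng.uniform(lo, hi))

    scores = interaction_scores(couplings)
    corr = correlate_with_distance(scores, dm)
    tp = top_pairs(scores, percentile)
    top_set = {(int(r.pos_i), int(r.pos_j)) for r in tp.itertuples()}
    return {
        "rho": corr.rho,
        "p_value": corr.p_value,
        "n_pairs": corr.n,
        "n_contacts": len(contacts),
        "strong_pairs": set(strong),
        "top_pairs": top_set,
        "top_matches_planted": top_set == set(strong),
        "scores": scores,
        "distances": dm,
    }
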