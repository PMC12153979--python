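"""Pipeline orchestration: fixture bundles and staged end-to-end runs.

``make_fixtures`` writes a complete synthetic dataset bundle (designs,
ground-truth landscape, selection counts, kinetic rates, stability tables,
fixture structure). ``run_pipeline`` executes the analysis stages in
dependency order over such a bundle and records a manifest with the seed,
config hash and inputs, so a rerun with the same seed reproduces every
numeric artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from amynuc import __version__
from amynuc.calibration import (
    apply_calibration,
    fit_calibration,
    rates_table_to_ddg,
)
from amynuc.constants import AB42, APR2, T_KELVIN, R_KCAL
from amynuc.couplings import correlate_with_distance, interaction_scores, top_pairs
from amynuc.energy_model import add_reference_variant, fit_energy_model, significance_terms
from amynuc.enrichment import process_counts
from amynuc.io import read_tsv, write_tsv
from amynuc.library_design import LibraryDesign, enumerate_variants, paper_designs
from amynuc.stability import compute_ratios, position_mean_ratios, rank_polymorphs
from amynuc.structure import contact_map, distance_matrix, parse_structure
from amynuc.synthetic import (
    sample_landscape,
    serpentine_fixture,
    simulate_selection,
    generate_stability_table,
)

__all__ = ["make_fixtures", "run_pipeline", "validate_config"]

log = logging.getLogger(__name__)

_REQUIRED_KEYS = ("outdir", "seed")


def _config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    for key in _REQUIRED_KEYS:
        if key not in config:
            raise ValueError(f"pipeline config missing required field {key!r}")
    config.setdefault("order", 2)
    config.setdefault("lam", 1e-5)
    config.setdefault("folds", 10)
    config.setdefault("min_input_reads", 10)
    config.setdefault("ddg_bounds", [0.6, 10.0])
    config.setdefault("contact_threshold", 8.0)
    config.setdefault("scale", "demo")
    return config


def _demo_design(seed: int) -> LibraryDesign:
    # C-terminal-like double-mutant scan, subset of positions to stay small
    return LibraryDesign.from_scheme("demo", range(31, 43), "NNK", AB42, max_order=2)


def make_fixtures(outdir: str | Path, seed: int = 0, scale: str = "demo") -> dict[str, Path]:
    """Write a synthetic dataset bundle sufficient for an end-to-end run.

    ``scale='demo'`` simulates one reduced double-mutant scan plus a reduced
    combinatorial library (a few thousand variants); ``scale='paper-shaped'``
    writes all five library designs at reduced depth (singles plus a random
    subset of doubles for the scans).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    meta = {"seed": seed, "scale": scale, "version": __version__}

    if scale == "demo":
        designs = {"demo": _demo_design(seed), "comb2": paper_designs()["comb2"]}
        doubles_cap = {"demo": 2000}
    elif scale == "paper-shaped":
        designs = paper_designs()
        doubles_cap = {"shallow": 2500, "nterm": 1500, "cterm": 1500}
    else:
        raise ValueError(f"unknown scale {scale!r}")

    landscape = sample_landscape(
        list(designs.values()), coupling_density=0.02, seed=int(rng.integers(2**31))
    )
    fo, cp = landscape.to_frames()
    paths["landscape_first_order"] = write_tsv(fo, outdir / "landscape_first_order.tsv", meta)
    paths["landscape_couplings"] = write_tsv(cp, outdir / "landscape_couplings.tsv", meta)

    for name, design in designs.items():
        if design.is_combinatorial:
            # the selected combinatorial pools lack the WT genotype; it is
            # added back artificially (GR 0, big error) before model fitting
            variants = [v for v in enumerate_variants(design, design.max_order) if v.order > 0]
            if len(variants) > 4000:
                idx = rng.choice(len(variants), size=4000, replace=False)
                variants = [variants[i] for i in sorted(idx)]
            n_syn = 0
        else:
            singles = enumerate_variants(design, 1)
            doubles = [
                v for v in enumerate_variants(design, 2) if v.order == 2
            ]
            cap = doubles_cap.get(name, 2000)
            if len(doubles) > cap:
                idx = rng.choice(len(doubles), size=cap, replace=False)
                doubles = [doubles[i] for i in sorted(idx)]
            variants = [v for v in singles if v.order == 1] + doubles
            variants.insert(0, enumerate_variants(design, 0)[0])
            n_syn = 3
        counts = simulate_selection(
            landscape,
            variants,
            depth=max(150 * len(variants), 10_000),
            replicates=3,
            seed=int(rng.integers(2**31)),
            n_wt_synonyms=n_syn,
        )
        paths[f"counts_{name}"] = write_tsv(counts, outdir / f"counts_{name}.tsv", meta)

    # kinetic rates table: invert transition-state theory on a few singles
    fo_map = dict(zip(fo["mutation"], fo["ddg_act"]))
    picks = sorted(fo_map)[:: max(1, len(fo_map) // 8)][:8]
    k_wt = 1.0
    rates = [{"variant": "WT", "kn": k_wt, "k2": k_wt}]
    for m in picks:
        k = k_wt * math.exp(-fo_map[m] / (R_KCAL * T_KELVIN))
        rates.append({"variant": m, "kn": k, "k2": k})
    import pandas as pd

    paths["rates"] = write_tsv(pd.DataFrame(rates), outdir / "rates.tsv", meta)

    stab = generate_stability_table(
        fo_map,
        structures=(("FIX1", 4), ("FIX2", 3)),
        region=APR2,
        correlation=0.9,
        seed=int(rng.integers(2**31)),
    )
    paths["stability"] = write_tsv(stab, outdir / "stability.tsv", meta)

    pdb_text = serpentine_fixture(chains=("A", "B"))
    pdb_path = outdir / "fixture.pdb"
    pdb_path.write_text(pdb_text)
    paths["structure"] = pdb_path
    return paths


def run_pipeline(config: dict[str, Any] | str | Path) -> dict[str, Any]:
    """Run fixture generation and all analysis stages per a config mapping.

    Stages: counts -> growth rates -> model fit -> calibration -> ratios &
    couplings -> structure comparison. Returns a manifest dict (also written
    to ``<outdir>/manifest.json``).
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    config = validate_config(config)
    outdir = Path(config["outdir"])
    seed = int(config["seed"])
    chash = _config_hash(config)
    meta = {"seed": seed, "config_hash": chash, "version": __version__}
    manifest: dict[str, Any] = {"config": config, "config_hash": chash, "version": __version__, "stages": {}}

    paths = make_fixtures(outdir / "fixtures", seed=seed, scale=config["scale"])
    manifest["stages"]["fixtures"] = {k: str(v) for k, v in paths.items()}

    # growth rates + fit per library
    double_models = {}
    comb_result = None
    for counts_key in [k for k in paths if k.startswith("counts_")]:
        name = counts_key.removeprefix("counts_")
        counts = read_tsv(paths[counts_key])
        is_comb = name.startswith("comb")
        has_wt = bool((counts["variant"] == "WT").any())
        growth = process_counts(
            counts,
            reference=None if has_wt else str(counts["variant"].iloc[0]),
            min_input_reads=config["min_input_reads"],
        )
        write_tsv(growth, outdir / f"growth_{name}.tsv", meta)
        if is_comb:
            growth = add_reference_variant(growth)
            model, report = fit_energy_model(
                growth, order=config["order"], lam=config["lam"], folds=config["folds"], seed=seed
            )
            comb_result = (name, model, report)
        else:
            model, report = fit_energy_model(
                growth, order=1, lam=config["lam"], folds=config["folds"], seed=seed
            )
            double_models[name] = (model, report)
        write_tsv(model.to_frame(), outdir / f"terms_{name}.tsv", meta)
        manifest["stages"][f"fit_{name}"] = {"r2": report.r2, "n": report.n_variants}

    # calibration on the first double-mutant model
    if double_models:
        name, (model, report) = next(iter(double_models.items()))
        rates = read_tsv(paths["rates"])
        ddg = rates_table_to_ddg(rates)
        shared = [m for m in ddg["variant"] if m in model.first_order]
        if len(shared) >= 2:
            traits = [model.first_order[m] for m in shared]
            exp = ddg.set_index("variant").loc[shared, "ddg_exp"].tolist()
            cal = fit_calibration(traits, exp)
            calibrated = apply_calibration(model, cal)
            write_tsv(calibrated.to_frame(), outdir / f"terms_{name}_kcal.tsv", meta)
            sig = significance_terms(calibrated, report)
            write_tsv(sig, outdir / f"significance_{name}.tsv", meta)
            manifest["stages"]["calibration"] = {"slope": cal.slope, "n": cal.n}

            # ratio analysis against surrogate stability tables
            stab = read_tsv(paths["stability"])
            ratios = compute_ratios(
                calibrated.first_order, stab,
                lower=config["ddg_bounds"][0], upper=config["ddg_bounds"][1],
            )
            write_tsv(ratios, outdir / "ratios.tsv", meta)
            write_tsv(position_mean_ratios(ratios), outdir / "ratios_by_position.tsv", meta)
            ranked = rank_polymorphs(ratios, region=APR2)
            write_tsv(ranked, outdir / "polymorph_ranking.tsv", meta)
            manifest["stages"]["ratios"] = {"best_structure": ranked.iloc[0]["structure"]}

    # couplings vs structure
    if comb_result is not None:
        name, model, report = comb_result
        if model.couplings:
            scores = interaction_scores(model.couplings)
            write_tsv(scores, outdir / "interaction_scores.tsv", meta)
            struct = parse_structure(paths["structure"], chains=["A"], structure_id="FIX1")
            dm = distance_matrix(struct, mode="monomer", chain="A")
            write_tsv(dm.to_long(), outdir / "distances.tsv", meta)
            write_tsv(contact_map(dm, config["contact_threshold"]), outdir / "contacts.tsv", meta)
            corr = correlate_with_distance(scores, dm)
            tp = top_pairs(scores)
            write_tsv(tp, outdir / "top_pairs.tsv", meta)
            manifest["stages"]["couplings"] = {
                "rho": corr.rho, "p": corr.p_value, "n_pairs": int(len(scores)),
                "top_pairs": [f"{int(r.pos_i)}-{int(r.pos_j)}" for r in tp.itertuples()],
            }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
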