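"""Variant counts -> relative growth rates with Poisson error estimates.

Mirrors standard DMS count processing: per-replicate enrichment scores are
log frequency ratios (0.5 pseudocount on raw counts), growth rates are
enrichment scores relative to a reference (WT or a designated variant),
errors are Poisson counting terms for variant and reference, replicates are
merged by inverse-variance weighting, and the merged table is centered on the
error-weighted mean of WT-synonymous variants.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

__all__ = [
    "count_error",
    "enrichment_scores",
    "filter_counts",
    "merge_replicates",
    "process_counts",
    "replicate_labels",
    "scale_unit_interval",
]

log = logging.getLogger(__name__)

_COUNT_RE = re.compile(r"^(input|output)(\d+)$")


def replicate_labels(table: pd.DataFrame) -> list[int]:
    """Replicate indices present as input{r}/output{r} column pairs."""
    ins = {int(m.group(2)) for c in table.columns if (m := _COUNT_RE.match(c)) and m.group(1) == "input"}
    outs = {int(m.group(2)) for c in table.columns if (m := _COUNT_RE.match(c)) and m.group(1) == "output"}
    reps = sorted(ins & outs)
    if not reps:
        raise ValueError("no input{r}/output{r} column pairs found")
    if ins != outs:
        raise ValueError(f"unpaired replicate columns: inputs {sorted(ins)} vs outputs {sorted(outs)}")
    return reps


def filter_counts(table: pd.DataFrame, min_input_reads: int = 10) -> pd.DataFrame:
    """Drop variants with fewer than ``min_input_reads`` input reads in ANY replicate.

    The boundary is inclusive: exactly ``min_input_reads`` reads is retained.
    Removals are logged and recorded in ``table.attrs['filter_log']``.
    """
    if table.empty:
        raise ValueError("empty count table")
    reps = replicate_labels(table)
    keep = np.ones(len(table), dtype=bool)
    for r in reps:
        keep &= table[f"input{r}"].to_numpy() >= min_input_reads
    removed = table.loc[~keep, "variant"].tolist()
    if removed:
        log.info("filter_counts: removed %d variants below %d input reads", len(removed), min_input_reads)
    out = table.loc[keep].reset_index(drop=True)
    out.attrs["filter_log"] = {"min_input_reads": min_input_reads, "removed": removed}
    return out


def _reference_index(table: pd.DataFrame, reference: str | None) -> int:
    if reference is None:
        mask = (table.get("mutations", pd.Series("", index=table.index)).fillna("") == "") | (
            table["variant"] == "WT"
        )
        # prefer the row literally named WT over synonyms
        named = table.index[table["variant"] == "WT"]
        if len(named):
            return int(named[0])
        idx = table.index[mask]
        if len(idx) == 0:
            raise ValueError("no WT reference found; pass reference=<variant id>")
        return int(idx[0])
    idx = table.index[table["variant"] == reference]
    if len(idx) == 0:
        raise ValueError(f"reference variant {reference!r} not present in table")
    return int(idx[0])


def enrichment_scores(
    table: pd.DataFrame, reference: str | None = None, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-replicate enrichment scores and WT-relative growth rates.

    ES_r = ln((n_out + c)/depth_out) - ln((n_in + c)/depth_in);
    GR_r = ES_r - ES_r(reference). Pool depths cancel in GR, which is the
    quantity all downstream stages consume. Natural log throughout.
    """
    reps = replicate_labels(table)
    out = table.copy()
    ref = _reference_index(out, reference)
    for r in reps:
        n_in = out[f"input{r}"].to_numpy(dtype=float) + pseudocount
        n_out = out[f"output{r}"].to_numpy(dtype=float) + pseudocount
        es = np.log(n_out / n_out.sum()) - np.log(n_in / n_in.sum())
        out[f"es{r}"] = es
        out[f"gr{r}"] = es - es[ref]
    out.attrs["reference_index"] = ref
    return out


def count_error(
    table: pd.DataFrame, reference: str | None = None, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-replicate Poisson counting error for each WT-relative growth rate.

    sigma^2 = 1/(n_in+c) + 1/(n_out+c) + 1/(ref_in+c) + 1/(ref_out+c).
    """
    reps = replicate_labels(table)
    out = table.copy()
    ref = _reference_index(out, reference)
    for r in reps:
        n_in = out[f"input{r}"].to_numpy(dtype=float) + pseudocount
        n_out = out[f"output{r}"].to_numpy(dtype=float) + pseudocount
        var = 1.0 / n_in + 1.0 / n_out + 1.0 / n_in[ref] + 1.0 / n_out[ref]
        out[f"sigma{r}"] = np.sqrt(var)
    return out


def merge_replicates(table: pd.DataFrame, center: bool = True) -> pd.DataFrame:
    """Inverse-variance weighted merge across replicates, then WT-synonym centering.

    merged GR = sum(GR_r / sigma_r^2) / sum(1 / sigma_r^2);
    merged sigma = sqrt(1 / sum(1 / sigma_r^2)). If ``center`` and the table
    flags WT synonyms, all merged GR are shifted so the error-weighted mean
    over synonyms is exactly 0.
    """
    reps = replicate_labels(table)
    gr = np.column_stack([table[f"gr{r}"].to_numpy(dtype=float) for r in reps])
    sig = np.column_stack([table[f"sigma{r}"].to_numpy(dtype=float) for r in reps])
    w = 1.0 / sig**2
    wsum = w.sum(axis=1)
    merged = (gr * w).sum(axis=1) / wsum
    merged_sigma = np.sqrt(1.0 / wsum)

    out = table.copy()
    out["gr"] = merged
    out["sigma"] = merged_sigma
    shift = 0.0
    syn = out.get("is_wt_synonym")
    if center and syn is not None and bool(syn.any()):
        mask = syn.to_numpy(dtype=bool)
        wts = 1.0 / merged_sigma[mask] ** 2
        shift = float(np.sum(merged[mask] * wts) / np.sum(wts))
        out["gr"] = merged - shift
    out.attrs["centering_shift"] = shift
    return out


def scale_unit_interval(values: pd.Series | np.ndarray) -> np.ndarray:
    """Affine map of merged growth rates onto [0, 1]; visualization only."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if not hi > lo:
        raise ValueError("cannot scale a constant series to the unit interval")
    return (v - lo) / (hi - lo)


def process_counts(
    table: pd.DataFrame,
    reference: str | None = None,
    min_input_reads: int = 10,
    pseudocount: float = 0.5,
    center: bool = True,
) -> pd.DataFrame:
    """Full count-table pipeline: filter -> ES/GR -> errors -> merged table."""
    t = filter_counts(table, min_input_reads)
    t = enrichment_scores(t, reference, pseudocount)
    t = count_error(t, reference, pseudocount)
    return merge_replicates(t, center=center)
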