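"""Knockout-control differential enrichment statistics.

The chain implemented here: identification-quality (razor+unique) filter,
log2 transform with per-sample mean centering, downshifted imputation of
missing values, input-normalized wildtype-vs-knockout fold change per
antibody column, a paired t-test across columns, and the three-criterion
enrichment call (average fold change > 1.5, p <= 0.05, detected in at
least two wildtype eluates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import GENOTYPES, KO, WT, IntensityTable, SampleDesign

logger = logging.getLogger(__name__)

FC_THRESHOLD = 1.5
ALPHA = 0.05
MIN_WT_DETECTED = 2
MIN_RAZOR_UNIQUE = 2
SHIFT_SD_MULT = 2.5
JITTER_MAX = 0.3


@dataclass
class NormalizedTable:
    """Log2-transformed, per-sample mean-centered intensities.

    ``imputed_mask`` flags cells filled by :func:`impute_missing`;
    non-imputed cells equal ``log2(raw) - sample_mean``.
    """

    protein_ids: list[str]
    gene_names: list[str]
    razor_unique: "object"  # pd.DataFrame, as on IntensityTable
    design: SampleDesign
    values: np.ndarray
    imputed_mask: np.ndarray

    @property
    def samples(self) -> list[str]:
        return self.design.sample_names

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)


@dataclass(frozen=True)
class EnrichmentRecord:
    """Per-protein enrichment result."""

    protein_id: str
    gene: str
    column_ids: tuple[str, ...]
    per_column_log2fc: tuple[float, ...]
    avg_fold_change: float
    p_value: float
    q_value: float
    n_wt_detected: int
    passes_qc: bool
    enriched: bool


def qc_filter(table: IntensityTable, min_razor_unique: int = MIN_RAZOR_UNIQUE) -> IntensityTable:
    """Keep proteins with razor+unique count >= threshold in WT *or* KO."""
    counts = table.razor_unique
    keep = (
        (counts[WT].to_numpy() >= min_razor_unique)
        | (counts[KO].to_numpy() >= min_razor_unique)
    )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("qc_filter: dropped %d / %d proteins", dropped, table.n_proteins)
    return table.subset(keep)


def log_transform_normalize(table: IntensityTable) -> NormalizedTable:
    """log2-transform and center each sample on its mean over present values."""
    raw = table.values
    present = ~np.isnan(raw)
    if np.any(raw[present] <= 0):
        raise ValueError("nonpositive present intensity; zeros must be missing on read")
    logged = np.where(present, np.log2(np.where(present, raw, 1.0)), np.nan)
    col_means = np.nanmean(logged, axis=0)
    values = logged - col_means
    return NormalizedTable(
        protein_ids=list(table.protein_ids),
        gene_names=list(table.gene_names),
        razor_unique=table.razor_unique,
        design=table.design,
        values=values,
        imputed_mask=np.zeros_like(values, dtype=bool),
    )


def impute_missing(
    table: NormalizedTable,
    shift_sd_mult: float = SHIFT_SD_MULT,
    jitter_max: float = JITTER_MAX,
    seed: int = 0,
) -> NormalizedTable:
    """Downshift-impute missing cells.

    For a missing cell in sample ``s``: draw ``u ~ Uniform(0, jitter_max)``
    and set the value to ``u - shift_sd_mult * sigma_s`` where ``sigma_s``
    is the (n-1) standard deviation of the sample's present values.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11D]))
    values = table.values.copy()
    mask = table.imputed_mask.copy()
    for j, name in enumerate(table.samples):
        col = values[:, j]
        missing = np.isnan(col)
        present = col[~missing]
        if present.size < 2:
            raise ValueError(f"sample {name!r} has fewer than 2 present values")
        if not missing.any():
            continue
        sigma = float(np.std(present, ddof=1))
        u = rng.uniform(0.0, jitter_max, size=int(missing.sum()))
        values[missing, j] = u - shift_sd_mult * sigma
        mask[missing, j] = True
    return NormalizedTable(
        protein_ids=table.protein_ids,
        gene_names=table.gene_names,
        razor_unique=table.razor_unique,
        design=table.design,
        values=values,
        imputed_mask=mask,
    )


def input_normalized_eluates(table: NormalizedTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-protein eluate-minus-input levels for each genotype.

    Returns (wt, ko, column_ids) where wt/ko have shape
    (n_proteins, n_columns), columns sorted by antibody column id.
    """
    design = table.design
    out = {}
    for genotype in GENOTYPES:
        input_j = table.sample_index(design.input_sample(genotype))
        cols = []
        for _, sample_name in design.eluate_samples(genotype):
            j = table.sample_index(sample_name)
            cols.append(table.values[:, j] - table.values[:, input_j])
        out[genotype] = np.column_stack(cols)
    column_ids = [c for c, _ in design.eluate_samples(WT)]
    if column_ids != [c for c, _ in design.eluate_samples(KO)]:
        raise ValueError("WT and KO eluate columns are not matched")
    return out[WT], out[KO], column_ids


def fold_change_vs_input(
    table: NormalizedTable, fc_average: str = "linear"
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Input-normalized per-column log2 fold changes and the average FC.

    ``delta[:, c] = (wt_eluate_c - wt_input) - (ko_eluate_c - ko_input)``;
    the average fold change is the arithmetic mean over columns of
    ``2**delta`` (``fc_average="linear"``, default) or ``2**mean(delta)``
    (``"geometric"``).
    """
    wt, ko, column_ids = input_normalized_eluates(table)
    delta = wt - ko
    if fc_average == "linear":
        avg_fc = np.mean(2.0**delta, axis=1)
    elif fc_average == "geometric":
        avg_fc = 2.0 ** np.mean(delta, axis=1)
    else:
        raise ValueError(f"unknown fc_average {fc_average!r}")
    return delta, avg_fc, column_ids


def paired_t_test(wt_vals, ko_vals) -> tuple[float, float]:
    """Two-sided paired t-test on matched per-column values.

    Degenerate contract: if the differences have zero spread, p is 1 when
    their mean is 0 and 0 otherwise.
    """
    wt = np.asarray(wt_vals, dtype=float)
    ko = np.asarray(ko_vals, dtype=float)
    if wt.shape != ko.shape or wt.ndim != 1 or wt.size < 2:
        raise ValueError("paired_t_test needs two equal-length vectors, n >= 2")
    t, p = _paired_t_matrix(wt[None, :], ko[None, :])
    return float(t[0]), float(p[0])


def _paired_t_matrix(wt: np.ndarray, ko: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired t over rows of (n_proteins, n_columns) matrices."""
    d = wt - ko
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    degenerate = sd == 0
    if np.any(degenerate):
        logger.warning("paired t-test: %d degenerate rows (zero-spread differences)", int(degenerate.sum()))
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)
        p = np.where(degenerate, np.where(mean == 0, 1.0, 0.0), p)
    return t, p


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    # Benjamini-Hochberg, informational only — never used in the call.
    return stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")


def count_wt_detected(table: NormalizedTable) -> np.ndarray:
    """Number of NON-imputed wildtype eluate measurements per protein."""
    idx = [table.sample_index(s) for _, s in table.design.eluate_samples(WT)]
    return (~table.imputed_mask[:, idx]).sum(axis=1).astype(int)


def call_enrichment(
    table: NormalizedTable,
    delta: np.ndarray,
    avg_fc: np.ndarray,
    p_values: np.ndarray,
    n_wt_detected: np.ndarray,
    column_ids: list[str],
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
    min_wt_detected: int = MIN_WT_DETECTED,
) -> list[EnrichmentRecord]:
    """Assemble per-protein records and apply the three-criterion call.

    Output is sorted by descending average fold change, ties broken by
    ascending p value then accession.
    """
    q = _bh_qvalues(p_values)
    records = []
    for i, pid in enumerate(table.protein_ids):
        enriched = (
            avg_fc[i] > fc_threshold
            and p_values[i] <= alpha
            and n_wt_detected[i] >= min_wt_detected
        )
        records.append(
            EnrichmentRecord(
                protein_id=pid,
                gene=table.gene_names[i],
                column_ids=tuple(column_ids),
                per_column_log2fc=tuple(float(x) for x in delta[i]),
                avg_fold_change=float(avg_fc[i]),
                p_value=float(p_values[i]),
                q_value=float(q[i]),
                n_wt_detected=int(n_wt_detected[i]),
                passes_qc=True,  # qc_filter ran upstream; survivors pass
                enriched=bool(enriched),
            )
        )
    records.sort(key=lambda r: (-r.avg_fold_change, r.p_value, r.protein_id))
    return records


def run_enrichment(
    table: IntensityTable,
    min_razor_unique: int = MIN_RAZOR_UNIQUE,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
    min_wt_detected: int = MIN_WT_DETECTED,
    fc_average: str = "linear",
    shift_sd_mult: float = SHIFT_SD_MULT,
    jitter_max: float = JITTER_MAX,
    seed: int = 0,
) -> tuple[list[EnrichmentRecord], dict]:
    """Full enrichment chain; returns (records, stage-count report)."""
    n_total = table.n_proteins
    filtered = qc_filter(table, min_razor_unique)
    normalized = log_transform_normalize(filtered)
    imputed = impute_missing(normalized, shift_sd_mult, jitter_max, seed)
    delta, avg_fc, column_ids = fold_change_vs_input(imputed, fc_average)
    wt, ko, _ = input_normalized_eluates(imputed)
    _, p = _paired_t_matrix(wt, ko)
    n_det = count_wt_detected(imputed)
    records = call_enrichment(
        imputed, delta, avg_fc, p, n_det, column_ids, fc_threshold, alpha, min_wt_detected
    )
    report = {
        "n_proteins_total": n_total,
        "n_dropped_qc": n_total - filtered.n_proteins,
        "n_analyzed": filtered.n_proteins,
        "n_imputed_cells": int(imputed.imputed_mask.sum()),
        "n_enriched": sum(r.enriched for r in records),
    }
    return records, report
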