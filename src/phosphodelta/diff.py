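"""Cross-method aggregation, CV cascade, classification and significance.

The experiment quantifies each phosphopeptide in up to three enrichment
methods (SIMAC, TiO2, TiSH).  Within each method the log2(H/L) ratios are
median-centred, then the per-method H/L values of each peptide are averaged.
Peptides pass the cascade filter if their cross-method coefficient of
variation (CV) is below 40%, if they were seen in a single method (no CV), or
if the CV is high but every single method ratio is already below the
hyperphosphorylation threshold 0.75.  A peptide is called hyperphosphorylated
in the mutant when the mean H/L ratio falls below 0.75 (log2 < -0.42) and
hypophosphorylated above 1.3; significance of peptides quantified in at least
two methods is a two-tailed one-sample t-test of the method-level log2 ratios
against zero at alpha = 0.05.  Protein-abundance flags from the non-enriched
extract annotate whether a ratio change could instead reflect protein level.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceMeasurement, PhosphopeptideMeasurement

HYPER = "hyper"
HYPO = "hypo"
UNCHANGED = "unchanged"

BRANCH_LOW_CV = "low_cv"
BRANCH_SINGLE = "single_method"
BRANCH_HIGH_CV_ALL_LOW = "high_cv_all_low"
BRANCH_REJECTED = "rejected"


@dataclass
class PeptideRatioSummary:
    """Cross-method aggregate for one phosphopeptide."""

    peptide_id: str
    sequence: str
    protein_acc: str
    sites: str
    per_method_hl: dict[str, float]
    mean_hl: float
    mean_log2: float
    cv: float | None              # fraction (sd/mean on the H/L scale), None if 1 method
    n_methods: int
    p_value: float | None = None
    degenerate_p: bool = False    # p forced to 0/1 by a zero-variance sample
    phospho_class: str = UNCHANGED
    kept_by_cascade: bool = False
    cascade_branch: str = BRANCH_REJECTED

    @property
    def per_method_log2(self) -> list[float]:
        return [math.log2(v) for v in self.per_method_hl.values()]


@dataclass(frozen=True)
class AbundanceFlag:
    protein_acc: str
    protein_hl: float | None
    status: str  # unchanged | reduced | unknown


def aggregate_scans(scan_ratios: Sequence[tuple[float, float]]) -> float:
    """Weighted mean of the scan-level log2 ratios quantifying one peptide."""
    if not scan_ratios:
        raise ValueError("no scans to aggregate")
    values, weights = zip(*scan_ratios)
    if any(w <= 0 for w in weights):
        raise ValueError("scan weights must be positive")
    return float(np.average(values, weights=weights))


def median_normalize(
    records: Sequence[PhosphopeptideMeasurement],
) -> list[PhosphopeptideMeasurement]:
    """Centre log2(H/L) ratios on zero independently within each method."""
    by_method: dict[str, list[float]] = {}
    for m in records:
        by_method.setdefault(m.method, []).append(m.log2_ratio)
    medians = {meth: statistics.median(vals) for meth, vals in by_method.items()}
    return [m.with_log2(m.log2_ratio - medians[m.method]) for m in records]


def summarize_across_methods(
    records: Sequence[PhosphopeptideMeasurement],
) -> dict[str, PeptideRatioSummary]:
    """Aggregate measurements into one summary per peptide identity.

    Per-method duplicates of a peptide are averaged on the log2 scale first;
    the cross-method mean is the arithmetic mean of the per-method H/L values
    and the CV is the sample standard deviation over the mean on the H/L
    scale (absent for single-method peptides).
    """
    grouped: dict[str, dict[str, list[PhosphopeptideMeasurement]]] = {}
    for m in records:
        grouped.setdefault(m.peptide_id, {}).setdefault(m.method, []).append(m)

    summaries: dict[str, PeptideRatioSummary] = {}
    for pid, methods in grouped.items():
        per_method_hl: dict[str, float] = {}
        for meth, ms in methods.items():
            mean_log2 = sum(m.log2_ratio for m in ms) / len(ms)
            per_method_hl[meth] = 2.0**mean_log2
        first = next(iter(methods.values()))[0]
        hls = list(per_method_hl.values())
        mean_hl = sum(hls) / len(hls)
        cv = None
        if len(hls) > 1:
            cv = statistics.stdev(hls) / mean_hl
        summaries[pid] = PeptideRatioSummary(
            peptide_id=pid,
            sequence=first.sequence,
            protein_acc=first.protein_acc,
            sites=";".join(
                f"{r}{p}" for r, p in zip(first.site_residues, first.site_positions)
            ),
            per_method_hl=per_method_hl,
            mean_hl=mean_hl,
            mean_log2=sum(math.log2(v) for v in hls) / len(hls),
            cv=cv,
            n_methods=len(per_method_hl),
        )
    return summaries


def cascade_filter(
    summaries: Mapping[str, PeptideRatioSummary] | Iterable[PeptideRatioSummary],
    cv_max: float = 0.40,
    low_threshold: float = 0.75,
) -> list[PeptideRatioSummary]:
    """Apply the CV filter cascade; returns the kept subset.

    Kept if CV < cv_max (branch ``low_cv``), CV absent (``single_method``),
    or CV >= cv_max with every per-method H/L below ``low_threshold``
    (``high_cv_all_low``).  Branches are recorded on every summary.
    """
    if isinstance(summaries, Mapping):
        summaries = summaries.values()
    kept = []
    for s in summaries:
        if s.cv is None:
            s.cascade_branch = BRANCH_SINGLE
        elif s.cv < cv_max:
            s.cascade_branch = BRANCH_LOW_CV
        elif all(v < low_threshold for v in s.per_method_hl.values()):
            s.cascade_branch = BRANCH_HIGH_CV_ALL_LOW
        else:
            s.cascade_branch = BRANCH_REJECTED
        s.kept_by_cascade = s.cascade_branch != BRANCH_REJECTED
        if s.kept_by_cascade:
            kept.append(s)
    return kept


def classify(
    summary: PeptideRatioSummary, low: float = 0.75, high: float = 1.3
) -> str:
    """Hyper- / hypo- / unchanged call from the cross-method mean H/L.

    Boundaries are exclusive: exactly 0.75 or 1.3 is ``unchanged``.
    """
    if summary.mean_hl < low:
        summary.phospho_class = HYPER
    elif summary.mean_hl > high:
        summary.phospho_class = HYPO
    else:
        summary.phospho_class = UNCHANGED
    return summary.phospho_class


def significance_test(
    summaries: Iterable[PeptideRatioSummary], alpha: float = 0.05
) -> list[PeptideRatioSummary]:
    """Two-tailed one-sample t-test of method-level log2 ratios against 0.

    Only peptides quantified in >= 2 methods are testable; single-method
    peptides keep ``p_value = None``.  Zero-variance samples get p forced to
    0 (nonzero mean) or 1 (zero mean) with ``degenerate_p`` set.  Returns the
    significant subset (p < alpha).
    """
    significant = []
    for s in summaries:
        if s.n_methods < 2:
            s.p_value = None
            continue
        values = s.per_method_log2
        sd = statistics.stdev(values)
        if sd == 0.0:
            s.p_value = 1.0 if math.isclose(sum(values), 0.0, abs_tol=1e-12) else 0.0
            s.degenerate_p = True
        else:
            s.p_value = float(stats.ttest_1samp(values, 0.0).pvalue)
        if s.p_value < alpha:
            significant.append(s)
    return significant


def abundance_correct(
    summaries: Iterable[PeptideRatioSummary],
    abundance: Sequence[AbundanceMeasurement],
    threshold: float = 0.8,
) -> dict[str, AbundanceFlag]:
    """Annotate peptides with the protein-level abundance status.

    The non-enriched table is aggregated to protein level (median of peptide
    H/L per protein); a protein is ``unchanged`` at H/L >= threshold,
    ``reduced`` below it and ``unknown`` when absent from the table.  The
    annotation never removes a peptide.
    """
    per_protein: dict[str, list[float]] = {}
    for a in abundance:
        per_protein.setdefault(a.protein_acc, []).append(a.hl_ratio)
    protein_hl = {acc: statistics.median(v) for acc, v in per_protein.items()}

    flags: dict[str, AbundanceFlag] = {}
    for s in summaries:
        hl = protein_hl.get(s.protein_acc)
        if hl is None:
            status = "unknown"
        elif hl >= threshold:
            status = "unchanged"
        else:
            status = "reduced"
        flags[s.peptide_id] = AbundanceFlag(
            protein_acc=s.protein_acc, protein_hl=hl, status=status
        )
    return flags


def volcano_table(
    summaries: Iterable[PeptideRatioSummary], alpha: float = 0.05
) -> pd.DataFrame:
    """One row per tested (>= 2 methods) peptide, volcano-plot ready.

    Columns: peptide_id, protein, mean_log2, p_value, minus_log10_p,
    p_bh (Benjamini-Hochberg adjusted, emitted for transparency; the
    significance call itself uses the raw p), phospho_class, significant.
    """
    tested = [s for s in summaries if s.p_value is not None]
    if not tested:
        return pd.DataFrame(
            columns=[
                "peptide_id", "protein", "mean_log2", "p_value",
                "minus_log10_p", "p_bh", "phospho_class", "significant",
            ]
        )
    raw_p = [s.p_value for s in tested]
    tiny = np.finfo(float).tiny
    p_bh = multipletests(raw_p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "peptide_id": [s.peptide_id for s in tested],
            "protein": [s.protein_acc for s in tested],
            "mean_log2": [s.mean_log2 for s in tested],
            "p_value": raw_p,
            "minus_log10_p": [-math.log10(max(p, tiny)) for p in raw_p],
            "p_bh": p_bh,
            "phospho_class": [s.phospho_class for s in tested],
            "significant": [p < alpha for p in raw_p],
        }
    )


def volcano_counts(volcano: pd.DataFrame) -> tuple[int, int]:
    """(significant hyper, significant hypo) counts from a volcano table."""
    sig = volcano[volcano["significant"]]
    return (
        int((sig["phospho_class"] == HYPER).sum()),
        int((sig["phospho_class"] == HYPO).sum()),
    )
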