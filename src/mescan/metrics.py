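"""Evaluation statistics for the pipeline.

These are the method's headline quality measures: how faithfully pooled
sample proportions are recovered from index counts; the false-negative rate
against a set of putatively fixed loci; a sensitivity estimate adjusted for
duplication-driven and motif-driven misses and for residual misses confirmed
by PCR; specificity from PCR-checked positive genotypes; the replication
failure rate between technical replicates; per-locus coverage overdispersion;
and confusion-matrix scoring against simulated truth.

Rates are reported as percentages; display rounding is 3 significant figures
for rates and 1 decimal for the adjusted sensitivity, with raw floats
retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (half-to-even on the float grid)."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")


@dataclass
class IndexProportionReport:
    table: pd.DataFrame  # per sample: count, expected_pct, observed_pct
    mean_abs_deviation: float  # percentage points, raw

    def __str__(self) -> str:
        return f"{self.table}\nmean |observed - expected| = {self.mean_abs_deviation:.3g} pp"


def index_proportions(
    counts: dict[str, int],
    expected_pct: dict[str, float],
) -> IndexProportionReport:
    """Observed vs expected index fractions in a pooled library.

    ``counts`` are assigned read pairs per sample (or index); ``expected_pct``
    the design proportions in percent.  Observed percent is
    ``100 * count / total`` rounded to 3 significant figures for display; the
    mean absolute deviation uses unrounded values.
    """
    if set(counts) != set(expected_pct):
        raise ValueError("counts and expected proportions must cover the same samples")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no assigned read pairs")
    rows = []
    devs = []
    for key in counts:
        obs = 100.0 * counts[key] / total
        rows.append(
            {
                "sample": key,
                "read_pairs": counts[key],
                "expected_pct": expected_pct[key],
                "observed_pct": round_sig(obs, 3),
                "observed_pct_raw": obs,
            }
        )
        devs.append(abs(obs - expected_pct[key]))
    table = pd.DataFrame(rows).set_index("sample")
    return IndexProportionReport(table, float(np.mean(devs)))


def false_negative_rate(n_missed: int, n_total: int) -> float:
    """Percent of putatively fixed loci not retrieved, 3 significant figures."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_missed < 0 or n_missed > n_total:
        raise ValueError("n_missed outside [0, n_total]")
    return round_sig(100.0 * n_missed / n_total, 3)


@dataclass(frozen=True)
class SensitivityInputs:
    n_total: int  # putatively fixed loci
    n_dup: int  # misses inside recently duplicated regions
    n_no_motif: int  # misses lacking detectable element sequence
    n_putative_residual: int  # remaining putative misses
    pcr_confirm_rate: float  # fraction of residuals confirmed as real misses

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_dup, self.n_no_motif, self.n_putative_residual) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.pcr_confirm_rate <= 1:
            raise ValueError("confirm rate must be in [0, 1]")


def adjusted_sensitivity(inputs: SensitivityInputs) -> tuple[float, float]:
    """(estimated false-negative count, sensitivity percent to 1 decimal).

    The false-negative estimate keeps the fractional residual product
    unrounded before summation:
    ``FN = n_dup + n_no_motif + pcr_confirm_rate * n_putative_residual``;
    sensitivity is ``100 * (n_total - FN) / n_total``.
    """
    fn = inputs.n_dup + inputs.n_no_motif + inputs.pcr_confirm_rate * inputs.n_putative_residual
    sens = 100.0 * (inputs.n_total - fn) / inputs.n_total
    return fn, round(sens, 1)


def specificity(n_false_pos: int, n_pos_checked: int) -> float:
    """Percent of checked positive genotypes that are genuine (raw float)."""
    if n_pos_checked <= 0:
        raise ValueError("n_pos_checked must be positive")
    if not 0 <= n_false_pos <= n_pos_checked:
        raise ValueError("n_false_pos outside [0, n_pos_checked]")
    return 100.0 * (1.0 - n_false_pos / n_pos_checked)


@dataclass(frozen=True)
class ReplicationInputs:
    n_union: int  # loci positive in either replicate
    miss_a: int  # of those, absent from replicate a
    miss_b: int

    def __post_init__(self) -> None:
        if self.n_union <= 0:
            raise ValueError("n_union must be positive")
        if not (0 <= self.miss_a <= self.n_union and 0 <= self.miss_b <= self.n_union):
            raise ValueError("misses must lie in [0, n_union]")


def replication_failure_rate(inputs: ReplicationInputs) -> float:
    """Average percent of union loci missed per replicate, 3 significant figures.

    The mean of the two per-replicate miss fractions:
    ``100 * (miss_a + miss_b) / (2 * n_union)``.  Symmetric in the replicates.
    """
    return round_sig(100.0 * (inputs.miss_a + inputs.miss_b) / (2.0 * inputs.n_union), 3)


def coverage_dispersion(counts) -> tuple[float, float, float]:
    """(mean, unbiased variance, variance/mean) of per-locus pair counts."""
    arr = np.asarray(counts, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two loci")
    mean = float(arr.mean())
    var = float(arr.var(ddof=1))
    ratio = var / mean if mean > 0 else float("nan")
    return mean, var, ratio


@dataclass
class TruthEvaluation:
    per_sample: pd.DataFrame  # sensitivity, specificity, fdr per sample (%)
    overall: dict[str, float] = field(default_factory=dict)
    confusion: dict[str, int] = field(default_factory=dict)


def evaluate_against_truth(
    calls: pd.DataFrame,
    truth_carriers: pd.DataFrame,
    position_tol: int = 3,
) -> TruthEvaluation:
    """Confusion-matrix rates of presence/absence calls against simulated truth.

    ``calls`` is loci x samples in {0,1} indexed by ``chrom:endpoint`` ids;
    ``truth_carriers`` is samples x loci (the simulator's genotype > 0).
    Called loci are matched to truth loci by identifier, then by position
    within ``position_tol``.  Cells over truth loci count TP/FN/TN/FP; called
    loci with no truth counterpart contribute their positive cells as FP.
    """
    truth = truth_carriers.T  # loci x samples
    samples = list(truth.columns)
    matched: dict[str, str] = {}
    truth_pos = {lid: _parse_locus(lid) for lid in truth.index}
    for lid in calls.index:
        if lid in truth.index:
            matched[lid] = lid
            continue
        chrom, pos = _parse_locus(lid)
        best = None
        for tid, (tc, tp) in truth_pos.items():
            if tc == chrom and abs(tp - pos) <= position_tol:
                d = abs(tp - pos)
                if best is None or d < best[0]:
                    best = (d, tid)
        if best is not None:
            matched[lid] = best[1]

    tp = fn = fp = tn = 0
    per_sample = {s: {"tp": 0, "fn": 0, "fp": 0, "tn": 0} for s in samples}
    called = pd.DataFrame(0, index=truth.index, columns=samples)
    for lid, tid in matched.items():
        for s in samples:
            if s in calls.columns and calls.loc[lid, s]:
                called.loc[tid, s] = 1
    for tid in truth.index:
        for s in samples:
            t = bool(truth.loc[tid, s])
            c = bool(called.loc[tid, s])
            key = ("tp" if c else "fn") if t else ("fp" if c else "tn")
            per_sample[s][key] += 1
    extra = [lid for lid in calls.index if lid not in matched]
    for lid in extra:
        for s in samples:
            if s in calls.columns and calls.loc[lid, s]:
                per_sample[s]["fp"] += 1

    rows = {}
    for s in samples:
        c = per_sample[s]
        tp += c["tp"]
        fn += c["fn"]
        fp += c["fp"]
        tn += c["tn"]
        rows[s] = {
            "sensitivity": _pct(c["tp"], c["tp"] + c["fn"]),
            "specificity": _pct(c["tn"], c["tn"] + c["fp"]),
            "fdr": _pct(c["fp"], c["tp"] + c["fp"], default=0.0),
        }
    overall = {
        "sensitivity": _pct(tp, tp + fn),
        "specificity": _pct(tn, tn + fp),
        "fdr": _pct(fp, tp + fp, default=0.0),
    }
    return TruthEvaluation(
        pd.DataFrame(rows).T,
        overall,
        {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
    )


def _pct(num: int, den: int, default: float = 100.0) -> float:
    return 100.0 * num / den if den else default


def _parse_locus(lid: str) -> tuple[str, int]:
    chrom, pos = lid.rsplit(":", 1)
    return chrom, int(pos)
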