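"""Differential splicing calls: Fisher exact test, BH-FDR, threshold
filters, and the bidirectional knockdown/overexpression join.

Per contrast, each event's pooled inclusion/skipping counts in treatment
and control form a 2x2 table tested with a two-sided Fisher exact test;
p-values are Benjamini–Hochberg adjusted jointly across all tested
events of the contrast.  An event passes the screen when its total
junction reads are >= 15, |dSI| >= 0.10 and FDR < 0.2 (all
configurable).  High-confidence calls additionally require the SI shift
to run in opposite directions between knockdown and overexpression.
"""

from __future__ import annotations

import math
import operator
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

from statsmodels.stats.multitest import multipletests

from .quantify import EventQuantification


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    Sums the hypergeometric probabilities of every table with the same
    margins whose probability does not exceed that of the observed
    table (minimum-likelihood two-sided rule).  Computed in exact
    integer arithmetic, so ties are decided exactly rather than to
    floating-point tolerance.
    """
    (a, b), (c, d) = table
    cells = []
    for x in (a, b, c, d):
        if isinstance(x, float):
            if not x.is_integer():
                raise ValueError(f"table cells must be integers, got {x!r}")
            x = int(x)
        else:
            try:
                x = operator.index(x)
            except TypeError:
                raise ValueError(f"table cells must be integers, got {x!r}")
        if x < 0:
            raise ValueError(f"table cells must be non-negative, got {x}")
        cells.append(x)
    a, b, c, d = cells
    n1, n2 = a + b, c + d
    k = a + c
    n = n1 + n2
    if n == 0:
        raise ValueError("table has no observations")
    if n1 == 0 or n2 == 0 or k == 0 or k == n:
        return 1.0
    lo, hi = max(0, k - n2), min(k, n1)
    # unnormalised probabilities: comb(n1, i) * comb(n2, k - i)
    weights = [math.comb(n1, i) * math.comb(n2, k - i) for i in range(lo, hi + 1)]
    obs = weights[a - lo]
    total = sum(weights)
    tail = sum(w for w in weights if w <= obs)
    return float(Fraction(tail, total))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    if len(p_values) == 0:
        return []
    for p in p_values:
        if not (0 < p <= 1):
            raise ValueError(f"p-values must be in (0, 1], got {p}")
    return [float(q) for q in multipletests(list(p_values), method="fdr_bh")[1]]


@dataclass
class Thresholds:
    """Screening thresholds for differential events.

    total_reads: minimum junction-read support (per arm, see
    ``total_rule``); delta_si: minimum |dSI|; fdr: strict upper bound on
    the BH-adjusted p; total_rule: how the two arms' totals combine into
    the reported total ("min" — each arm must carry the support — or
    "sum"); ir_min_covered: minimum intron covered fraction for
    intron-retention events.
    """

    total_reads: int = 15
    delta_si: float = 0.10
    fdr: float = 0.2
    total_rule: str = "min"
    ir_min_covered: float = 0.9


def passes_filters(
    total_junction_reads: int,
    delta_si: Optional[float],
    fdr: Optional[float],
    thresholds: Thresholds,
) -> bool:
    """The screen's printed inequalities: total >= T, |dSI| >= T, FDR < T."""
    if delta_si is None or fdr is None:
        return False
    return (
        total_junction_reads >= thresholds.total_reads
        and abs(delta_si) >= thresholds.delta_si - 1e-12
        and fdr < thresholds.fdr
    )


@dataclass
class ContrastResult:
    event_id: str
    contrast_id: str
    si_treatment: Optional[float]
    si_control: Optional[float]
    delta_si: Optional[float]
    p_value: Optional[float]
    fdr: Optional[float] = None
    total_junction_reads: int = 0
    passes_filters: bool = False
    tested: bool = True


def _pool(quants: Sequence[EventQuantification]) -> EventQuantification:
    """Pool replicate quantifications of one event by count summation."""
    first = quants[0]
    inc = sum(q.inclusion_reads for q in quants)
    skip = sum(q.skipping_reads for q in quants)
    covs = [q.ir_covered_fraction for q in quants if q.ir_covered_fraction is not None]
    deps = [q.ir_mean_depth for q in quants if q.ir_mean_depth is not None]
    return EventQuantification(
        event_id=first.event_id,
        sample_id="pooled",
        inclusion_reads=inc,
        skipping_reads=skip,
        ir_covered_fraction=max(covs) if covs else None,
        ir_mean_depth=max(deps) if deps else None,
    )


def call_contrast(
    quants_treatment: Sequence[dict[str, EventQuantification]],
    quants_control: Sequence[dict[str, EventQuantification]],
    contrast_id: str,
    thresholds: Optional[Thresholds] = None,
) -> list[ContrastResult]:
    """Differential calls for one treatment-vs-control contrast.

    Each argument is a list of per-sample {event_id: quantification}
    maps (replicates are pooled by count summation).  Events with an
    undefined SI in either pooled arm are excluded from testing and
    flagged ``tested=False``.  BH-FDR is computed jointly across all
    tested events of the contrast, all event types together.
    """
    thresholds = thresholds or Thresholds()
    event_ids = sorted(
        set().union(*[set(q) for q in quants_treatment + list(quants_control)])
    )
    results: list[ContrastResult] = []
    tested_idx: list[int] = []
    pvals: list[float] = []
    for eid in event_ids:
        qt = [q[eid] for q in quants_treatment if eid in q]
        qc = [q[eid] for q in quants_control if eid in q]
        pt = _pool(qt) if qt else None
        pc = _pool(qc) if qc else None
        si_t = pt.si if pt else None
        si_c = pc.si if pc else None
        if si_t is None or si_c is None:
            results.append(
                ContrastResult(
                    eid, contrast_id, si_t, si_c, None, None,
                    total_junction_reads=0, tested=False,
                )
            )
            continue
        if thresholds.total_rule == "sum":
            total = pt.total_junction_reads + pc.total_junction_reads
        else:
            total = min(pt.total_junction_reads, pc.total_junction_reads)
        p = fisher_exact_2x2(
            [
                [pt.inclusion_reads, pt.skipping_reads],
                [pc.inclusion_reads, pc.skipping_reads],
            ]
        )
        res = ContrastResult(
            eid, contrast_id, si_t, si_c, si_t - si_c, p,
            total_junction_reads=total,
        )
        # intron-retention QC gate: require evidence the intron is covered
        covs = [
            q.ir_covered_fraction
            for q in qt + qc
            if q.ir_covered_fraction is not None
        ]
        res._ir_gate_ok = (not covs) or max(covs) >= thresholds.ir_min_covered
        results.append(res)
        tested_idx.append(len(results) - 1)
        pvals.append(p)
    if pvals:
        fdrs = bh_fdr(pvals)
        for i, q in zip(tested_idx, fdrs):
            res = results[i]
            res.fdr = q
            res.passes_filters = passes_filters(
                res.total_junction_reads, res.delta_si, q, thresholds
            ) and getattr(res, "_ir_gate_ok", True)
    return results


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


@dataclass
class HighConfidenceCall:
    event_id: str
    kd_results: list[ContrastResult]
    oe_results: list[ContrastResult]
    direction_consistent: bool
    mode: str
    satisfying_pairs: list[tuple[str, str]] = field(default_factory=list)


def join_bidirectional(
    kd: Sequence[Sequence[ContrastResult]],
    oe: Sequence[Sequence[ContrastResult]],
    mode: str = "strict",
) -> list[HighConfidenceCall]:
    """Join knockdown and overexpression contrasts into high-confidence calls.

    strict: every supplied KD and OE contrast passes the screen and all
    KD dSI share one sign opposite to all OE dSI.  relaxed: at least one
    (KD, OE) pair is opposite-signed with both members passing.  A dSI
    of exactly zero never satisfies either rule.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    if not kd or not oe:
        raise ValueError("need at least one KD and one OE contrast")
    kd_by_event = [{r.event_id: r for r in rs} for rs in kd]
    oe_by_event = [{r.event_id: r for r in rs} for rs in oe]
    event_ids = sorted(
        set().union(*[set(d) for d in kd_by_event + oe_by_event])
    )
    calls = []
    for eid in event_ids:
        kd_rs = [d[eid] for d in kd_by_event if eid in d]
        oe_rs = [d[eid] for d in oe_by_event if eid in d]
        pairs = []
        if mode == "strict":
            ok = (
                len(kd_rs) == len(kd)
                and len(oe_rs) == len(oe)
                and all(r.passes_filters for r in kd_rs + oe_rs)
            )
            if ok:
                kd_signs = {_sign(r.delta_si) for r in kd_rs}
                oe_signs = {_sign(r.delta_si) for r in oe_rs}
                ok = (
                    len(kd_signs) == 1
                    and len(oe_signs) == 1
                    and 0 not in kd_signs
                    and kd_signs == {-next(iter(oe_signs))}
                )
            if ok:
                pairs = [
                    (k.contrast_id, o.contrast_id) for k in kd_rs for o in oe_rs
                ]
        else:
            for k in kd_rs:
                for o in oe_rs:
                    if (
                        k.passes_filters
                        and o.passes_filters
                        and _sign(k.delta_si) != 0
                        and _sign(k.delta_si) == -_sign(o.delta_si)
                    ):
                        pairs.append((k.contrast_id, o.contrast_id))
            ok = bool(pairs)
        if ok:
            calls.append(
                HighConfidenceCall(
                    event_id=eid,
                    kd_results=kd_rs,
                    oe_results=oe_rs,
                    direction_consistent=True,
                    mode=mode,
                    satisfying_pairs=pairs,
                )
            )
    return calls


CONTRAST_COLUMNS = [
    "event_id",
    "contrast_id",
    "si_treatment",
    "si_control",
    "delta_si",
    "p_value",
    "fdr",
    "total_junction_reads",
    "passes_filters",
    "tested",
]


def write_contrast_results(
    results: Sequence[ContrastResult], path: Union[str, Path]
) -> None:
    def fmt(x, spec="{:.6g}"):
        return "NA" if x is None else spec.format(x)

    with open(path, "w") as fh:
        fh.write("\t".join(CONTRAST_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.event_id,
                        r.contrast_id,
                        fmt(r.si_treatment),
                        fmt(r.si_control),
                        fmt(r.delta_si),
                        fmt(r.p_value, "{:.6e}"),
                        fmt(r.fdr, "{:.6e}"),
                        str(r.total_junction_reads),
                        "1" if r.passes_filters else "0",
                        "1" if r.tested else "0",
                    ]
                )
                + "\n"
            )


def read_contrast_results(path: Union[str, Path]) -> list[ContrastResult]:
    out = []

    def parse(x, conv=float):
        return None if x == "NA" else conv(x)

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CONTRAST_COLUMNS:
            raise ValueError(f"{path}: unexpected contrast header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                ContrastResult(
                    event_id=f[0],
                    contrast_id=f[1],
                    si_treatment=parse(f[2]),
                    si_control=parse(f[3]),
                    delta_si=parse(f[4]),
                    p_value=parse(f[5]),
                    fdr=parse(f[6]),
                    total_junction_reads=int(f[7]),
                    passes_filters=f[8] == "1",
                    tested=f[9] == "1",
                )
            )
    return out


def write_high_confidence_calls(
    calls: Sequence[HighConfidenceCall], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "event_id\tmode\tkd_delta_si\toe_delta_si\tsatisfying_pairs\n"
        )
        for c in calls:
            kd = ";".join(
                f"{r.contrast_id}={r.delta_si:.6g}" for r in c.kd_results
            )
            oe = ";".join(
                f"{r.contrast_id}={r.delta_si:.6g}" for r in c.oe_results
            )
            pairs = ";".join(f"{a}|{b}" for a, b in c.satisfying_pairs)
            fh.write(f"{c.event_id}\t{c.mode}\t{kd}\t{oe}\t{pairs}\n")
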