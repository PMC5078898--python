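"""Recovery scoring of called regions against planted truth."""

from __future__ import annotations

import pandas as pd

from .genome import GenomicInterval


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(intersection/|a|, intersection/|b|); 0 for different chromosomes."""
    inter = a.overlap_length(b)
    if inter == 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def score_domain_recovery(
    called: list[GenomicInterval],
    truth: list[GenomicInterval],
    min_reciprocal: float = 0.5,
) -> dict[str, float]:
    """Sensitivity and precision at a reciprocal-overlap threshold.

    A truth domain is recovered when some called domain overlaps it by at
    least ``min_reciprocal`` of both lengths; a called domain is a true
    positive when it matches some truth domain the same way.
    """
    matched_truth = 0
    matched_called = set()
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, c in enumerate(called):
        by_chrom.setdefault(c.chrom, []).append((i, c))
    for t in truth:
        hit = False
        for i, c in by_chrom.get(t.chrom, []):
            if reciprocal_overlap(t, c) >= min_reciprocal:
                hit = True
                matched_called.add(i)
        if hit:
            matched_truth += 1
    sens = matched_truth / len(truth) if truth else float("nan")
    prec = len(matched_called) / len(called) if called else float("nan")
    return {"sensitivity": sens, "precision": prec,
            "n_called": len(called), "n_truth": len(truth)}


def score_dmr_recovery(
    dmrs: pd.DataFrame,
    truth_dmrs: list[GenomicInterval],
    truth_directions: list[str] | None = None,
) -> dict[str, float]:
    """DMR sensitivity and empirical FDR by >= 1 bp overlap with truth.

    A truth DMR counts as recovered when at least one called region
    overlaps it (with matching direction when directions are supplied); a
    called region overlapping no truth DMR is a false discovery.
    """
    called = [
        (GenomicInterval(r.chrom, int(r.start), int(r.end)),
         getattr(r, "direction", None))
        for r in dmrs.itertuples(index=False)
    ]
    recovered = 0
    for j, t in enumerate(truth_dmrs):
        want = truth_directions[j] if truth_directions else None
        for iv, d in called:
            if iv.overlaps(t) and (want is None or d == want):
                recovered += 1
                break
    false = 0
    for iv, _ in called:
        if not any(iv.overlaps(t) for t in truth_dmrs):
            false += 1
    sens = recovered / len(truth_dmrs) if truth_dmrs else float("nan")
    fdr = false / len(called) if called else 0.0
    return {"sensitivity": sens, "fdr": fdr,
            "n_called": len(called), "n_truth": len(truth_dmrs)}
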