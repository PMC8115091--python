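"""Coverage titration: precision/recall of reduced-coverage call sets
against the full-coverage call set as truth.

Each reduced-coverage call set is matched against the truth with the same
rules used for cross-technology SV comparison (multimatch enabled,
breakpoint distance 1 kb, sizes restricted to [50, 1e6] bp by default).
SNV titration reuses the exact-site comparison through the same driver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .compare import MatchParams, match_callsets, snv_set_compare
from .datamodel import SNVRecord, SVRecord


@dataclass
class TitrationPoint:
    coverage: float
    precision: Optional[float]
    recall: Optional[float]
    n_calls: int
    tp: int
    fp: int
    fn: int


def default_titration_params() -> MatchParams:
    return MatchParams(refdist=1000, sizemin=50, sizemax=1_000_000, multimatch=True)


def titration_curve(
    truth_calls: Sequence[SVRecord],
    callsets_by_coverage: Dict[float, Sequence[SVRecord]],
    params: Optional[MatchParams] = None,
) -> List[TitrationPoint]:
    """One precision/recall point per coverage, ordered by coverage."""
    if not truth_calls:
        raise ValueError("empty truth call set")
    params = params if params is not None else default_titration_params()
    points = []
    for coverage in sorted(callsets_by_coverage):
        calls = callsets_by_coverage[coverage]
        res = match_callsets(truth_calls, calls, params)
        points.append(
            TitrationPoint(
                coverage=coverage,
                precision=res.precision,
                recall=res.recall,
                n_calls=len(calls),
                tp=res.tp,
                fp=res.fp,
                fn=res.fn,
            )
        )
    return points


def snv_titration_curve(
    truth_snvs: Sequence[SNVRecord],
    callsets_by_coverage: Dict[float, Sequence[SNVRecord]],
) -> List[TitrationPoint]:
    """SNV analogue using exact site identity instead of fuzzy matching."""
    if not truth_snvs:
        raise ValueError("empty truth call set")
    points = []
    for coverage in sorted(callsets_by_coverage):
        calls = callsets_by_coverage[coverage]
        shared, only_truth, only_calls = snv_set_compare(truth_snvs, calls)
        tp, fn, fp = len(shared), len(only_truth), len(only_calls)
        points.append(
            TitrationPoint(
                coverage=coverage,
                precision=tp / (tp + fp) if tp + fp else None,
                recall=tp / (tp + fn) if tp + fn else None,
                n_calls=len(calls),
                tp=tp,
                fp=fp,
                fn=fn,
            )
        )
    return points
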