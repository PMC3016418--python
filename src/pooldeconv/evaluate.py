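"""Performance metrics: marker-level recall/precision and per-pool-kind
false-positive / false-negative hit rates against simulation truth."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

from .deconvolution import DeconvolutionResult
from .design import PoolingDesign
from .fpc_io import MarkerHits

__all__ = [
    "MarkerOutcome",
    "MetricsReport",
    "classify_markers",
    "compute_metrics",
    "pool_hit_rates",
    "estimate_error_rates",
    "round_half_up",
]

SCREENED = ("RSP", "CSP", "RP", "CP")


@dataclass(frozen=True)
class MarkerOutcome:
    """Classification of one marker's deconvolution against truth.

    ``TP``: the returned clone set is non-empty and every clone is a planted
    true positive (a strict subset still anchors the right contig).
    ``F+``: the returned set contains at least one non-true clone.
    ``no_solution``: nothing was returned.
    """

    marker: str
    call: str  # TP | F+ | no_solution


@dataclass
class MetricsReport:
    n_markers: int
    n_tp: int
    n_fp: int
    n_no_solution: int
    recall: float
    precision: Optional[float]  # None when no marker has a solution


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding, as used for report presentation."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def classify_markers(
    results: Iterable[DeconvolutionResult], truth_tp: Mapping[str, set[str]]
) -> list[MarkerOutcome]:
    """Deterministically classify every result; truth must cover all markers."""
    outcomes: list[MarkerOutcome] = []
    for res in results:
        if res.marker not in truth_tp:
            raise KeyError(f"marker {res.marker!r} missing from truth")
        returned = res.returned_clones()
        if not returned:
            call = "no_solution"
        elif returned <= truth_tp[res.marker]:
            call = "TP"
        else:
            call = "F+"
        outcomes.append(MarkerOutcome(marker=res.marker, call=call))
    return outcomes


def compute_metrics(outcomes: Iterable[MarkerOutcome]) -> MetricsReport:
    """Recall = TP markers / all markers; precision = TP / markers with solutions."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no marker outcomes to evaluate")
    n_tp = sum(1 for o in outcomes if o.call == "TP")
    n_fp = sum(1 for o in outcomes if o.call == "F+")
    n_no = sum(1 for o in outcomes if o.call == "no_solution")
    n = len(outcomes)
    recall = n_tp / n
    precision = n_tp / (n_tp + n_fp) if (n_tp + n_fp) > 0 else None
    return MetricsReport(
        n_markers=n, n_tp=n_tp, n_fp=n_fp, n_no_solution=n_no, recall=recall, precision=precision
    )


def _hit_sets(mh: MarkerHits) -> dict[str, set]:
    return {"RSP": mh.rsp_hits, "CSP": mh.csp_hits, "RP": mh.rp_hits, "CP": mh.cp_hits}


def pool_hit_rates(
    observed: Iterable[MarkerHits],
    true_hits: Mapping[str, MarkerHits],
    design: Optional[PoolingDesign] = None,
) -> dict[str, tuple[Optional[float], Optional[float]]]:
    """Per pool kind: (F+ rate, F- rate), pooled over markers.

    F+ rate = spurious hits / observed hits; F- rate = missed true hits /
    true hits.  A rate with a zero denominator is None.
    """
    spurious = {k: 0 for k in SCREENED}
    n_obs = {k: 0 for k in SCREENED}
    missed = {k: 0 for k in SCREENED}
    n_true = {k: 0 for k in SCREENED}
    for obs in observed:
        th = true_hits[obs.marker]
        o, t = _hit_sets(obs), _hit_sets(th)
        for k in SCREENED:
            spurious[k] += len(o[k] - t[k])
            n_obs[k] += len(o[k])
            missed[k] += len(t[k] - o[k])
            n_true[k] += len(t[k])
    return {
        k: (
            spurious[k] / n_obs[k] if n_obs[k] else None,
            missed[k] / n_true[k] if n_true[k] else None,
        )
        for k in SCREENED
    }


def estimate_error_rates(
    observed: Iterable[MarkerHits],
    true_hits: Mapping[str, MarkerHits],
    design: PoolingDesign,
) -> dict[str, dict[str, float]]:
    """Per-opportunity estimates of the injected per-pool error probabilities.

    p_fp_hat = spurious hits / (marker, non-true pool) opportunities and
    p_fn_hat = missed hits / (marker, true pool) opportunities, with their
    binomial standard errors and opportunity counts.
    """
    n_pools = {k: design.n_pools(k) for k in SCREENED}
    spurious = {k: 0 for k in SCREENED}
    n_neg = {k: 0 for k in SCREENED}
    missed = {k: 0 for k in SCREENED}
    n_true = {k: 0 for k in SCREENED}
    for obs in observed:
        th = true_hits[obs.marker]
        o, t = _hit_sets(obs), _hit_sets(th)
        for k in SCREENED:
            spurious[k] += len(o[k] - t[k])
            n_neg[k] += n_pools[k] - len(t[k])
            missed[k] += len(t[k] - o[k])
            n_true[k] += len(t[k])
    out: dict[str, dict[str, float]] = {}
    for k in SCREENED:
        p_fp = spurious[k] / n_neg[k] if n_neg[k] else float("nan")
        p_fn = missed[k] / n_true[k] if n_true[k] else float("nan")
        out[k] = {
            "p_fp_hat": p_fp,
            "p_fp_n": n_neg[k],
            "p_fp_se": (p_fp * (1 - p_fp) / n_neg[k]) ** 0.5 if n_neg[k] else float("nan"),
            "p_fn_hat": p_fn,
            "p_fn_n": n_true[k],
            "p_fn_se": (p_fn * (1 - p_fn) / n_true[k]) ** 0.5 if n_true[k] else float("nan"),
        }
    return out
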