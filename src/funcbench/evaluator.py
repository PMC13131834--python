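"""Protein-centric precision/recall/F1 evaluation of GO term predictions.

The prediction task is treated as a collection of per-protein binary
decisions.  For a score threshold tau, with P_i(tau) the predicted terms of
protein i scoring >= tau and T_i its ground-truth set:

    precision(tau) = (1/m(tau)) * sum_{i: |P_i|>0} |P_i & T_i| / |P_i|
    recall(tau)    = (1/n)      * sum_{i=1..n}    |P_i & T_i| / |T_i|

where n is the number of benchmark proteins in the aspect and m(tau) the number
of those with at least one prediction at tau.  F1 is their harmonic mean, and
Fmax — the maximum F1 over a tau grid (default 0.01 .. 1.00, step 0.01) — is
the headline metric.  Ties in Fmax resolve to the smallest tau.  Scores are
compared with a closed lower bound (>= tau).

A micro-averaged variant (pooling protein-term pairs before dividing) is
available through ``averaging="micro"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .baselines import PredictionRecord, PredictionSet
from .benchmark_builder import GroundTruth
from .ontology import ASPECTS, OntologyGraph, ancestors

logger = logging.getLogger(__name__)

DEFAULT_TAU_GRID = tuple(round(t / 100.0, 2) for t in range(1, 101))

ORACLE_MAX_PROTEINS = 50
ORACLE_MAX_TERMS = 200


@dataclass(frozen=True)
class ThresholdMetrics:
    tau: float
    precision: float
    recall: float
    f1: float
    n_covered: int


@dataclass
class AspectResult:
    curve: list[ThresholdMetrics]
    fmax: float
    tau_best: float
    n_benchmark: int


@dataclass
class EvaluationResult:
    method_label: str
    window_label: str
    aspects: dict[str, AspectResult] = field(default_factory=dict)
    skipped_aspects: list[str] = field(default_factory=list)


@dataclass
class ComparisonReport:
    """Fmax deltas between two windows for the methods shared by both."""

    label_a: str
    label_b: str
    rows: list[dict]          # method, aspect, fmax_a, fmax_b, delta
    unshared: dict[str, list[str]]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("method\taspect\tfmax_a\tfmax_b\tdelta\n")
            for row in self.rows:
                fh.write(
                    f"{row['method']}\t{row['aspect']}\t"
                    f"{row['fmax_a']:.4f}\t{row['fmax_b']:.4f}\t{row['delta']:+.4f}\n"
                )


def _f1(precision: float, recall: float) -> float:
    denom = precision + recall
    return 2.0 * precision * recall / denom if denom > 0 else 0.0


def prepare_predictions(
    predictions: PredictionSet,
    graph: OntologyGraph,
    exclude_roots: bool = True,
) -> PredictionSet:
    """Propagate prediction scores up the DAG with the max rule and drop roots.

    score(ancestor) := max(score(ancestor), score(descendant)) for every
    predicted term.  Terms unknown to (or obsolete in) the ontology are dropped
    with a logged count; scores outside (0, 1] raise a validation error.
    Idempotent on already-consistent input.
    """
    offenders = [
        f"{r.protein}\t{r.term}\t{r.score}"
        for r in predictions.records
        if not (0.0 < r.score <= 1.0)
    ]
    if offenders:
        raise ValueError(
            "prediction scores outside (0, 1]:\n" + "\n".join(offenders[:10])
        )
    n_dropped = 0
    per_protein: dict[str, dict[str, float]] = {}
    for r in predictions.records:
        if r.term not in graph.terms:
            n_dropped += 1
            continue
        scores = per_protein.setdefault(r.protein, {})
        scores[r.term] = max(scores.get(r.term, 0.0), r.score)
    if n_dropped:
        logger.warning(
            "%s: dropped %d predictions on unknown/obsolete terms",
            predictions.method_label, n_dropped,
        )
    roots = set(graph.roots.values()) if exclude_roots else set()
    records = []
    for protein in sorted(per_protein):
        scores = per_protein[protein]
        propagated = dict(scores)
        for term, score in scores.items():
            for anc in ancestors(graph, term):
                if propagated.get(anc, 0.0) < score:
                    propagated[anc] = score
        for term in sorted(propagated):
            if term in roots:
                continue
            records.append(PredictionRecord(protein, term, propagated[term]))
    return PredictionSet(
        method_label=predictions.method_label, records=records, propagated=True
    )


def _aspect_sweep(
    pred_by_protein: Mapping[str, Mapping[str, float]],
    gt: Mapping[str, set[str]],
    tau_grid: np.ndarray,
    averaging: str,
) -> AspectResult:
    n = len(gt)
    n_tau = len(tau_grid)
    prec_sum = np.zeros(n_tau)
    rec_sum = np.zeros(n_tau)
    covered = np.zeros(n_tau, dtype=int)
    tp_total = np.zeros(n_tau)
    pred_total = np.zeros(n_tau)
    gt_total = 0
    # sorted order makes the floating-point accumulation independent of input order
    for protein, true_terms in sorted(gt.items()):
        gt_total += len(true_terms)
        scores = pred_by_protein.get(protein, {})
        if scores:
            arr = np.fromiter(scores.values(), dtype=float, count=len(scores))
            truth = np.fromiter(
                (t in true_terms for t in scores), dtype=bool, count=len(scores)
            )
            above = arr[:, None] >= tau_grid[None, :]          # terms x taus
            n_pred = above.sum(axis=0)
            n_tp = (above & truth[:, None]).sum(axis=0)
        else:
            n_pred = np.zeros(n_tau, dtype=int)
            n_tp = np.zeros(n_tau, dtype=int)
        has_pred = n_pred > 0
        covered += has_pred
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(has_pred, n_tp / np.maximum(n_pred, 1), 0.0)
        prec_sum += ratio
        rec_sum += n_tp / len(true_terms)
        tp_total += n_tp
        pred_total += n_pred
    if averaging == "protein":
        precision = np.where(covered > 0, prec_sum / np.maximum(covered, 1), 0.0)
        recall = rec_sum / n
    elif averaging == "micro":
        precision = np.where(pred_total > 0, tp_total / np.maximum(pred_total, 1), 0.0)
        recall = tp_total / gt_total
    else:
        raise ValueError(f"unknown averaging mode {averaging!r}")
    curve = []
    for k in range(n_tau):
        p, r = float(precision[k]), float(recall[k])
        curve.append(
            ThresholdMetrics(
                tau=float(tau_grid[k]), precision=p, recall=r,
                f1=_f1(p, r), n_covered=int(covered[k]),
            )
        )
    f1s = np.array([tm.f1 for tm in curve])
    best = int(np.argmax(f1s))                  # argmax -> first (smallest) tau on ties
    return AspectResult(
        curve=curve, fmax=float(f1s[best]), tau_best=curve[best].tau, n_benchmark=n
    )


def evaluate(
    predictions: PredictionSet,
    ground_truth: GroundTruth,
    graph: OntologyGraph,
    tau_grid: Iterable[float] | None = None,
    averaging: str = "protein",
    window_label: str = "",
) -> EvaluationResult:
    """Sweep the tau grid per aspect and report the full curve plus Fmax.

    *predictions* should already be prepared (see :func:`prepare_predictions`);
    aspects with an empty ground truth are skipped with a warning.
    """
    grid = np.asarray(sorted(tau_grid) if tau_grid is not None else DEFAULT_TAU_GRID,
                      dtype=float)
    pred_by_protein_all = predictions.by_protein()
    result = EvaluationResult(
        method_label=predictions.method_label, window_label=window_label
    )
    for aspect in ASPECTS:
        gt = ground_truth.by_aspect.get(aspect, {})
        if not gt:
            logger.warning("aspect %s has empty ground truth; skipped", aspect)
            result.skipped_aspects.append(aspect)
            continue
        pred_by_protein = {
            protein: {
                t: s for t, s in scores.items()
                if t in graph.terms and graph.aspect_of(t) == aspect
            }
            for protein, scores in pred_by_protein_all.items()
            if protein in gt
        }
        result.aspects[aspect] = _aspect_sweep(pred_by_protein, gt, grid, averaging)
    return result


def fmax_oracle(
    predictions: Mapping[str, Mapping[str, float]],
    ground_truth: Mapping[str, set[str]],
    tau_grid: Iterable[float] | None = None,
) -> tuple[float, float]:
    """Brute-force Fmax on a small instance, by direct set operations.

    Candidate thresholds are every distinct prediction score plus the fixed tau
    grid; precision/recall follow the protein-centric definitions.  Shares no
    code with :func:`evaluate`; intended as an independent cross-check in tests.

    Refuses instances larger than 50 proteins or 200 distinct terms.
    """
    proteins = set(ground_truth)
    all_terms = {t for terms in ground_truth.values() for t in terms}
    for scores in predictions.values():
        all_terms |= set(scores)
    if len(proteins) > ORACLE_MAX_PROTEINS or len(all_terms) > ORACLE_MAX_TERMS:
        raise ValueError(
            f"oracle refuses large instance: {len(proteins)} proteins, "
            f"{len(all_terms)} terms"
        )
    grid = list(tau_grid) if tau_grid is not None else list(DEFAULT_TAU_GRID)
    candidates = sorted(
        set(grid)
        | {s for p in proteins for s in predictions.get(p, {}).values()}
    )
    n = len(proteins)
    best_f1, best_tau = 0.0, min(candidates)
    for tau in candidates:
        precisions = []
        recall_sum = 0.0
        for protein in sorted(proteins):
            pred = {t for t, s in predictions.get(protein, {}).items() if s >= tau}
            true = ground_truth[protein]
            if pred:
                precisions.append(len(pred & true) / len(pred))
            recall_sum += len(pred & true) / len(true)
        precision = sum(precisions) / len(precisions) if precisions else 0.0
        recall = recall_sum / n
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        if f1 > best_f1:
            best_f1, best_tau = f1, tau
    return best_f1, best_tau


def compare_windows(
    a: Iterable[EvaluationResult],
    b: Iterable[EvaluationResult],
) -> ComparisonReport:
    """Per shared method and aspect, pair the Fmax values of two windows."""
    by_method_a = {r.method_label: r for r in a}
    by_method_b = {r.method_label: r for r in b}
    label_a = next(iter(by_method_a.values())).window_label if by_method_a else ""
    label_b = next(iter(by_method_b.values())).window_label if by_method_b else ""
    shared = sorted(by_method_a.keys() & by_method_b.keys())
    if not shared:
        logger.warning("no shared methods between %r and %r", label_a, label_b)
    rows = []
    for method in shared:
        for aspect in ASPECTS:
            ra = by_method_a[method].aspects.get(aspect)
            rb = by_method_b[method].aspects.get(aspect)
            if ra is None or rb is None:
                continue
            rows.append(
                {
                    "method": method,
                    "aspect": aspect,
                    "fmax_a": round(ra.fmax, 4),
                    "fmax_b": round(rb.fmax, 4),
                    "delta": round(rb.fmax - ra.fmax, 4),
                }
            )
    unshared = {
        "a_only": sorted(by_method_a.keys() - by_method_b.keys()),
        "b_only": sorted(by_method_b.keys() - by_method_a.keys()),
    }
    return ComparisonReport(label_a=label_a, label_b=label_b, rows=rows,
                            unshared=unshared)


def export_curves(result: EvaluationResult, out_dir) -> Path:
    """Write one curve TSV per aspect plus a JSON summary; deterministic bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "method": result.method_label,
        "window": result.window_label,
        "aspects": {},
        "skipped": sorted(result.skipped_aspects),
    }
    for aspect in sorted(result.aspects):
        ar = result.aspects[aspect]
        with open(out / f"curve_{aspect}.tsv", "w") as fh:
            fh.write("tau\tprecision\trecall\tf1\tn_covered\n")
            for tm in ar.curve:
                fh.write(
                    f"{tm.tau:.2f}\t{tm.precision:.6f}\t{tm.recall:.6f}\t"
                    f"{tm.f1:.6f}\t{tm.n_covered}\n"
                )
        summary["aspects"][aspect] = {
            "fmax": round(ar.fmax, 6),
            "tau_best": ar.tau_best,
            "n_benchmark": ar.n_benchmark,
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
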