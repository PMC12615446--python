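"""Long-read validation filtering plus fusion-caller benchmarking metrics."""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AlignmentHit, FusionCall


@dataclass
class ValidationResult:
    fusion_id: str
    n_supporting_hits: int
    validated: bool
    est_length: int | None  # subject length of the best supporting hit


@dataclass
class BenchmarkMetrics:
    tool: str
    tp: int
    fp: int
    tf: int
    sensitivity: float  # percent
    precision: float  # percent
    f_measure: float  # 0-1 scale


def filter_longread_hits(
    hits: list[AlignmentHit],
    min_identity: float = 80.0,
    min_len: int = 150,
    strict: bool = True,
) -> list[ValidationResult]:
    """Group hits by query and keep those clearing both thresholds.

    Default comparisons are strict (identity > min_identity and alignment
    length > min_len).  A fusion is validated iff it keeps >= 1 hit; its
    estimated transcript length is the subject length of its best-bitscore
    supporting hit (when the slen column was present).
    """
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)

    def _passes(h: AlignmentHit) -> bool:
        if strict:
            return h.pct_identity > min_identity and h.aln_len > min_len
        return h.pct_identity >= min_identity and h.aln_len >= min_len

    out: list[ValidationResult] = []
    for query_id, qhits in by_query.items():
        supporting = [h for h in qhits if _passes(h)]
        est = None
        if supporting:
            best = max(supporting, key=lambda h: h.bitscore)
            est = best.subject_len
        out.append(
            ValidationResult(
                fusion_id=query_id,
                n_supporting_hits=len(supporting),
                validated=bool(supporting),
                est_length=est,
            )
        )
    return out


def _match_key(call: FusionCall) -> tuple[str, str]:
    return (call.gene5, call.gene3)


def benchmark_metrics(
    per_tool_predictions: dict[str, list[FusionCall]],
    truth_pairs: list[tuple[str, str]],
    match_tolerance: int = 0,
    truth_breakpoints: dict[tuple[str, str], tuple[int, int]] | None = None,
) -> list[BenchmarkMetrics]:
    """Sensitivity/precision/F per tool against a truth set of ordered pairs.

    S = 100*TP/TF, P = 100*TP/(TP+FP) (0 when no predictions), F = harmonic
    mean of S and P on the 0-1 scale.  Matching uses the ordered gene-pair
    key; when ``truth_breakpoints`` is given, breakpoints must additionally
    agree within ``match_tolerance``.  Tools are ranked by F then S.
    """
    if not truth_pairs:
        raise ValueError("truth set must be nonempty")
    truth = set(truth_pairs)
    tf = len(truth)
    out: list[BenchmarkMetrics] = []
    for tool, preds in per_tool_predictions.items():
        matched: set[tuple[str, str]] = set()
        n_fp = 0
        seen_pred: set[tuple] = set()
        for call in preds:
            key = _match_key(call)
            pred_key = (key, call.bp5, call.bp3)
            if pred_key in seen_pred:
                continue
            seen_pred.add(pred_key)
            ok = key in truth
            if ok and truth_breakpoints is not None:
                tbp5, tbp3 = truth_breakpoints[key]
                ok = abs(call.bp5 - tbp5) <= match_tolerance and abs(call.bp3 - tbp3) <= match_tolerance
            if ok:
                matched.add(key)
            else:
                n_fp += 1
        tp = len(matched)
        sens = 100.0 * tp / tf
        prec = 100.0 * tp / (tp + n_fp) if (tp + n_fp) > 0 else 0.0
        f = 2 * (sens / 100) * (prec / 100) / ((sens + prec) / 100) if (sens + prec) > 0 else 0.0
        out.append(BenchmarkMetrics(tool, tp, n_fp, tf, sens, prec, f))
    out.sort(key=lambda m: (-m.f_measure, -m.sensitivity, m.tool))
    return out


def write_metrics(path, metrics: list[BenchmarkMetrics]) -> None:
    with open(path, "w") as fh:
        fh.write("tool\tTP\tFP\tTF\tsensitivity_pct\tprecision_pct\tF\n")
        for m in metrics:
            fh.write(
                f"{m.tool}\t{m.tp}\t{m.fp}\t{m.tf}\t{m.sensitivity:.2f}\t"
                f"{m.precision:.2f}\t{m.f_measure:.4f}\n"
            )


def write_validation(path, results: list[ValidationResult]) -> None:
    with open(path, "w") as fh:
        fh.write("fusion_id\tn_supporting_hits\tvalidated\test_length\n")
        for r in results:
            est = r.est_length if r.est_length is not None else "."
            fh.write(f"{r.fusion_id}\t{r.n_supporting_hits}\t{str(r.validated).lower()}\t{est}\n")
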