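"""Parental-gene co-expression, fusion-present vs fusion-absent fold changes,
and Livak 2^-ddCt relative quantification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FoldChangeResult:
    gene: str
    fusion_id: str
    mean_fp: float
    mean_fa: float
    fc: float
    status: str  # up | down | unchanged


@dataclass
class DdctResult:
    target_gene: str
    reference_gene: str
    dct_control: list[float]
    dct_treated: list[float]
    ddct: float
    rq: float
    rq_mean: float
    rq_sd: float
    p_value: float


def parental_correlation(
    expr_matrix: pd.DataFrame,
    pairs: list[tuple[str, str]],
    log_base: float = 2.0,
) -> tuple[float, np.ndarray]:
    """Pearson R between log(TPM+1) of 5' and 3' parents over fusion pairs.

    Each pair contributes one point: its parents' mean-across-samples TPM.
    """
    pts = []
    for g5, g3 in pairs:
        if g5 in expr_matrix.index and g3 in expr_matrix.index:
            m5 = float(expr_matrix.loc[g5].mean())
            m3 = float(expr_matrix.loc[g3].mean())
            pts.append((np.log(m5 + 1) / np.log(log_base), np.log(m3 + 1) / np.log(log_base)))
    if len(pts) < 3:
        raise ValueError("need >= 3 pairs with both genes present")
    points = np.asarray(pts)
    x, y = points[:, 0], points[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate correlation: zero-variance axis")
    r = float(stats.pearsonr(x, y).statistic)
    return r, points


def fp_fa_fold_change(
    expr_matrix: pd.DataFrame,
    fusion_presence: dict[str, set[str]],
    fusion_genes: dict[str, tuple[str, str]],
    fc_threshold: float = 2.0,
) -> list[FoldChangeResult]:
    """Fold change of each parental gene between fusion-present (F/P) and
    fusion-absent (F/A) samples; fc = (mean_fp + 1) / (mean_fa + 1).

    Fusions with an empty F/A or F/P group are skipped with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    all_samples = list(expr_matrix.columns)
    results: list[FoldChangeResult] = []
    for fusion_id, fp_samples in fusion_presence.items():
        fp = [s for s in all_samples if s in fp_samples]
        fa = [s for s in all_samples if s not in fp_samples]
        if not fp or not fa:
            logger.warning("fusion %s: empty F/P or F/A group, skipped", fusion_id)
            continue
        for gene in fusion_genes[fusion_id]:
            if gene not in expr_matrix.index:
                raise KeyError(f"gene {gene} not in expression matrix")
            mean_fp = float(expr_matrix.loc[gene, fp].mean())
            mean_fa = float(expr_matrix.loc[gene, fa].mean())
            fc = (mean_fp + 1.0) / (mean_fa + 1.0)
            if fc >= fc_threshold:
                status = "up"
            elif fc <= 1.0 / fc_threshold:
                status = "down"
            else:
                status = "unchanged"
            results.append(FoldChangeResult(gene, fusion_id, mean_fp, mean_fa, fc, status))
    return results


def ddct(
    ct_table: pd.DataFrame,
    target: str,
    reference: str,
    control_label: str,
    treated_label: str,
) -> DdctResult:
    """Livak relative quantification with Welch's t-test on per-replicate dCt.

    ``ct_table`` columns: sample_id, group, gene, ct, replicate.
    dCt = Ct_target - Ct_reference per replicate; ddCt = mean dCt(treated) -
    mean dCt(control); RQ = 2^-ddCt.  Per-replicate RQ values (against the
    control-group mean dCt) give the reported mean +/- SD.
    """
    required = {"group", "gene", "ct", "replicate"}
    if not required <= set(ct_table.columns):
        raise ValueError(f"ct table missing columns: {required - set(ct_table.columns)}")

    def _dcts(label: str) -> np.ndarray:
        sub = ct_table[ct_table["group"] == label]
        tgt = sub[sub["gene"] == target].set_index("replicate")["ct"]
        ref = sub[sub["gene"] == reference].set_index("replicate")["ct"]
        if tgt.empty:
            raise ValueError(f"no Ct values for target {target!r} in group {label!r}")
        missing = set(tgt.index) - set(ref.index)
        if missing or ref.empty:
            raise ValueError(f"missing reference Ct for group {label!r}")
        return (tgt - ref.loc[tgt.index]).to_numpy(dtype=float)

    dct_c = _dcts(control_label)
    dct_t = _dcts(treated_label)
    if len(dct_c) < 2 or len(dct_t) < 2:
        raise ValueError("need >= 2 replicates per group")
    ddct_val = float(dct_t.mean() - dct_c.mean())
    rq = float(2.0 ** -ddct_val)
    rq_reps = 2.0 ** -(dct_t - dct_c.mean())
    if np.allclose(dct_c, dct_c[0]) and np.allclose(dct_t, dct_t[0]):
        p = 1.0 if np.isclose(dct_c[0], dct_t[0]) else 0.0
    else:
        p = float(stats.ttest_ind(dct_c, dct_t, equal_var=False).pvalue)
    return DdctResult(
        target_gene=target,
        reference_gene=reference,
        dct_control=dct_c.tolist(),
        dct_treated=dct_t.tolist(),
        ddct=ddct_val,
        rq=rq,
        rq_mean=float(rq_reps.mean()),
        rq_sd=float(rq_reps.std(ddof=1)),
        p_value=p,
    )


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "gene", "ct", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    return df


def write_fold_changes(path, results: list[FoldChangeResult]) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tfusion_id\tmean_fp\tmean_fa\tfc\tstatus\n")
        for r in results:
            fh.write(
                f"{r.gene}\t{r.fusion_id}\t{r.mean_fp:.6g}\t{r.mean_fa:.6g}\t"
                f"{r.fc:.6g}\t{r.status}\n"
            )
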