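"""Per-compartment differential expression against the control.

A transcript is called significant in a comparison when its log2 fold change
is strictly greater than 1 or strictly less than −1 *and* its p-value is at
or below the compartment threshold (1e-4 for coral and Symbiodiniaceae,
1e-3 for prokaryotes). A transcript significant in at least one
treatment-vs-control comparison is a differentially expressed transcript
(DET). The module also provides the ordination input transform
sqrt(log2(CPM+1)) and Bray–Curtis sample dissimilarities.

The two-group test is pluggable; the default is Welch's t on log2(CPM+1),
which is approximately calibrated for moderately dispersed count data and
keeps the stage free of any particular count-model fitting machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import DataError, DesignError
from .simulate import COMPARISONS, ExpressionMatrix

#: Per-compartment p-value thresholds for DET calling.
P_THRESHOLDS: dict[str, float] = {
    "coral": 1e-4,
    "symbiodiniaceae": 1e-4,
    "prokaryote": 1e-3,
}

#: Strict |logFC| cutoff: significant means logFC > 1 or logFC < −1.
LOGFC_CUTOFF: float = 1.0


def cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: value[i, j] = count[i, j] / colsum[j] × 1e6."""
    if counts.unit != "count":
        raise DataError("cpm() expects a raw count matrix")
    colsums = counts.data.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise DataError(f"zero library size for sample {zero.index[0]!r}")
    out = counts.data / colsums * 1e6
    return ExpressionMatrix(compartment=counts.compartment, unit="cpm", data=out)


def welch_t_log(treat: np.ndarray, ctrl: np.ndarray) -> float:
    """Two-sided Welch t-test on log2(CPM + 1); returns the p-value."""
    res = stats.ttest_ind(
        np.log2(treat + 1.0), np.log2(ctrl + 1.0), equal_var=False
    )
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def pairwise_de(
    cpm_mat: ExpressionMatrix,
    design: pd.DataFrame,
    treatment: str,
    test: Callable[[np.ndarray, np.ndarray], float] = welch_t_log,
    prior: float = 1.0,
) -> pd.DataFrame:
    """One treatment-vs-control comparison for every transcript.

    logFC = log2((mean treatment CPM + prior) / (mean control CPM + prior));
    the pseudo-CPM ``prior`` stabilizes fold changes at zeros. Returns a
    DataFrame with columns transcript_id, comparison, logFC, p_value,
    significant (the strict |logFC| > 1 rule at the compartment threshold).
    """
    if cpm_mat.unit != "cpm":
        raise DataError("pairwise_de() expects a CPM matrix")
    if treatment == "control":
        raise DesignError("treatment must differ from the control")
    t_samples = design.loc[design["treatment"] == treatment, "sample_id"]
    c_samples = design.loc[design["treatment"] == "control", "sample_id"]
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise DesignError(
            f"need >= 2 replicates per group (treatment {treatment!r}: "
            f"{len(t_samples)}, control: {len(c_samples)})"
        )
    T = cpm_mat.data[list(t_samples)].to_numpy(dtype=float)
    C = cpm_mat.data[list(c_samples)].to_numpy(dtype=float)
    logfc = np.log2((T.mean(axis=1) + prior) / (C.mean(axis=1) + prior))
    pvals = np.array([test(T[i], C[i]) for i in range(T.shape[0])])
    thr = P_THRESHOLDS[cpm_mat.compartment]
    out = pd.DataFrame(
        {
            "transcript_id": cpm_mat.data.index,
            "comparison": f"control_vs_{treatment}",
            "logFC": logfc,
            "p_value": pvals,
        }
    )
    out["significant"] = (np.abs(out["logFC"]) > LOGFC_CUTOFF) & (
        out["p_value"] <= thr
    )
    return out


@dataclass
class DETSet:
    """Per-comparison significant transcripts for one compartment.

    ``venn_counts`` maps each nonempty comparison subset (as a sorted
    '&'-joined key) to the number of DETs significant in exactly that subset;
    the counts sum to the union size.
    """

    compartment: str
    per_comparison: dict[str, set] = field(default_factory=dict)
    union: set = field(default_factory=set)
    venn_counts: dict[str, int] = field(default_factory=dict)
    up_down: pd.DataFrame | None = None

    @property
    def shared_all(self) -> set:
        """DETs significant in every comparison."""
        sets = list(self.per_comparison.values())
        return set.intersection(*sets) if sets else set()


def call_dets(
    de_results: Mapping[str, pd.DataFrame] | pd.DataFrame,
    compartment: str,
) -> DETSet:
    """Union DETs, Venn region counts and per-comparison up/down counts.

    ``de_results`` is either one concatenated pairwise_de() table or a mapping
    comparison -> table; all four comparisons must be present.
    """
    if isinstance(de_results, pd.DataFrame):
        table = de_results
    else:
        table = (
            pd.concat(de_results.values(), ignore_index=True)
            if de_results
            else pd.DataFrame(
                columns=["transcript_id", "comparison", "logFC", "p_value", "significant"]
            )
        )
    present = set(table["comparison"].unique())
    missing = set(COMPARISONS) - present
    if missing and len(table):
        raise DesignError(f"missing comparisons: {sorted(missing)}")

    per_comp: dict[str, set] = {c: set() for c in COMPARISONS}
    sig = table[table["significant"]] if len(table) else table
    for c, grp in sig.groupby("comparison"):
        per_comp[c] = set(grp["transcript_id"])
    union = set().union(*per_comp.values()) if per_comp else set()

    membership: dict[str, tuple] = {}
    for tid in union:
        key = tuple(sorted(c for c, s in per_comp.items() if tid in s))
        membership[tid] = key
    venn: dict[str, int] = {}
    for r in range(1, len(COMPARISONS) + 1):
        for combo in combinations(sorted(COMPARISONS), r):
            n = sum(1 for k in membership.values() if k == combo)
            if n:
                venn["&".join(combo)] = n

    rows = []
    for c in COMPARISONS:
        sub = sig[sig["comparison"] == c] if len(sig) else sig
        rows.append(
            {
                "comparison": c,
                "up": int((sub["logFC"] > 0).sum()) if len(sub) else 0,
                "down": int((sub["logFC"] < 0).sum()) if len(sub) else 0,
            }
        )
    return DETSet(
        compartment=compartment,
        per_comparison=per_comp,
        union=union,
        venn_counts=venn,
        up_down=pd.DataFrame(rows),
    )


def ordination_transform(cpm_mat: ExpressionMatrix) -> pd.DataFrame:
    """sqrt(log2(CPM + 1)), the input transform for ordination."""
    if cpm_mat.unit != "cpm":
        raise DataError("ordination_transform() expects a CPM matrix")
    vals = cpm_mat.data.to_numpy(dtype=float)
    if (vals < 0).any():
        raise DataError("negative values in CPM matrix")
    return pd.DataFrame(
        np.sqrt(np.log2(vals + 1.0)),
        index=cpm_mat.data.index,
        columns=cpm_mat.data.columns,
    )


def bray_curtis(transformed: pd.DataFrame) -> pd.DataFrame:
    """Sample × sample Bray–Curtis dissimilarity, d(u,v) = Σ|u−v| / Σ(u+v).

    Columns are samples; the result is a symmetric square DataFrame with a
    zero diagonal and entries in [0, 1].
    """
    X = transformed.to_numpy(dtype=float).T
    if (X < 0).any():
        raise DataError("Bray–Curtis requires nonnegative values")
    d = squareform(pdist(X, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # two all-zero samples: define d = 0
    return pd.DataFrame(d, index=transformed.columns, columns=transformed.columns)
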