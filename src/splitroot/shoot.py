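"""Shoot differential expression: one-way ANOVA, BH FDR, and Tukey coding.

At each time point the shoot transcriptome is tested gene-by-gene with a
one-way ANOVA over the three nitrogen conditions (C.NO3, Split, C.Cl); genes
passing a Benjamini-Hochberg FDR cutoff (10% by default) are differentially
expressed. Each DEG's pattern is then summarized by a three-digit Tukey code
``T1 T2 T3`` from post-hoc Tukey HSD pairwise comparisons:

* T1: C.NO3 vs C.Cl, * T2: Split vs C.Cl, * T3: Split vs C.NO3,

with +1 when the first condition is significantly greater, -1 when smaller,
0 when the comparison is not significant at ``alpha``. Codes with at least
two significant digits define a regulation group; the biologically named
pattern classes are:

* ``split_induced``   — up in split plants vs both controls (T2=+1, T3=+1);
* ``split_repressed`` — down in split plants vs both controls (T2=-1, T3=-1);
* ``n_tracking_class``   — expression follows N supply, C.NO3 > Split > C.Cl
  in the full pattern (T1=+1, T2>=0, T3<=0);
* ``depletion_induced``  — up under homogeneous depletion (T1=-1, T2<=0, T3>=0).
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, SHOOT_CONDITIONS
from .preprocess import log2_transform

#: the three Tukey comparisons as (first, second) condition names
SHOOT_COMPARISONS = (
    ("C.NO3", "C.Cl"),
    ("Split", "C.Cl"),
    ("Split", "C.NO3"),
)

PATTERN_CLASSES = (
    "split_induced",
    "split_repressed",
    "n_tracking_class",
    "depletion_induced",
    "ambiguous",
    "not_de",
)

#: canonical enumeration of all 27 codes: lexicographic in (t1, t2, t3)
#: over digits (-1, 0, +1); group ids are 1-based positions in this table
CODE_TABLE: tuple[tuple[int, int, int], ...] = tuple(
    itertools.product((-1, 0, 1), repeat=3)
)


class TukeyCode(NamedTuple):
    t1: int
    t2: int
    t3: int


class AnalysisError(ValueError):
    """Raised for invalid inputs to the differential-expression analyses."""


# -- one-way ANOVA ----------------------------------------------------------

def _anova_f_vectorized(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """F statistics and p-values per gene; groups are genes x reps arrays.

    Degenerate genes (zero within-group variance) get p = 1 when all group
    means coincide and p = 0 otherwise.
    """
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    if (ns < 2).any():
        raise AnalysisError("each condition needs >= 2 replicates")
    N = int(ns.sum())
    means = np.column_stack([g.mean(axis=1) for g in groups])  # G x k
    grand = np.concatenate(groups, axis=1).mean(axis=1)
    ssb = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros_like(ssb)
    for g, m in zip(groups, means.T):
        ssw += ((g - m[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, N - k
    # degenerate zero-variance genes, judged with a relative tolerance so
    # that float noise in the sums of squares cannot flip the rule
    tol = 1e-18 * (1.0 + grand**2)
    degenerate = ssw <= tol
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = np.where(
        ~degenerate,
        stats.f.sf(np.where(~degenerate, f, 0.0), df_b, df_w),
        np.where(ssb > tol, 0.0, 1.0),
    )
    f = np.where(~degenerate, f, np.where(ssb > tol, np.inf, np.nan))
    return f, p


def anova_three_condition(values_by_condition) -> float:
    """One-way ANOVA p-value for one gene's three condition groups."""
    groups = [np.asarray(v, dtype=float).reshape(1, -1) for v in values_by_condition]
    if len(groups) != 3:
        raise AnalysisError("exactly three conditions are required")
    _, p = _anova_f_vectorized(groups)
    return float(p[0])


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise AnalysisError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# -- Tukey HSD coding -------------------------------------------------------

@lru_cache(maxsize=None)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(stats.studentized_range.isf(alpha, k, df))


def _tukey_digits_vectorized(
    groups: dict[str, np.ndarray], comparisons, alpha: float
) -> np.ndarray:
    """Signed significance digit per comparison, genes x comparisons.

    Tukey-Kramer form: |mean_i - mean_j| compared with
    ``q(1-alpha; k, df) * sqrt(MSE/2 * (1/n_i + 1/n_j))``, which reduces to
    the classic equal-n HSD here since the design is balanced. Zero-MSE
    genes: tied means give 0 (no evidence), distinct means give the sign.
    """
    names = list(groups)
    k = len(names)
    ns = {c: groups[c].shape[1] for c in names}
    N = sum(ns.values())
    means = {c: groups[c].mean(axis=1) for c in names}
    ssw = sum(((groups[c] - means[c][:, None]) ** 2).sum(axis=1) for c in names)
    df_w = N - k
    mse = ssw / df_w
    qc = _q_crit(alpha, k, df_w)
    out = np.zeros((next(iter(groups.values())).shape[0], len(comparisons)), dtype=int)
    grand = sum(means[c] * ns[c] for c in names) / N
    tol = 1e-9 * (1.0 + np.abs(grand))
    for j, (c1, c2) in enumerate(comparisons):
        diff = means[c1] - means[c2]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[c1] + 1.0 / ns[c2]))
        with np.errstate(divide="ignore", invalid="ignore"):
            sig = np.where(se > tol, np.abs(diff) >= qc * se, np.abs(diff) > tol)
        out[:, j] = np.where(sig, np.sign(diff).astype(int), 0)
    return out


def tukey_code(values_by_condition, alpha: float = 0.05) -> TukeyCode:
    """Tukey code for one gene given (C.NO3, Split, C.Cl) replicate vectors."""
    if len(values_by_condition) != 3:
        raise AnalysisError("exactly three conditions are required")
    groups = {
        cond: np.asarray(v, dtype=float).reshape(1, -1)
        for cond, v in zip(SHOOT_CONDITIONS, values_by_condition)
    }
    if any(g.shape[1] < 2 for g in groups.values()):
        raise AnalysisError("each condition needs >= 2 replicates")
    digits = _tukey_digits_vectorized(groups, SHOOT_COMPARISONS, alpha)[0]
    return TukeyCode(*digits.tolist())


def assign_regulation_group(code: TukeyCode) -> tuple[int | None, str]:
    """Regulation-group id and pattern class for a Tukey code.

    The group id is the 1-based position of the code in :data:`CODE_TABLE`
    (all 27 codes, lexicographic in (t1, t2, t3) over digits -1 < 0 < +1).
    Codes with fewer than two significant digits have no clearly defined
    pattern: their group id is None and their class ``ambiguous``.
    """
    code = TukeyCode(*code)
    if sum(d != 0 for d in code) < 2:
        return None, "ambiguous"
    group_id = CODE_TABLE.index(tuple(code)) + 1
    t1, t2, t3 = code
    if t2 == 1 and t3 == 1:
        cls = "split_induced"
    elif t2 == -1 and t3 == -1:
        cls = "split_repressed"
    elif t1 == 1 and t2 >= 0 and t3 <= 0:
        cls = "n_tracking_class"
    elif t1 == -1 and t2 <= 0 and t3 >= 0:
        cls = "depletion_induced"
    else:
        cls = "ambiguous"
    return group_id, cls


# -- per-time-point pipeline ------------------------------------------------

def shoot_deg_pipeline(
    shoot: ExpressionMatrix,
    fdr_cutoff: float = 0.10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ANOVA + BH + Tukey coding of every time point of a shoot matrix.

    Expects a low-expression-filtered matrix; linear-scale input is log2
    transformed first. Returns one row per (gene, time point) with columns
    ``gene_id, time_h, p_anova, fdr, t1, t2, t3, group_id, pattern_class``;
    codes and classes are attached only to DEGs (``fdr <= fdr_cutoff``),
    other genes are ``not_de`` with zero digits.
    """
    if shoot.scale == "linear":
        shoot = log2_transform(shoot)
    frames = []
    for t in shoot.time_points():
        sub = shoot.select(time_h=t)
        groups = {}
        for cond in SHOOT_CONDITIONS:
            block = sub.select(condition=cond).ordered(("replicate",))
            if block.n_samples == 0:
                raise AnalysisError(f"time {t} h: condition {cond!r} is missing")
            groups[cond] = block.values.to_numpy(dtype=float)
        _, p = _anova_f_vectorized([groups[c] for c in SHOOT_CONDITIONS])
        fdr = benjamini_hochberg(p)
        is_deg = fdr <= fdr_cutoff
        digits = np.zeros((shoot.n_genes, 3), dtype=int)
        if is_deg.any():
            deg_groups = {c: groups[c][is_deg] for c in SHOOT_CONDITIONS}
            digits[is_deg] = _tukey_digits_vectorized(
                deg_groups, SHOOT_COMPARISONS, alpha
            )
        group_ids: list[float | None] = []
        classes = []
        for i, deg in enumerate(is_deg):
            if not deg:
                group_ids.append(None)
                classes.append("not_de")
            else:
                gid, cls = assign_regulation_group(TukeyCode(*digits[i]))
                group_ids.append(gid)
                classes.append(cls)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": shoot.gene_ids,
                    "time_h": t,
                    "p_anova": p,
                    "fdr": fdr,
                    "t1": digits[:, 0],
                    "t2": digits[:, 1],
                    "t3": digits[:, 2],
                    "group_id": pd.array(group_ids, dtype="Int64"),
                    "pattern_class": classes,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def shoot_deg_set(records: pd.DataFrame) -> set[str]:
    """Genes differentially expressed at any time point."""
    return set(records.loc[records["pattern_class"] != "not_de", "gene_id"])
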