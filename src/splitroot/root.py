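"""Root differential expression by pairwise rank products and RP coding.

The two root halves of a split plant are harvested from the same individual,
so their transcriptomes are interdependent and a joint multi-condition model
is inappropriate; instead each of the six condition contrasts is tested
separately with the rank-product statistic:

1. C.NO3 vs Sp.NO3,  2. C.NO3 vs Sp.Cl,  3. C.NO3 vs C.Cl,
4. Sp.NO3 vs Sp.Cl,  5. Sp.NO3 vs C.Cl,  6. Sp.Cl vs C.Cl.

For a contrast (A, B) with replicates paired by index, each replicate i
yields per-gene log fold changes d_i = b_i - a_i; genes are ranked by
decreasing d_i (rank 1 = most up in B) and the up-regulation rank product is
the geometric mean of a gene's ranks across replicates (down-regulation uses
-d_i). Significance is the permutation-based percentage of false prediction
(PFP): null rank products are generated by shuffling each replicate's rank
vector independently, and for the gene at sorted position j,
``PFP = E[null rank products <= observed] / j``. A gene's RP-code digit for
the contrast is +1 when the up tail passes the cutoff (first condition
lower), -1 for the down tail, 0 otherwise, giving a six-digit code R1..R6.

Genes with R1 != 0 respond to the systemic N-demand signal (C.NO3 vs Sp.NO3
differ only in whole-plant N status); genes with R6 != 0 respond to the
systemic N-supply signal (C.Cl vs Sp.Cl).
"""

from __future__ import annotations

import itertools
from math import factorial

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix
from .preprocess import log2_transform

ROOT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("C.NO3", "Sp.NO3"),
    ("C.NO3", "Sp.Cl"),
    ("C.NO3", "C.Cl"),
    ("Sp.NO3", "Sp.Cl"),
    ("Sp.NO3", "C.Cl"),
    ("Sp.Cl", "C.Cl"),
)

EXHAUSTIVE_LIMIT = 10**6  # enumerate all (G!)^k joint permutations below this


class RankProductError(ValueError):
    pass


def _rank_columns(d: np.ndarray) -> np.ndarray:
    """Per-replicate descending ranks (rank 1 = largest d); average ties."""
    return np.column_stack(
        [rankdata(-d[:, i], method="average") for i in range(d.shape[1])]
    )


def _rank_product(ranks: np.ndarray) -> np.ndarray:
    return np.exp(np.log(ranks).mean(axis=1))


def _null_rp_sample(
    ranks: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null rank products from n_perm independent shuffles of each column."""
    G, k = ranks.shape
    out = np.empty((n_perm, G))
    logr = np.log(ranks)
    for p in range(n_perm):
        acc = np.zeros(G)
        for i in range(k):
            acc += logr[rng.permutation(G), i]
        out[p] = np.exp(acc / k)
    return out.ravel()


def _null_rp_exhaustive(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """All null rank products over every joint permutation of the columns."""
    G, k = ranks.shape
    n_joint = factorial(G) ** k
    cols = [list(itertools.permutations(ranks[:, i])) for i in range(k)]
    vals = []
    for assignment in itertools.product(*cols):
        arr = np.array(assignment).T  # G x k
        vals.append(_rank_product(arr))
    return np.concatenate(vals), n_joint


def _pfp_from_null(rp: np.ndarray, null_sorted: np.ndarray, n_draws: int) -> np.ndarray:
    """PFP per gene: expected null count at or below observed / sorted rank."""
    expected = np.searchsorted(null_sorted, rp, side="right") / n_draws
    j = rankdata(rp, method="max")  # genes called if thresholding at rp_g
    return expected / j


def rank_product_contrast(
    a_reps: np.ndarray,
    b_reps: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    gene_ids=None,
    mode: str = "auto",
) -> pd.DataFrame:
    """Rank-product statistics and PFPs for one contrast (A, B).

    Parameters
    ----------
    a_reps, b_reps
        Genes x replicates log-scale values, replicates paired by column.
    n_perm
        Permutations for the sampled null (ignored when enumeration runs).
    mode
        ``auto`` enumerates all (G!)^k joint rank permutations when that is
        at most ``EXHAUSTIVE_LIMIT`` and samples otherwise; ``sample`` and
        ``exhaustive`` force one path.

    Returns a DataFrame with ``rp_up, rp_down, pfp_up, pfp_down`` per gene.
    PFP values are reported untruncated and may exceed 1.
    """
    a = np.asarray(a_reps, dtype=float)
    b = np.asarray(b_reps, dtype=float)
    if a.shape != b.shape:
        raise RankProductError(
            f"replicate mismatch: A is {a.shape}, B is {b.shape}"
        )
    if n_perm < 1:
        raise RankProductError("n_perm must be >= 1")
    G, k = a.shape
    d = b - a
    ranks_up = _rank_columns(d)
    ranks_down = _rank_columns(-d)
    rp_up = _rank_product(ranks_up)
    rp_down = _rank_product(ranks_down)

    if mode not in ("auto", "sample", "exhaustive"):
        raise RankProductError(f"unknown mode {mode!r}")
    exhaustive = mode == "exhaustive" or (
        mode == "auto" and factorial(G) ** k <= EXHAUSTIVE_LIMIT
    )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = {}
    for tail, ranks, rp in (("up", ranks_up, rp_up), ("down", ranks_down, rp_down)):
        if exhaustive:
            null_vals, n_draws = _null_rp_exhaustive(ranks)
        else:
            null_vals, n_draws = _null_rp_sample(ranks, n_perm, rng), n_perm
        null_vals.sort()
        # observed RPs carry float noise from the log-mean-exp; tolerate it
        # when counting null values at or below the observed statistic
        out[f"pfp_{tail}"] = _pfp_from_null(rp * (1 + 1e-12), null_vals, n_draws)
        out[f"rp_{tail}"] = rp
    index = gene_ids if gene_ids is not None else pd.RangeIndex(G)
    return pd.DataFrame(
        {k_: out[k_] for k_ in ("rp_up", "rp_down", "pfp_up", "pfp_down")},
        index=index,
    )


def rp_code_assemble(
    results: dict[int, pd.DataFrame], pfp_cutoff: float = 0.10
) -> pd.DataFrame:
    """Six-digit RP codes from per-contrast rank-product results.

    ``results`` maps contrast number (1..6) to a :func:`rank_product_contrast`
    frame on a shared gene universe. Digit semantics: +1 when the up tail
    passes (first condition lower), -1 when the down tail passes; when both
    tails pass the smaller PFP wins and an exact tie gives 0. The
    ``group_id`` column indexes the code among the distinct nonzero codes
    observed (lexicographic order, 1-based); all-zero codes are non-DEG and
    get no group.
    """
    missing = [i for i in range(1, 7) if i not in results]
    if missing:
        raise RankProductError(f"missing contrasts: {missing}")
    index = results[1].index
    digits = np.zeros((len(index), 6), dtype=int)
    for i in range(1, 7):
        r = results[i]
        if not r.index.equals(index):
            raise RankProductError(f"contrast {i}: gene universe differs")
        up = (r["pfp_up"] <= pfp_cutoff).to_numpy()
        down = (r["pfp_down"] <= pfp_cutoff).to_numpy()
        both = up & down
        d = np.where(up, 1, 0) + np.where(down, -1, 0)  # both -> 0 via sum
        tie_break = np.sign(r["pfp_down"] - r["pfp_up"]).astype(int)
        d = np.where(both, tie_break, d)
        digits[:, i - 1] = d
    code_df = pd.DataFrame(
        digits, index=index, columns=[f"r{i}" for i in range(1, 7)]
    )
    nonzero = code_df.loc[(digits != 0).any(axis=1)]
    observed = sorted({tuple(row) for row in nonzero.to_numpy()})
    lookup = {code: i + 1 for i, code in enumerate(observed)}
    code_df["group_id"] = [
        lookup.get(tuple(row)) for row in digits
    ]
    return code_df


def systemic_signal_sets(codes: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(N-demand, N-supply) responsive gene sets from assembled RP codes."""
    demand = set(codes.index[codes["r1"] != 0])
    supply = set(codes.index[codes["r6"] != 0])
    return demand, supply


def root_deg_pipeline(
    root: ExpressionMatrix,
    pfp_cutoff: float = 0.10,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank-product coding of every time point of a root matrix.

    Expects a low-expression-filtered matrix; linear input is log2
    transformed. Returns one row per (gene, time point) with the six digits
    ``r1..r6``, the per-time-point ``group_id``, and per-contrast
    ``rp_up_i, rp_down_i, pfp_up_i, pfp_down_i`` columns.
    """
    if root.scale == "linear":
        root = log2_transform(root)
    rng = np.random.default_rng(seed)
    frames = []
    for t in root.time_points():
        sub = root.select(time_h=t)
        blocks = {}
        for cond in set(c for pair in ROOT_CONTRASTS for c in pair):
            block = sub.select(condition=cond).ordered(("replicate",))
            if block.n_samples == 0:
                raise RankProductError(f"time {t} h: condition {cond!r} is missing")
            blocks[cond] = block.values.to_numpy(dtype=float)
        results = {}
        for i, (ca, cb) in enumerate(ROOT_CONTRASTS, start=1):
            results[i] = rank_product_contrast(
                blocks[ca],
                blocks[cb],
                n_perm=n_perm,
                seed=rng,
                gene_ids=root.gene_ids,
                mode="auto",
            )
        codes = rp_code_assemble(results, pfp_cutoff=pfp_cutoff)
        codes.insert(0, "time_h", t)
        codes.insert(0, "gene_id", codes.index)
        for i in range(1, 7):
            for col in ("rp_up", "rp_down", "pfp_up", "pfp_down"):
                codes[f"{col}_{i}"] = results[i][col]
        frames.append(codes.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


def root_deg_set(records: pd.DataFrame) -> set[str]:
    """Genes with a nonzero RP code at any time point."""
    digits = records[[f"r{i}" for i in range(1, 7)]].to_numpy()
    return set(records.loc[(digits != 0).any(axis=1), "gene_id"])


def interdependency_diagnostic(
    root: ExpressionMatrix, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Test whether the two root halves of split plants covary.

    For every gene the Sp.NO3 and Sp.Cl replicate deviations (residuals
    after removing per-condition per-time means) are correlated across the
    paired samples (same plant pool); the statistic is the mean correlation
    over genes. Its permutation p-value re-pairs the Sp.Cl replicates within
    each time point at random: under independent halves the statistic is
    exchangeable under re-pairing. This diagnostic is an artifact of this
    package (the choice of test for half-to-half dependence is ours); a
    small p indicates that a joint model across the four root conditions
    would double-count plants and that pairwise contrasts are preferable.
    """
    if root.scale == "linear":
        root = log2_transform(root)
    resid = {}
    layout = None
    for cond in ("Sp.NO3", "Sp.Cl"):
        sub = root.select(condition=cond).ordered(("time_h", "replicate"))
        meta = sub.samples
        reps = sorted(set(meta["replicate"]))
        if len(reps) < 2:
            raise RankProductError("interdependency diagnostic needs >= 2 replicates")
        x = sub.values.to_numpy(dtype=float)
        times = meta["time_h"].to_numpy()
        r = np.empty_like(x)
        for t in np.unique(times):
            cols = times == t
            r[:, cols] = x[:, cols] - x[:, cols].mean(axis=1, keepdims=True)
        resid[cond] = r
        layout = times if layout is None else layout
    A, B = resid["Sp.NO3"], resid["Sp.Cl"]

    def mean_corr(bmat: np.ndarray) -> float:
        num = (A * bmat).sum(axis=1)
        den = np.sqrt((A**2).sum(axis=1) * (bmat**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / den
        return float(np.nanmean(r))

    stat = mean_corr(B)
    rng = np.random.default_rng(seed)
    hits = 0
    time_blocks = [np.flatnonzero(layout == t) for t in np.unique(layout)]
    for _ in range(n_perm):
        perm_cols = np.arange(B.shape[1])
        for cols in time_blocks:
            perm_cols[cols] = cols[rng.permutation(len(cols))]
        if mean_corr(B[:, perm_cols]) >= stat:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return stat, p
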