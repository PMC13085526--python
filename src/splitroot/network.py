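"""Shoot-root correlated gene-pair identification and network assembly.

Three-step pair analysis per nitrogen condition: (i) Pearson correlation of
every shoot gene against every root gene over the matched time x replicate
series of the same plants (split shoots pair with Sp.NO3 roots for the
N-replete side and with Sp.Cl roots for the N-deplete side), with BH
adjustment over the full pair grid and a stringent FDR cutoff (0.001 by
default, roughly |r| > 0.9 at 12 matched samples); (ii) retention of pairs
whose shoot member is a shoot DEG and whose root member is a root DEG;
(iii) retention of pairs where at least one member is an experimentally
reported shoot-root mobile transcript. Pairs from the four conditions are
compared by 4-set Venn decomposition and assembled into a single network
whose edges carry condition and sign annotations.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, ROOT_CONDITIONS, SHOOT_FOR_ROOT_CONDITION
from .preprocess import log2_transform
from .shoot import benjamini_hochberg

PAIR_COLUMNS = [
    "shoot_gene",
    "root_gene",
    "condition",
    "r",
    "p",
    "fdr",
    "sign",
    "mobility_support",
]


class AlignmentError(ValueError):
    pass


def _aligned_series(
    shoot: ExpressionMatrix, root: ExpressionMatrix, condition: str,
    collapse_replicates: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched (genes x N) log2 arrays for one root condition's plants."""
    shoot_cond = SHOOT_FOR_ROOT_CONDITION[condition]
    s = shoot.select(condition=shoot_cond).ordered(("time_h", "replicate"))
    r = root.select(condition=condition).ordered(("time_h", "replicate"))
    s_key = list(zip(s.samples["time_h"], s.samples["replicate"]))
    r_key = list(zip(r.samples["time_h"], r.samples["replicate"]))
    if s_key != r_key:
        unmatched = sorted(set(s_key) ^ set(r_key))
        raise AlignmentError(
            f"condition {condition}: shoot/root series misaligned at "
            f"(time, replicate) = {unmatched}"
        )
    if len(s_key) < 4:
        raise AlignmentError(
            f"condition {condition}: need >= 4 matched samples, got {len(s_key)}"
        )
    x = s.values.to_numpy(dtype=float)
    y = r.values.to_numpy(dtype=float)
    if collapse_replicates:
        times = s.samples["time_h"].to_numpy()
        uniq = np.unique(times)
        if len(uniq) < 4:
            raise AlignmentError("collapsed series needs >= 4 time points")
        x = np.column_stack([x[:, times == t].mean(axis=1) for t in uniq])
        y = np.column_stack([y[:, times == t].mean(axis=1) for t in uniq])
    return x, y


def correlation_grid(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p for every row of x against every row of y."""
    n = x.shape[1]
    xs = x - x.mean(axis=1, keepdims=True)
    ys = y - y.mean(axis=1, keepdims=True)
    xn = np.sqrt((xs**2).sum(axis=1))
    yn = np.sqrt((ys**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xs @ ys.T) / np.outer(xn, yn)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return r, p


def interorgan_correlation(
    shoot: ExpressionMatrix,
    root: ExpressionMatrix,
    fdr_cutoff: float = 0.001,
    conditions=ROOT_CONDITIONS,
    collapse_replicates: bool = False,
) -> pd.DataFrame:
    """Significantly correlated shoot-root gene pairs per condition.

    Both matrices should already be filtered (low expression and dynamic
    range); linear-scale input is log2 transformed. BH adjustment is applied
    across the full shoot x root pair grid separately per condition. Returns
    the retained pairs (``fdr <= fdr_cutoff``) as a DataFrame with columns
    ``shoot_gene, root_gene, condition, r, p, fdr, sign, mobility_support``
    (mobility unset until :func:`filter_pairs_by_mobility`).
    """
    if shoot.scale == "linear":
        shoot = log2_transform(shoot)
    if root.scale == "linear":
        root = log2_transform(root)
    frames = []
    for cond in conditions:
        x, y = _aligned_series(shoot, root, cond, collapse_replicates)
        r, p = correlation_grid(x, y)
        fdr = benjamini_hochberg(p.ravel()).reshape(p.shape)
        keep = fdr <= fdr_cutoff
        si, ri = np.nonzero(keep)
        frames.append(
            pd.DataFrame(
                {
                    "shoot_gene": np.array(shoot.gene_ids)[si],
                    "root_gene": np.array(root.gene_ids)[ri],
                    "condition": cond,
                    "r": r[keep],
                    "p": p[keep],
                    "fdr": fdr[keep],
                    "sign": np.where(r[keep] >= 0, "positive", "negative"),
                    "mobility_support": "unknown",
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=PAIR_COLUMNS
    )
    return out[PAIR_COLUMNS]


def filter_pairs_by_deg(
    pairs: pd.DataFrame, shoot_deg_set: set[str], root_deg_set: set[str]
) -> pd.DataFrame:
    """Keep pairs whose shoot member is a shoot DEG and root member a root DEG."""
    keep = pairs["shoot_gene"].isin(shoot_deg_set) & pairs["root_gene"].isin(
        root_deg_set
    )
    return pairs[keep].reset_index(drop=True)


def filter_pairs_by_mobility(pairs: pd.DataFrame, mobile_set: set[str]) -> pd.DataFrame:
    """Keep pairs with at least one reported shoot-root mobile transcript."""
    s = pairs["shoot_gene"].isin(mobile_set)
    r = pairs["root_gene"].isin(mobile_set)
    out = pairs[s | r].copy()
    sm, rm = s[out.index], r[out.index]
    out["mobility_support"] = np.select(
        [sm & rm, sm, rm], ["both", "shoot_mobile", "root_mobile"], default="none"
    )
    return out.reset_index(drop=True)


def condition_venn(
    pairs: pd.DataFrame, split_by_sign: bool = False
) -> dict[str, dict[str, int]]:
    """Counts of all 15 nonempty regions of the 4-condition Venn diagram.

    Pair identity is the condition-free (shoot_gene, root_gene) key. Region
    keys name the exact membership, e.g. ``"C.NO3&Sp.Cl"`` counts pairs
    found under exactly those two conditions. With ``split_by_sign`` the
    decomposition is computed separately for positively and negatively
    correlated pairs (a pair whose sign differs between conditions appears
    in both decompositions under the respective conditions).
    """

    def venn_of(sub: pd.DataFrame) -> dict[str, int]:
        membership: dict[tuple[str, str], set[str]] = {}
        for row in sub.itertuples():
            membership.setdefault((row.shoot_gene, row.root_gene), set()).add(
                row.condition
            )
        counts = {}
        for k in range(1, 5):
            for combo in itertools.combinations(ROOT_CONDITIONS, k):
                counts["&".join(combo)] = 0
        for conds in membership.values():
            key = "&".join(c for c in ROOT_CONDITIONS if c in conds)
            counts[key] += 1
        return counts

    if not split_by_sign:
        return {"all": venn_of(pairs)}
    return {
        sign: venn_of(pairs[pairs["sign"] == sign])
        for sign in ("positive", "negative")
    }


def build_network(pairs: pd.DataFrame) -> nx.Graph:
    """Assemble the integrated inter-organ network from annotated pairs.

    Nodes are (gene, organ) occurrences named ``shoot:GENE`` / ``root:GENE``
    (a gene expressed in both organs contributes two nodes, so self-pairing
    across organs is representable while same-node self-edges cannot occur).
    One edge joins each (shoot_gene, root_gene) pair and carries the sorted
    set of conditions it was found under plus the per-condition signs.
    """
    g = nx.Graph()
    for row in pairs.itertuples():
        u, v = f"shoot:{row.shoot_gene}", f"root:{row.root_gene}"
        g.add_node(u, gene=row.shoot_gene, organ="shoot")
        g.add_node(v, gene=row.root_gene, organ="root")
        if g.has_edge(u, v):
            data = g.edges[u, v]
            conds = set(data["conditions"].split(",")) | {row.condition}
            data["conditions"] = ",".join(sorted(conds))
            signs = dict(
                item.split(":") for item in data["signs"].split(",") if item
            )
            signs[row.condition] = row.sign
            data["signs"] = ",".join(f"{c}:{s}" for c, s in sorted(signs.items()))
        else:
            g.add_edge(
                u,
                v,
                conditions=row.condition,
                signs=f"{row.condition}:{row.sign}",
            )
    return g


def export_sif(g: nx.Graph, path) -> None:
    """SIF export: ``source <interaction> target`` per edge."""
    lines = [
        f"{u}\tinterorgan_correlation\t{v}" for u, v in sorted(g.edges())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def export_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_venn(venn: dict, path) -> None:
    Path(path).write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
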