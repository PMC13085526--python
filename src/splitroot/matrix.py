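"""Expression-matrix container for split-root shoot/root transcriptomes.

The experimental design has shoots sampled under three nitrogen conditions
(homogeneous nitrate C.NO3, heterogeneous Split, homogeneous depletion C.Cl)
and roots under four (C.NO3, Sp.NO3, Sp.Cl, C.Cl — the Sp.* conditions are
the two halves of one split-root plant and share a shoot). Samples carry the
metadata needed downstream: organ, condition, time, replicate, and the
plant-pool identifier that links the two root halves of one plant to its
shoot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SHOOT_CONDITIONS = ("C.NO3", "Split", "C.Cl")
ROOT_CONDITIONS = ("C.NO3", "Sp.NO3", "Sp.Cl", "C.Cl")
ORGANS = ("shoot", "root")

#: shoot condition matched to each root condition when pairing organs of the
#: same plants (split shoots serve both root halves)
SHOOT_FOR_ROOT_CONDITION = {
    "C.NO3": "C.NO3",
    "Sp.NO3": "Split",
    "Sp.Cl": "Split",
    "C.Cl": "C.Cl",
}

SAMPLE_COLUMNS = [
    "sample_id",
    "organ",
    "condition",
    "time_h",
    "replicate",
    "plant_pool_id",
    "genotype",
    "species",
]


class MatrixError(ValueError):
    """Raised for malformed expression matrices or metadata."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id, non-negative.
    samples
        DataFrame indexed by sample id with columns ``organ``, ``condition``,
        ``time_h``, ``replicate``, ``plant_pool_id``, ``genotype``,
        ``species``; row order matches the column order of ``values``.
    scale
        ``"linear"`` or ``"log2"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise MatrixError(f"unknown scale {self.scale!r}")
        if list(self.values.columns) != list(self.samples.index):
            raise MatrixError("sample metadata does not match value columns")
        if self.values.index.has_duplicates:
            raise MatrixError("duplicate gene ids")
        vals = self.values.to_numpy()
        if np.isnan(vals).any():
            raise MatrixError("missing values are not allowed")
        if (vals < 0).any():
            raise MatrixError("negative expression values")
        for sid, row in self.samples.iterrows():
            organ, cond = row["organ"], row["condition"]
            if organ not in ORGANS:
                raise MatrixError(
                    f"sample {sid}: unknown organ {organ!r}; allowed: {ORGANS}"
                )
            allowed = SHOOT_CONDITIONS if organ == "shoot" else ROOT_CONDITIONS
            if cond not in allowed:
                raise MatrixError(
                    f"sample {sid}: condition {cond!r} invalid for organ "
                    f"{organ!r}; allowed: {allowed}"
                )

    # -- basic views ---------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def organ(self) -> str:
        organs = set(self.samples["organ"])
        if len(organs) != 1:
            raise MatrixError("matrix mixes organs")
        return organs.pop()

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(gene_ids)])

    def subset_samples(self, mask) -> "ExpressionMatrix":
        sub = self.samples[mask]
        return replace(
            self, values=self.values[sub.index], samples=sub
        )

    def select(self, condition=None, time_h=None) -> "ExpressionMatrix":
        """Subset samples by condition and/or time point."""
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if time_h is not None:
            mask &= self.samples["time_h"] == time_h
        return self.subset_samples(mask)

    def ordered(self, by=("condition", "time_h", "replicate")) -> "ExpressionMatrix":
        """Return a copy with samples sorted by the given metadata keys."""
        sub = self.samples.sort_values(list(by), kind="mergesort")
        return replace(self, values=self.values[sub.index], samples=sub)

    def conditions(self) -> list[str]:
        order = SHOOT_CONDITIONS if self.organ == "shoot" else ROOT_CONDITIONS
        present = set(self.samples["condition"])
        return [c for c in order if c in present]

    def time_points(self) -> list[float]:
        return sorted(set(self.samples["time_h"]))


def make_sample_table(records: list[dict]) -> pd.DataFrame:
    """Build a sample-metadata table from dicts (one per sample)."""
    df = pd.DataFrame.from_records(records, columns=SAMPLE_COLUMNS)
    return df.set_index("sample_id", drop=False).rename_axis(None)
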