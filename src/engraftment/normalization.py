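"""Depth-scaled log10 normalization of amplicon count tables.

Raw read counts are not comparable across samples because sequencing depth
varies. Each count ``c`` in a sample of total depth ``T`` is transformed to

    log10(c / T * Dbar + 1)

where ``Dbar`` is the arithmetic mean depth over a stated set of samples
(by default, all samples entering the current analysis). Rescaling every
sample to the common depth ``Dbar`` before adding the pseudo-count gives the
+1 a comparable effect across samples of different depth; a zero count maps
to exactly 0 and values are non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import CountTable

__all__ = ["NormalizedTable", "normalize_counts", "relative_abundance"]


@dataclass(frozen=True)
class NormalizedTable:
    """Log10 depth-scaled abundances, same shape as the source count table.

    ``mean_depth`` records the Dbar used, making every run auditable.
    """

    values: pd.DataFrame
    mean_depth: float

    @property
    def asv_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def column(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", float_format="%.6f")


def normalize_counts(
    table: CountTable, depth_scope: list[str] | None = None
) -> NormalizedTable:
    """Apply the depth-scaled log10 pseudo-count normalization.

    Parameters
    ----------
    table:
        Validated count table (all depths >= 1).
    depth_scope:
        Sample ids whose depths define the mean depth Dbar. Default: all
        samples in ``table``. Dbar is recomputed for each analysis subset, so
        pass an explicit scope to freeze it across subsets.
    """
    depths = table.depths()
    if depth_scope is None:
        scope_depths = depths
    else:
        missing = [s for s in depth_scope if s not in depths.index]
        if missing:
            raise KeyError(f"depth_scope samples not in table: {missing}")
        scope_depths = depths.loc[list(depth_scope)]
    mean_depth = float(scope_depths.mean())
    values = np.log10(
        table.counts.to_numpy(dtype=float) / depths.to_numpy(dtype=float) * mean_depth
        + 1.0
    )
    df = pd.DataFrame(values, index=table.counts.index, columns=table.counts.columns)
    return NormalizedTable(values=df, mean_depth=mean_depth)


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1."""
    counts = table.counts.to_numpy(dtype=float)
    props = counts / counts.sum(axis=0, keepdims=True)
    return pd.DataFrame(props, index=table.counts.index, columns=table.counts.columns)
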