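"""Quantile normalisation across datasets and per-species mean structure.

All datasets — both species, all assays — are forced onto one common
distribution (the mean of the per-rank order statistics across columns), so
that values are comparable across experimental platforms.  Ranks within each
column are preserved; tied entries share the mean of the reference values
their rank span covers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binning import StructureMatrix
from .layout import InvalidParameterError


def quantile_normalise(matrix: StructureMatrix) -> StructureMatrix:
    """Map every column onto the cross-column mean-of-order-statistics.

    The reference distribution is the row-wise mean of each column's sorted
    values.  Each entry is replaced by the reference value at its rank; a
    group of tied entries receives the mean of the reference values across
    the ranks the group spans (the common microarray dialect).
    """
    values = matrix.values
    if values.isna().any().any():
        raise InvalidParameterError("matrix has missing cells; normalisation is complete-case")
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise InvalidParameterError("need at least 2 regions and 2 datasets")
    arr = values.to_numpy(dtype=float)
    n, k = arr.shape
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(k):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        ranked = reference.copy()
        # ties: average the reference values over each tied span
        start = 0
        while start < n:
            stop = start + 1
            while stop < n and sorted_col[stop] == sorted_col[start]:
                stop += 1
            if stop - start > 1:
                ranked[start:stop] = reference[start:stop].mean()
            start = stop
        out[order, j] = ranked
    norm_values = pd.DataFrame(out, index=values.index, columns=values.columns)
    return StructureMatrix(
        regions=matrix.regions,
        values=norm_values,
        datasets=matrix.datasets,
        stage="normalised",
        reference=reference,
    )


def mean_structure(matrix: StructureMatrix, species: str) -> pd.Series:
    """Arithmetic mean of a species' normalised values per region."""
    cols = matrix.species_columns(species)
    return matrix.values[cols].mean(axis=1)
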