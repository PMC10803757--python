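"""Reference-based blood cell-type deconvolution by constrained projection.

Each sample's beta profile over the reference probes is modelled as a
nonnegative mixture of cell-type methylation signatures whose fractions sum
to one (the canonical constrained-projection formulation):

    min_f || S^T f - b ||^2   s.t.  f >= 0,  sum(f) = 1

solved by nonnegative least squares with the sum-to-one constraint encoded
as a heavily weighted auxiliary equation, then an exact simplex
renormalization.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUM_CONSTRAINT_WEIGHT = 1e4


@dataclasses.dataclass
class CellReference:
    """Cell-type x probe matrix of mean beta signatures, values in [0, 1]."""

    signature: pd.DataFrame  # index: cell types, columns: probe ids

    def __post_init__(self) -> None:
        if self.signature.shape[0] < 2:
            raise ValueError("a cell reference needs >= 2 cell types")
        vals = self.signature.to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("signature values must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.signature.index)

    @property
    def probe_ids(self) -> pd.Index:
        return self.signature.columns


def estimate_composition(beta: pd.DataFrame, reference: CellReference) -> pd.DataFrame:
    """Estimate per-sample cell fractions.

    Returns a DataFrame indexed by sample id with one column per cell type
    plus ``residual_norm``, the Euclidean norm of the unconstrained fit
    residual on the shared probes.  Fractions are nonnegative and sum to one
    (within 1e-6 before, exactly after, renormalization).
    """
    shared = reference.probe_ids.intersection(beta.index)
    k = len(reference.cell_types)
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} probes shared between beta and reference; "
            f"need at least {k} (one per cell type)"
        )
    S = reference.signature[shared].to_numpy(dtype=float)  # k x p
    if np.linalg.matrix_rank(S) < k:
        raise ValueError("reference signature is rank-deficient on the shared probes")

    A = S.T  # p x k design
    weight = SUM_CONSTRAINT_WEIGHT * np.abs(S).max()
    A_aug = np.vstack([A, weight * np.ones((1, k))])

    rows = []
    for sample in beta.columns:
        b = beta.loc[shared, sample].to_numpy(dtype=float)
        b_aug = np.concatenate([b, [weight]])
        f, _ = nnls(A_aug, b_aug)
        total = f.sum()
        if total <= 0:
            raise ValueError(f"degenerate deconvolution for sample {sample!r}")
        f = f / total
        residual = float(np.linalg.norm(A @ f - b))
        rows.append([*f, residual])

    return pd.DataFrame(
        rows, index=beta.columns, columns=[*reference.cell_types, "residual_norm"]
    )


def read_reference_csv(path) -> CellReference:
    """Reference CSV: first column ``cell_type``, remaining columns probe ids."""
    table = pd.read_csv(path)
    if table.columns[0] != "cell_type":
        raise ValueError("reference CSV must start with a cell_type column")
    return CellReference(signature=table.set_index("cell_type"))


def write_reference_csv(reference: CellReference, path) -> None:
    reference.signature.rename_axis("cell_type").reset_index().to_csv(path, index=False)
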