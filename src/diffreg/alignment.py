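"""Change-of-basis alignment between diffusion embeddings.

Embeddings of the same scene computed from different modalities live in
different Euclidean spaces (eigenvectors can flip sign, permute, or mix
when spectra are close). When both embeddings are defined over the SAME
sample index set (same coarse pixel grid), the operator of inner
products between their eigenbases maps one embedding into the other's
space, after which plain Euclidean distances are comparable across
modalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .spectral import DiffusionEmbedding


@dataclass(frozen=True)
class BasisChangeOperator:
    """O[k, j] = <psi_k^ref, psi_j^src> over the common index set.

    Columns of both eigenvector sets are unit-normalized before taking
    inner products, so every entry lies in [-1, 1]. Maps source
    coordinate vectors c into the reference space as O @ c.
    """

    O: np.ndarray  # (l_ref, l_src)
    source_id: Optional[str] = None
    target_id: Optional[str] = None


def _unit_columns(psi: np.ndarray) -> np.ndarray:
    psi = np.asarray(psi, dtype=float)
    if psi.ndim != 2:
        raise ValueError("eigenvector set must be a 2-D (n, l) array")
    norms = np.linalg.norm(psi, axis=0)
    if np.any(norms <= 0):
        raise ValueError("eigenvector set contains a zero column")
    return psi / norms[None, :]


def build_operator(
    ref_psi: np.ndarray,
    src_psi: np.ndarray,
    source_id: Optional[str] = None,
    target_id: Optional[str] = None,
) -> BasisChangeOperator:
    """Inner-product matrix between reference and source eigenvectors.

    Both sets must be sampled on the same index set (same length n);
    embeddings over different grids are not pointwise comparable.
    """
    ref = _unit_columns(ref_psi)
    src = _unit_columns(src_psi)
    if ref.shape[0] != src.shape[0]:
        raise ValueError(
            f"eigenvector sets live on different index sets "
            f"(n={ref.shape[0]} vs n={src.shape[0]})"
        )
    return BasisChangeOperator(
        O=ref.T @ src, source_id=source_id, target_id=target_id
    )


def apply_operator(
    op: BasisChangeOperator,
    emb: Union[DiffusionEmbedding, np.ndarray],
) -> Union[DiffusionEmbedding, np.ndarray]:
    """Map embedding coordinates into the operator's reference space.

    Accepts a DiffusionEmbedding or a plain (..., l_src) coordinate
    array (e.g. an H x W x l diffusion-map image); returns the same kind
    with the last axis mapped to l_ref.
    """
    if isinstance(emb, DiffusionEmbedding):
        coords = apply_operator(op, emb.coords)
        l_ref = coords.shape[1]
        return DiffusionEmbedding(
            coords=coords,
            lam_tilde=np.full(l_ref, np.nan),
            eigenvalues=np.full(l_ref, np.nan),
            source_n=emb.source_n,
        )
    coords = np.asarray(emb, dtype=float)
    if coords.shape[-1] != op.O.shape[1]:
        raise ValueError(
            f"coordinate dimension {coords.shape[-1]} does not match the "
            f"operator's source dimension {op.O.shape[1]}"
        )
    return coords @ op.O.T
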