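"""Multi-block PLS-DA: Frobenius block scaling, super-matrix fit, per-LV
block weights, and correlation loadings.

Each block is divided by its Frobenius norm (the square root of the sum of
squared entries, computed on the training rows, uncentred) so that blocks
with large numeric values — e.g. absorbances versus scattering counts —
cannot dominate the fusion.  The scaled blocks are concatenated into one
super-matrix and fitted with ordinary PLS1; the super-weight of each latent
variable is then sliced by block to measure block importance:

    block_weight[b, a] = ||w_a restricted to block b||^2 / ||w_a||^2

which sums to 1 over blocks for every LV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import BlockSet
from .pls import PLSModel, fit_pls

__all__ = ["MBPLSModel", "frobenius_scale", "fit_mbpls", "correlation_loadings"]


def frobenius_scale(blocks: BlockSet, norms: dict[str, float] | None = None):
    """Divide each block by its Frobenius norm.

    With ``norms`` given (training norms), applies those divisors instead of
    recomputing — how held-out rows must be scaled inside cross-validation.

    Returns ``(scaled BlockSet, {modality: norm})``.
    """
    used: dict[str, float] = {}
    scaled = []
    for b in blocks.blocks:
        nrm = norms[b.modality] if norms is not None else float(
            np.linalg.norm(b.intensities)
        )
        if not np.isfinite(nrm) or nrm == 0.0:
            raise ValueError(f"zero or non-finite Frobenius norm for block {b.modality!r}")
        used[b.modality] = nrm
        scaled.append(b.with_data(intensities=b.intensities / nrm,
                                  note=f"frobenius_scale(norm={nrm:.6g})"))
    return BlockSet(scaled), used


@dataclass
class MBPLSModel:
    """PLS1 on the Frobenius-scaled super-matrix plus block bookkeeping."""

    inner: PLSModel
    block_norms: dict[str, float]
    boundaries: dict[str, slice]
    modalities: list[str]
    axes: dict[str, np.ndarray]

    @property
    def n_lv(self) -> int:
        return self.inner.n_lv

    @property
    def block_weights(self) -> np.ndarray:
        """(blocks x A) matrix of per-LV squared-norm shares; columns sum to 1."""
        W = self.inner.W
        out = np.zeros((len(self.modalities), W.shape[1]))
        for i, m in enumerate(self.modalities):
            out[i] = (W[self.boundaries[m]] ** 2).sum(axis=0)
        return out / (W**2).sum(axis=0)

    def predict(self, blocks: BlockSet, a: int | None = None) -> np.ndarray:
        """Continuous scores for new rows; applies the training block norms."""
        scaled, _ = frobenius_scale(blocks.subset(self.modalities), self.block_norms)
        return self.inner.predict(scaled.concatenate(), a=a)

    def block_coefficients(self, a: int | None = None) -> dict[str, np.ndarray]:
        """Per-block coefficients applicable to preprocessed-but-unscaled
        spectra: slice the super-coefficients and undo the block norm."""
        b = self.inner.coefficients(a)
        return {m: b[self.boundaries[m]] / self.block_norms[m] for m in self.modalities}


def fit_mbpls(blocks: BlockSet, y: np.ndarray, A: int) -> MBPLSModel:
    """Scale -> concatenate -> fit PLS1; record norms and block boundaries."""
    scaled, norms = frobenius_scale(blocks)
    inner = fit_pls(scaled.concatenate(), y, A, row_keys=blocks.row_keys)
    return MBPLSModel(
        inner=inner,
        block_norms=norms,
        boundaries=blocks.boundaries,
        modalities=blocks.modalities,
        axes={b.modality: b.axis for b in blocks.blocks},
    )


def correlation_loadings(
    model: MBPLSModel,
    variables: np.ndarray,
    lv_pair: tuple[int, int] = (1, 2),
) -> np.ndarray:
    """Pearson correlation of each variable with the global scores of two LVs.

    ``variables`` is (training rows x k): spectral channels or supplementary
    design dummies, row-aligned with the training rows.  Returns (k x 2)
    correlations; a zero-variance variable yields NaN (undefined, reported as
    missing, never as zero).  The reference circles at r = 0.5 and r = 1.0
    are plotting metadata attached downstream.
    """
    a1, a2 = lv_pair
    for a in (a1, a2):
        if not 1 <= a <= model.n_lv:
            raise ValueError(f"LV {a} not available (model has {model.n_lv})")
    V = np.atleast_2d(np.asarray(variables, float))
    if V.shape[0] != model.inner.T.shape[0]:
        raise ValueError("variables must be row-aligned with the training rows")
    out = np.full((V.shape[1], 2), np.nan)
    for j, a in enumerate((a1, a2)):
        t = model.inner.T[:, a - 1]
        tc = t - t.mean()
        tn = np.linalg.norm(tc)
        Vc = V - V.mean(axis=0)
        vn = np.linalg.norm(Vc, axis=0)
        ok = (vn > 0) & (tn > 0)
        out[ok, j] = (Vc[:, ok].T @ tc) / (vn[ok] * tn)
    return out
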