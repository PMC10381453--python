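"""Model interpretation: unscaled regression coefficients, discriminative
band selection, and the correlation-loading table.

The coefficients of the fused model, mapped back to each modality's own
scale, identify the spectral bands driving the damaged-versus-healthy
discrimination.  The strongest bands (local extrema of |b|) plus one 0/1
dummy per damage subgroup are correlated with the global scores of two
latent variables; plotted against reference circles at r = 0.5 and r = 1.0
this is the classic correlation-loading view of a multi-block model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import BlockSet, StudyDesign
from .multiblock import MBPLSModel, correlation_loadings

__all__ = [
    "PeakSelection",
    "unscaled_block_coefficients",
    "select_peaks",
    "correlation_plot_table",
]

INNER_RADIUS = 0.5
OUTER_RADIUS = 1.0


@dataclass
class PeakSelection:
    """Selected bands per modality: (wavenumber, coefficient, rank).

    Entries are local extrema of |b| on that modality's axis, sorted by
    descending |coefficient| (rank 1 = strongest).
    """

    peaks: dict[str, list[tuple[float, float, int]]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"modality": m, "wavenumber": wn, "coefficient": c, "rank": r}
            for m, lst in self.peaks.items()
            for wn, c, r in lst
        ]
        return pd.DataFrame(rows, columns=["modality", "wavenumber", "coefficient", "rank"])


def unscaled_block_coefficients(model: MBPLSModel, a: int | None = None) -> dict[str, np.ndarray]:
    """Per-block coefficient vectors applicable to preprocessed-but-unscaled
    spectra (the super-coefficients sliced by block, divided by each block's
    Frobenius norm).  Their concatenation predicts identically to the model."""
    return model.block_coefficients(a)


def _local_extrema(absb: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of |b|; plateaus keep their leftmost
    channel; the array ends count as extrema if they dominate the interior
    neighbour."""
    n = absb.size
    if n == 1:
        return np.array([0])
    idx = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and absb[j + 1] == absb[i]:
            j += 1  # plateau [i..j]
        left_ok = i == 0 or absb[i - 1] < absb[i]
        right_ok = j == n - 1 or absb[j + 1] < absb[i]
        whole_array = i == 0 and j == n - 1  # constant vector: no extremum
        if left_ok and right_ok and not whole_array:
            idx.append(i)
        i = j + 1
    return np.asarray(idx, int)


def select_peaks(
    coeffs: dict[str, np.ndarray],
    axes: dict[str, np.ndarray],
    k_per_block: int = 12,
    min_separation: float = 10.0,
) -> PeakSelection:
    """Top-k local extrema of |b| per modality, ranked by |coefficient|.

    ``min_separation`` (cm^-1) greedily suppresses weaker extrema closer
    than that to an already-selected one, so that on finely sampled axes a
    single strong band cannot fill the whole list with its noise wiggles;
    set it to 0 to rank raw extrema.  If a modality has fewer than k
    (separated) extrema, all of them are returned (no padding).
    """
    if k_per_block < 1:
        raise ValueError("k_per_block must be >= 1")
    out: dict[str, list[tuple[float, float, int]]] = {}
    for m, b in coeffs.items():
        absb = np.abs(np.asarray(b, float))
        ext = _local_extrema(absb)
        order = ext[np.argsort(-absb[ext], kind="stable")]
        chosen: list[int] = []
        for i in order:
            if len(chosen) == k_per_block:
                break
            if all(abs(axes[m][i] - axes[m][j]) >= min_separation for j in chosen):
                chosen.append(i)
        out[m] = [
            (float(axes[m][i]), float(b[i]), rank + 1) for rank, i in enumerate(chosen)
        ]
    return PeakSelection(out)


def correlation_plot_table(
    model: MBPLSModel,
    blocks: BlockSet,
    design: StudyDesign,
    selection: PeakSelection,
    lv_pair: tuple[int, int] = (1, 2),
    subgroups: list[str] | None = None,
) -> pd.DataFrame:
    """Correlation loadings of the selected bands and the subgroup dummies.

    Each selected spectral channel, plus one 0/1 dummy column per damage
    subgroup (supplementary variables, never refit into the model), is
    correlated with the global scores of ``lv_pair``.  Columns: variable
    label, modality, wavenumber (NaN for dummies), r1, r2, |b| rank, the
    reference radii, and ``inside_inner`` flagging points with
    r1^2 + r2^2 < 0.25 — variation not well explained by these two LVs.
    Zero-variance variables get missing correlations and the same flag left
    unset (NaN propagates).
    """
    if model.n_lv < 2:
        raise ValueError("correlation-loading plot needs a model with >= 2 LVs")
    if [k[0] for k in blocks.row_keys] != design.sample_ids:
        raise ValueError("blocks are not aligned with the design table")

    cols: list[np.ndarray] = []
    meta: list[dict] = []
    for m, lst in selection.peaks.items():
        block = blocks.subset([m]).blocks[0]
        for wn, coef, rank in lst:
            ch = int(np.argmin(np.abs(block.axis - wn)))
            cols.append(block.intensities[:, ch])
            meta.append(
                {"variable": f"{m} {wn:g}", "modality": m, "wavenumber": wn,
                 "rank": rank}
            )
    if subgroups is None:
        subgroups = sorted(g for g in pd.unique(design.subgroups) if g != "CTRL")
    for g in subgroups:
        cols.append((design.subgroups == g).astype(float))
        meta.append({"variable": g, "modality": "design", "wavenumber": np.nan,
                     "rank": np.nan})

    R = correlation_loadings(model, np.column_stack(cols), lv_pair)
    df = pd.DataFrame(meta)
    df["r1"], df["r2"] = R[:, 0], R[:, 1]
    rad2 = df["r1"] ** 2 + df["r2"] ** 2
    df["inside_inner"] = pd.array(rad2 < INNER_RADIUS**2, dtype="boolean")
    df.loc[rad2.isna(), "inside_inner"] = pd.NA
    df["missing"] = rad2.isna()
    df.attrs["circle_radii"] = (INNER_RADIUS, OUTER_RADIUS)
    df.attrs["lv_pair"] = lv_pair
    return df
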