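"""Per-spectrum preprocessing: clipping, Savitzky-Golay smoothing and
derivatives, standard normal variate (SNV), and wavenumber trimming.

Every operation acts row-by-row (no cross-spectrum coupling), so the row
ordering and any row subset commute with preprocessing.  The default stage
order is clip -> Savitzky-Golay -> SNV -> trim: the derivative filter wants
the wide untrimmed axis so its edge handling never touches the analysis
window, and SNV normalises whatever scale the derivative left behind.

Reference parameterisations for the three cartilage modalities (derivative
order / filter window / polynomial order / trim window in cm^-1):

    MIR    2 / 201 / 3 / 900-1800
    NIR    0 /   5 / 3 / 4545-8333
    Raman  1 / 205 / 3 / 800-1800
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.signal import savgol_filter

from .blocks import SpectralBlock

__all__ = [
    "PreprocessSpec",
    "REFERENCE_SPECS",
    "savitzky_golay",
    "snv",
    "trim",
    "clip",
    "preprocess_block",
    "average_replicates",
]


@dataclass
class PreprocessSpec:
    """Parameters of one modality's preprocessing chain.

    ``stage_order`` lists the stages actually applied, in order; supported
    names are ``clip``, ``savgol``, ``snv``, ``trim``.
    """

    deriv_order: int = 0
    sg_window: int = 5
    sg_polyorder: int = 3
    apply_snv: bool = True
    trim_lo: float | None = None
    trim_hi: float | None = None
    clip_regions: list[tuple[float, float]] = field(default_factory=list)
    stage_order: tuple[str, ...] = ("clip", "savgol", "snv", "trim")

    def validate(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError(f"sg_window must be odd, got {self.sg_window}")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")
        if self.deriv_order not in (0, 1, 2):
            raise ValueError("deriv_order must be 0, 1 or 2")
        if self.deriv_order > self.sg_polyorder:
            raise ValueError("deriv_order must be <= sg_polyorder")
        if self.trim_lo is not None and self.trim_hi is not None:
            if min(self.trim_lo, self.trim_hi) == max(self.trim_lo, self.trim_hi):
                raise ValueError("empty trim window")
        unknown = set(self.stage_order) - {"clip", "savgol", "snv", "trim"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "deriv_order": self.deriv_order,
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "apply_snv": self.apply_snv,
            "trim_lo": self.trim_lo,
            "trim_hi": self.trim_hi,
            "clip_regions": [list(r) for r in self.clip_regions],
            "stage_order": list(self.stage_order),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        d = dict(d)
        if "clip_regions" in d:
            d["clip_regions"] = [tuple(r) for r in d["clip_regions"]]
        if "stage_order" in d:
            d["stage_order"] = tuple(d["stage_order"])
        return cls(**d)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def read(cls, path) -> "PreprocessSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: The published per-modality chains (window sizes in channels, trims in cm^-1).
REFERENCE_SPECS: dict[str, PreprocessSpec] = {
    "MIR": PreprocessSpec(deriv_order=2, sg_window=201, sg_polyorder=3,
                          apply_snv=True, trim_lo=900.0, trim_hi=1800.0),
    "NIR": PreprocessSpec(deriv_order=0, sg_window=5, sg_polyorder=3,
                          apply_snv=True, trim_lo=8333.0, trim_hi=4545.0),
    "Raman": PreprocessSpec(deriv_order=1, sg_window=205, sg_polyorder=3,
                            apply_snv=True, trim_lo=800.0, trim_hi=1800.0),
}


def savitzky_golay(block: SpectralBlock, spec: PreprocessSpec) -> SpectralBlock:
    """Savitzky-Golay smoothing / differentiation of every row.

    The derivative is taken with respect to the channel index (not cm^-1);
    any constant axis-spacing rescale is absorbed by a subsequent SNV.  Edges
    are handled by polynomial fits within truncated windows, so the output
    length equals the input length.
    """
    spec.validate()
    if block.n_channels < spec.sg_window:
        raise ValueError(
            f"{block.modality}: SG window {spec.sg_window} exceeds "
            f"{block.n_channels} channels"
        )
    out = savgol_filter(
        block.intensities,
        window_length=spec.sg_window,
        polyorder=spec.sg_polyorder,
        deriv=spec.deriv_order,
        delta=1.0,
        axis=1,
        mode="interp",
    )
    note = f"savgol(deriv={spec.deriv_order}, window={spec.sg_window}, poly={spec.sg_polyorder})"
    return block.with_data(intensities=out, note=note)


def snv(block: SpectralBlock) -> SpectralBlock:
    """Standard normal variate: centre each row to mean 0 and scale to unit
    sample standard deviation (denominator n-1)."""
    X = block.intensities
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 channels per row")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        bad = [block.row_keys[i] for i in flat[:5]]
        raise ValueError(f"{block.modality}: constant row(s), cannot SNV: {bad}")
    return block.with_data(intensities=(X - mu) / sd, note="snv")


def trim(block: SpectralBlock, lo: float, hi: float) -> SpectralBlock:
    """Keep exactly the channels with lo <= wavenumber <= hi (closed
    interval); descending printed bounds are normalised."""
    lo, hi = (lo, hi) if lo <= hi else (hi, lo)
    mask = (block.axis >= lo) & (block.axis <= hi)
    if not mask.any():
        raise ValueError(
            f"{block.modality}: trim [{lo}, {hi}] leaves no channels "
            f"(axis spans [{block.axis[0]}, {block.axis[-1]}])"
        )
    return block.with_data(
        intensities=block.intensities[:, mask],
        axis=block.axis[mask],
        note=f"trim({lo}, {hi})",
    )


def clip(block: SpectralBlock, regions: list[tuple[float, float]]) -> SpectralBlock:
    """Delete the channels inside each (lo, hi) region (closed intervals)."""
    if not regions:
        return block
    drop = np.zeros(block.n_channels, bool)
    for lo, hi in regions:
        lo, hi = (lo, hi) if lo <= hi else (hi, lo)
        drop |= (block.axis >= lo) & (block.axis <= hi)
    if drop.all():
        raise ValueError(f"{block.modality}: clipping removed every channel")
    keep = ~drop
    return block.with_data(
        intensities=block.intensities[:, keep],
        axis=block.axis[keep],
        note=f"clip({regions})",
    )


def preprocess_block(block: SpectralBlock, spec: PreprocessSpec) -> SpectralBlock:
    """Run the full chain in ``spec.stage_order``, recording provenance."""
    spec.validate()
    out = block
    for stage in spec.stage_order:
        if stage == "clip":
            out = clip(out, spec.clip_regions)
        elif stage == "savgol":
            out = savitzky_golay(out, spec)
        elif stage == "snv":
            if spec.apply_snv:
                out = snv(out)
        elif stage == "trim":
            if spec.trim_lo is not None and spec.trim_hi is not None:
                out = trim(out, spec.trim_lo, spec.trim_hi)
    if not np.all(np.isfinite(out.intensities)):
        raise ValueError(f"{block.modality}: non-finite values after preprocessing")
    return out


def average_replicates(block: SpectralBlock) -> SpectralBlock:
    """Average the replicate spectra of each sample into one row.

    Replicates are preprocessed individually first; the model rows must be
    samples for leave-one-joint-out cross-validation to be well defined.
    Sample order follows first appearance; averaged rows carry replicate 0.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, (sid, _rep) in enumerate(block.row_keys):
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(i)
    mat = np.vstack([block.intensities[groups[s]].mean(axis=0) for s in order])
    return block.with_data(
        intensities=mat,
        row_keys=[(s, 0) for s in order],
        note="average_replicates",
    )
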