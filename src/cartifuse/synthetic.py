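"""Synthetic multi-modal spectral studies with known ground truth.

Emulates the structure of a paired damage/control cartilage study measured
with three vibrational modalities (MIR, NIR, Raman): ten knee joints, six
damaged and six adjacent control cylindrical specimens per joint, damaged
specimens split over five treatment subgroups (impact M1, abrasion M2,
collagenase-24h E1, collagenase-90min E2, trypsin E3), three replicate
spectra per sample, and one sample droppable from all blocks.

The per-replicate generative model is a sum of Gaussian bands on a linear
baseline with multiplicative scatter and i.i.d. noise:

    s(v) = m * sum_k a_k * exp(-(v - c_k)^2 / (2 w_k^2)) + b0 + b1*v + eps(v)

with amplitude ``a_k = base_k + delta_k * class + subgroup_shift_k + joint
effect``.  The multiplicative factor ``m``, the baseline and the noise are
exactly the artefacts that SNV and derivative preprocessing exist to remove.

Randomness is hierarchical: one study seed spawns per-joint, per-sample and
per-replicate generators keyed by their identifiers, so dropping a sample
never shifts any other sample's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .blocks import BlockSet, SpectralBlock, StudyDesign

__all__ = [
    "AxisSpec",
    "Peak",
    "SynthConfig",
    "SynthStudy",
    "generate_study",
    "drop_sample",
    "default_config",
    "null_config",
    "strong_config",
]

MODALITIES = ("MIR", "NIR", "Raman")
SUBGROUPS = ("M1", "M2", "E1", "E2", "E3")


@dataclass
class AxisSpec:
    """Wavenumber axis of one modality: inclusive endpoints, channel count."""

    start: float
    end: float
    n_channels: int

    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.n_channels)


@dataclass
class Peak:
    """One Gaussian band.

    ``base`` is the class-independent amplitude, ``delta`` the additive class
    effect (damaged minus control), ``subgroup_shift`` an optional additive
    amplitude shift per damage subgroup.
    """

    center: float
    width: float
    base: float
    delta: float = 0.0
    subgroup_shift: dict[str, float] = field(default_factory=dict)


def _default_axes() -> dict[str, AxisSpec]:
    # Instrument-like sampling: 0.25 cm^-1 for MIR and Raman, 10 cm^-1 for
    # NIR.  The published Savitzky-Golay windows are counted in channels
    # (201 / 205), so the grid must be fine enough that a ~15-20 cm^-1 band
    # spans a good fraction of the window; on a coarse grid those windows
    # would flatten every band.
    return {
        "MIR": AxisSpec(400.0, 4000.0, 14401),
        "NIR": AxisSpec(4000.0, 10000.0, 601),
        "Raman": AxisSpec(200.0, 3400.0, 12801),
    }


def _default_peaks(delta: float, e1_shift: float) -> dict[str, list[Peak]]:
    """Bands at the positions named in the cartilage-spectroscopy literature:
    ester 1740, amide I 1655, amide II 1564, amide III 1245 (MIR); protein
    combination bands 4726/4829 (NIR); phenylalanine 1004, amide III 1250,
    amide I 1665 (Raman)."""
    e1 = {"E1": e1_shift} if e1_shift else {}
    return {
        "MIR": [
            Peak(1740.0, 16.0, 0.50, delta, dict(e1)),
            Peak(1655.0, 20.0, 1.00, -delta, dict(e1)),
            Peak(1564.0, 18.0, 0.80, delta),
            Peak(1245.0, 22.0, 0.60, 0.0),
            Peak(2930.0, 40.0, 0.40, 0.0),
        ],
        "NIR": [
            Peak(4726.0, 45.0, 0.70, delta, dict(e1)),
            Peak(4829.0, 45.0, 0.65, -delta),
            Peak(5200.0, 120.0, 1.00, 0.0),
            Peak(6900.0, 150.0, 0.80, 0.0),
        ],
        "Raman": [
            Peak(1004.0, 10.0, 0.90, delta),
            Peak(1250.0, 20.0, 0.55, -delta, dict(e1)),
            Peak(1665.0, 18.0, 0.85, 0.0),
            Peak(2940.0, 45.0, 0.70, 0.0),
        ],
    }


@dataclass
class SynthConfig:
    """Full specification of a synthetic study.

    Defaults reproduce the reference design: 10 joints x (6 damaged + 6
    control) samples = 120 specimens, five damage subgroups of 12, three
    replicate spectra per sample.
    """

    n_joints: int = 10
    samples_per_joint_per_class: int = 6
    subgroup_scheme: dict[str, float] = field(
        default_factory=lambda: {g: 0.2 for g in SUBGROUPS}
    )
    replicates_per_sample: int = 3
    axes: dict[str, AxisSpec] = field(default_factory=_default_axes)
    peaks: dict[str, list[Peak]] = field(
        default_factory=lambda: _default_peaks(delta=0.06, e1_shift=0.08)
    )
    joint_effect_sd: float = 0.05
    replicate_noise_sd: float = 0.02
    baseline_offset_range: tuple[float, float] = (0.0, 0.2)
    baseline_slope_range: tuple[float, float] = (-1e-4, 1e-4)
    scatter_range: tuple[float, float] = (0.8, 1.2)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_joints < 1 or self.samples_per_joint_per_class < 1:
            raise ValueError("need at least one joint and one sample per class")
        frac = sum(self.subgroup_scheme.values())
        if abs(frac - 1.0) > 1e-9:
            raise ValueError(f"subgroup fractions must sum to 1, got {frac}")
        for name, ax in self.axes.items():
            if ax.n_channels < 8:
                raise ValueError(f"{name}: channel count < 8")
            if name not in self.peaks or not self.peaks[name]:
                raise ValueError(f"{name}: zero peaks configured")
            lo, hi = min(ax.start, ax.end), max(ax.start, ax.end)
            for p in self.peaks[name]:
                if not (lo <= p.center <= hi):
                    raise ValueError(
                        f"{name}: peak center {p.center} outside axis [{lo}, {hi}]"
                    )
        n_damaged = self.n_joints * self.samples_per_joint_per_class
        for g, f in self.subgroup_scheme.items():
            cnt = f * n_damaged
            if abs(cnt - round(cnt)) > 1e-9:
                raise ValueError(
                    f"subgroup {g}: fraction {f} of {n_damaged} damaged samples "
                    "is not an integer count"
                )

    # -- config (de)serialisation ------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_joints": self.n_joints,
            "samples_per_joint_per_class": self.samples_per_joint_per_class,
            "subgroup_scheme": dict(self.subgroup_scheme),
            "replicates_per_sample": self.replicates_per_sample,
            "axes": {
                m: {"start": a.start, "end": a.end, "n_channels": a.n_channels}
                for m, a in self.axes.items()
            },
            "peaks": {
                m: [
                    {
                        "center": p.center,
                        "width": p.width,
                        "base": p.base,
                        "delta": p.delta,
                        "subgroup_shift": dict(p.subgroup_shift),
                    }
                    for p in ps
                ]
                for m, ps in self.peaks.items()
            },
            "joint_effect_sd": self.joint_effect_sd,
            "replicate_noise_sd": self.replicate_noise_sd,
            "baseline_offset_range": list(self.baseline_offset_range),
            "baseline_slope_range": list(self.baseline_slope_range),
            "scatter_range": list(self.scatter_range),
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "axes" in d:
            d["axes"] = {m: AxisSpec(**a) for m, a in d["axes"].items()}
        if "peaks" in d:
            d["peaks"] = {m: [Peak(**p) for p in ps] for m, ps in d["peaks"].items()}
        for k in ("baseline_offset_range", "baseline_slope_range", "scatter_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def read(cls, path) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int = 0) -> SynthConfig:
    """Moderate class effect (3x replicate noise sd on selected bands)."""
    return SynthConfig(rng_seed=seed)


def null_config(seed: int = 0) -> SynthConfig:
    """No class effect anywhere: the pipeline's type-I-error test bed."""
    return SynthConfig(
        peaks=_default_peaks(delta=0.0, e1_shift=0.0), rng_seed=seed
    )


def strong_config(seed: int = 0) -> SynthConfig:
    """Large, easily recoverable class effect (7.5x replicate noise sd)."""
    return SynthConfig(
        peaks=_default_peaks(delta=0.15, e1_shift=0.08), rng_seed=seed
    )


@dataclass
class SynthStudy:
    """Generated study: aligned blocks, design table, and per-modality truth
    (channel indices carrying a nonzero class effect, widened by +-2 widths)."""

    blocks: dict[str, SpectralBlock]
    design: StudyDesign
    truth: dict[str, np.ndarray]
    config: SynthConfig

    def block_set(self, modalities: list[str] | None = None) -> BlockSet:
        names = modalities or list(self.blocks)
        return BlockSet([self.blocks[m] for m in names])


def _truth_channels(axis: np.ndarray, peaks: list[Peak]) -> np.ndarray:
    mask = np.zeros(axis.size, bool)
    for p in peaks:
        if p.delta != 0.0:
            mask |= np.abs(axis - p.center) <= 2.0 * p.width
    return np.flatnonzero(mask)


def _build_design(cfg: SynthConfig) -> StudyDesign:
    rows = []
    labels_cycle = list(cfg.subgroup_scheme)
    counts = {
        g: round(f * cfg.n_joints * cfg.samples_per_joint_per_class)
        for g, f in cfg.subgroup_scheme.items()
    }
    remaining = dict(counts)
    k = 0  # global damaged-sample counter, cycled over subgroups
    for j in range(cfg.n_joints):
        joint = f"J{j + 1:02d}"
        for s in range(cfg.samples_per_joint_per_class):
            # damaged specimen and its adjacent control from the same joint
            g = labels_cycle[k % len(labels_cycle)]
            while remaining[g] == 0:  # exhausted under uneven schemes
                k += 1
                g = labels_cycle[k % len(labels_cycle)]
            remaining[g] -= 1
            k += 1
            rows.append((f"{joint}-D{s + 1}", joint, 1, g, cfg.replicates_per_sample))
            rows.append((f"{joint}-C{s + 1}", joint, 0, "CTRL", cfg.replicates_per_sample))
    return StudyDesign(
        pd.DataFrame(rows, columns=list(StudyDesign.REQUIRED))
    )


def _sample_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def generate_study(cfg: SynthConfig) -> SynthStudy:
    """Simulate all replicate spectra of a study for every modality.

    Reproducible for a fixed ``cfg.rng_seed``; the per-entity RNG hierarchy
    guarantees that removing one sample leaves every other spectrum
    bit-identical.
    """
    cfg.validate()
    design = _build_design(cfg)
    tbl = design.table
    joint_index = {j: i for i, j in enumerate(pd.unique(tbl["joint_id"]))}

    joint_effects = {
        j: _sample_rng(cfg.rng_seed, 1, ji).normal(0.0, cfg.joint_effect_sd)
        for j, ji in joint_index.items()
    }

    axes = {m: cfg.axes[m].values() for m in cfg.axes}
    gauss = {
        m: np.stack(
            [np.exp(-((axes[m] - p.center) ** 2) / (2.0 * p.width**2)) for p in cfg.peaks[m]]
        )
        for m in cfg.axes
    }

    row_keys: list[tuple[str, int]] = []
    data: dict[str, list[np.ndarray]] = {m: [] for m in cfg.axes}
    for row in tbl.itertuples(index=False):
        ji = joint_index[row.joint_id]
        je = joint_effects[row.joint_id]
        # key sample-level draws by (joint, within-joint position, class),
        # recoverable from the sample id itself so the keying is stable
        si = int(str(row.sample_id).split("-")[1][1:]) * 2 + int(row.label)
        srng = _sample_rng(cfg.rng_seed, 2, ji, si)
        for r in range(cfg.replicates_per_sample):
            rrng = _sample_rng(cfg.rng_seed, 3, ji, si, r)
            row_keys.append((row.sample_id, r))
            for m in cfg.axes:
                amps = np.array(
                    [
                        p.base
                        + p.delta * row.label
                        + (p.subgroup_shift.get(row.subgroup, 0.0) if row.label else 0.0)
                        + je
                        for p in cfg.peaks[m]
                    ]
                )
                scatter = srng.uniform(*cfg.scatter_range)
                b0 = srng.uniform(*cfg.baseline_offset_range)
                b1 = srng.uniform(*cfg.baseline_slope_range)
                spectrum = scatter * amps @ gauss[m] + b0 + b1 * axes[m]
                if cfg.replicate_noise_sd > 0:
                    spectrum = spectrum + rrng.normal(
                        0.0, cfg.replicate_noise_sd, axes[m].size
                    )
                data[m].append(spectrum)

    # all replicates of one sample share their row_keys ordering across blocks
    keys_per_block = row_keys
    blocks = {
        m: SpectralBlock(
            modality=m,
            axis=axes[m],
            intensities=np.asarray(data[m]),
            row_keys=list(keys_per_block),
            provenance=[f"synthetic(seed={cfg.rng_seed})"],
        )
        for m in cfg.axes
    }
    truth = {m: _truth_channels(axes[m], cfg.peaks[m]) for m in cfg.axes}
    return SynthStudy(blocks=blocks, design=design, truth=truth, config=cfg)


def drop_sample(study: SynthStudy, sample_id: str) -> SynthStudy:
    """Exclude one sample (all replicates) from every block and the design,
    preserving cross-block row correspondence."""
    design = study.design.drop_sample(sample_id)  # raises on unknown id
    keep = np.array([k[0] != sample_id for k in study.blocks[next(iter(study.blocks))].row_keys])
    idx = np.flatnonzero(keep)
    blocks = {
        m: b.select_rows(idx, note=f"drop_sample({sample_id})")
        for m, b in study.blocks.items()
    }
    return SynthStudy(blocks=blocks, design=design, truth=study.truth, config=study.config)
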