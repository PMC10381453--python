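"""Core data containers: spectral blocks, study design, aligned block sets.

A *block* is one modality's wide spectral matrix (rows = spectra, columns =
wavenumber channels in cm^-1).  A *study design* carries the sample-level
metadata (joint, class, damage subgroup, replicate) that the grouped
cross-validation and the interpretation layer need.  A *block set* is an
ordered collection of blocks with row-for-row sample correspondence — the
precondition for any multi-block model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SpectralBlock", "StudyDesign", "BlockSet"]


@dataclass
class SpectralBlock:
    """One modality's spectra on a common wavenumber axis.

    Parameters
    ----------
    modality
        Label, e.g. ``"MIR"``, ``"NIR"``, ``"Raman"``.
    axis
        Wavenumbers in cm^-1, strictly increasing, one per column.
    intensities
        2-D array, one row per spectrum.
    row_keys
        List of ``(sample_id, replicate)`` tuples, one per row.  After
        replicate averaging the replicate slot is 0.
    provenance
        Free-form record of the transforms applied so far.
    """

    modality: str
    axis: np.ndarray
    intensities: np.ndarray
    row_keys: list[tuple[str, int]]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.axis.ndim != 1:
            raise ValueError("axis must be one-dimensional")
        if self.intensities.shape[1] != self.axis.size:
            raise ValueError(
                f"{self.modality}: axis has {self.axis.size} channels but "
                f"intensity matrix has {self.intensities.shape[1]} columns"
            )
        if len(self.row_keys) != self.intensities.shape[0]:
            raise ValueError(f"{self.modality}: row_keys/intensity row mismatch")
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError(f"{self.modality}: axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"{self.modality}: non-finite intensities")

    @property
    def n_rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    def with_data(
        self,
        intensities: np.ndarray | None = None,
        axis: np.ndarray | None = None,
        row_keys: list[tuple[str, int]] | None = None,
        note: str | None = None,
    ) -> "SpectralBlock":
        """Copy with replaced data and an optional provenance note."""
        prov = list(self.provenance) + ([note] if note else [])
        return SpectralBlock(
            modality=self.modality,
            axis=self.axis if axis is None else axis,
            intensities=self.intensities if intensities is None else intensities,
            row_keys=list(self.row_keys) if row_keys is None else list(row_keys),
            provenance=prov,
        )

    def select_rows(self, idx: np.ndarray, note: str | None = None) -> "SpectralBlock":
        idx = np.asarray(idx)
        return self.with_data(
            intensities=self.intensities[idx],
            row_keys=[self.row_keys[i] for i in np.atleast_1d(idx)],
            note=note,
        )

    # -- delimited-text I/O (header row = wavenumbers) ----------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=[repr(float(v)) for v in self.axis])
        df.insert(0, "sample_id", [k[0] for k in self.row_keys])
        df.insert(1, "replicate", [k[1] for k in self.row_keys])
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, modality: str) -> "SpectralBlock":
        df = pd.read_csv(path, sep="\t")
        keys = list(zip(df["sample_id"].astype(str), df["replicate"].astype(int)))
        mat = df.drop(columns=["sample_id", "replicate"])
        axis = np.array([float(c) for c in mat.columns])
        return cls(modality=modality, axis=axis, intensities=mat.to_numpy(float), row_keys=keys)


@dataclass
class StudyDesign:
    """Sample-level metadata shared by all blocks of a study.

    ``table`` has one row per sample with columns ``sample_id``, ``joint_id``,
    ``label`` (0 = normal cartilage, 1 = damaged cartilage), ``subgroup``
    (M1/M2/E1/E2/E3 for damaged, "CTRL" for controls) and ``replicates``.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "joint_id", "label", "subgroup", "replicates")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if not set(np.unique(self.table["label"])) <= {0, 1}:
            raise ValueError("labels must be 0/1")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy(int)

    @property
    def joints(self) -> np.ndarray:
        return self.table["joint_id"].to_numpy()

    @property
    def subgroups(self) -> np.ndarray:
        return self.table["subgroup"].to_numpy()

    def drop_sample(self, sample_id: str) -> "StudyDesign":
        if sample_id not in set(self.table["sample_id"]):
            raise KeyError(f"unknown sample id: {sample_id!r}")
        return StudyDesign(self.table[self.table["sample_id"] != sample_id].copy())

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "StudyDesign":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "joint_id": str})
        return cls(df)


@dataclass
class BlockSet:
    """Ordered, row-aligned blocks entering a fusion model.

    All blocks must share identical ``row_keys`` (sample-to-sample
    correspondence).  ``boundaries`` maps each modality to its column slice
    in the concatenated super-matrix.
    """

    blocks: list[SpectralBlock]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("empty block set")
        keys0 = self.blocks[0].row_keys
        for b in self.blocks[1:]:
            if b.row_keys != keys0:
                raise ValueError(
                    f"row keys of block {b.modality!r} do not match "
                    f"{self.blocks[0].modality!r}: multi-block analysis requires "
                    "sample-to-sample correspondence"
                )
        names = [b.modality for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate modality labels in block set")

    @property
    def row_keys(self) -> list[tuple[str, int]]:
        return self.blocks[0].row_keys

    @property
    def modalities(self) -> list[str]:
        return [b.modality for b in self.blocks]

    @property
    def n_rows(self) -> int:
        return self.blocks[0].n_rows

    @property
    def boundaries(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        start = 0
        for b in self.blocks:
            out[b.modality] = slice(start, start + b.n_channels)
            start += b.n_channels
        return out

    def concatenate(self) -> np.ndarray:
        return np.hstack([b.intensities for b in self.blocks])

    def subset(self, modalities: list[str]) -> "BlockSet":
        have = {b.modality: b for b in self.blocks}
        missing = [m for m in modalities if m not in have]
        if missing:
            raise KeyError(f"modalities absent from block set: {missing}")
        return BlockSet([have[m] for m in modalities])

    def select_rows(self, idx: np.ndarray) -> "BlockSet":
        return BlockSet([b.select_rows(idx) for b in self.blocks])
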