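"""Viscosity dataset schema, CSV I/O and the train/test/external split.

Records carry a system identifier (one DES composition family, e.g.
``DES6.1``), the mixture composition, temperature in K and viscosity in
mPa*s.  The modelled response is ``log10(eta / mPa*s)``.

The partitioning follows the ordered-response scheme: records are sorted
by log viscosity, every k-th record (default k = 9, ~11% of the data)
becomes the untouched external test set, and the remainder is randomly
divided so that the training set holds ~80% of the *total* data, leaving
~9% for internal testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .profiles import Component, DescriptorVector, MixtureSpec, mix_descriptors

__all__ = [
    "ViscosityRecord",
    "Dataset",
    "DATASET_COLUMNS",
    "read_dataset",
    "write_dataset",
    "ordered_response_split",
    "random_split",
    "split_dataset",
]

DATASET_COLUMNS = [
    "system_id",
    "hba",
    "hbd",
    "cosolvent",
    "ratio_hba",
    "ratio_hbd",
    "x_hba",
    "x_hbd",
    "x_cosolv",
    "T_K",
    "eta_mPas",
    "source",
]

#: Temperature window of the underlying experimental database (K).
T_DOMAIN = (283.15, 373.15)

SPLIT_LABELS = ("train", "test", "external")


@dataclass
class ViscosityRecord:
    """One (composition, temperature, viscosity) observation."""

    system_id: str
    mixture: MixtureSpec
    temperature: float
    viscosity: float
    source: str = ""
    split: str | None = None

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValidationError(
                f"{self.system_id}: viscosity must be positive, got "
                f"{self.viscosity}"
            )
        if not T_DOMAIN[0] <= self.temperature <= T_DOMAIN[1]:
            warnings.warn(
                f"{self.system_id}: T = {self.temperature} K lies outside "
                f"the in-domain window {T_DOMAIN}",
                stacklevel=2,
            )

    @property
    def log_viscosity(self) -> float:
        return float(np.log10(self.viscosity))


@dataclass
class Dataset:
    """A list of viscosity records plus, once attached, the p x 9 feature
    matrix ``(S1..S8, T)`` used by the network."""

    records: list[ViscosityRecord]
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.shape != (len(self.records), 9):
                raise ValidationError(
                    f"feature matrix shape {self.features.shape} does not "
                    f"match {len(self.records)} records x 9 inputs"
                )

    def __len__(self) -> int:
        return len(self.records)

    # -- derived arrays ----------------------------------------------------

    @property
    def log_viscosity(self) -> np.ndarray:
        return np.array([r.log_viscosity for r in self.records])

    @property
    def splits(self) -> np.ndarray:
        return np.array(
            [r.split if r.split is not None else "" for r in self.records]
        )

    @property
    def system_ids(self) -> np.ndarray:
        return np.array([r.system_id for r in self.records])

    def mask(self, split: str) -> np.ndarray:
        return self.splits == split

    def subset(self, index: np.ndarray) -> "Dataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        recs = [self.records[i] for i in index]
        feats = self.features[index] if self.features is not None else None
        return Dataset(records=recs, features=feats)

    def design(self, split: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, y)``; restricted to one split label if given."""
        if self.features is None:
            raise ValidationError(
                "no feature matrix attached; call attach_descriptors first"
            )
        if split is None:
            return self.features, self.log_viscosity
        m = self.mask(split)
        return self.features[m], self.log_viscosity[m]

    # -- descriptors -------------------------------------------------------

    def attach_descriptors(
        self, pure: Mapping[str, DescriptorVector]
    ) -> "Dataset":
        """Build the feature matrix from per-compound descriptors (in place).

        Each row is the mole-fraction mixed S1..S8 of the record's
        composition followed by its temperature in K.
        """
        feats = np.empty((len(self.records), 9))
        for i, rec in enumerate(self.records):
            d = mix_descriptors(pure, rec.mixture)
            feats[i, :8] = d.s
            feats[i, 8] = rec.temperature
        self.features = feats
        return self

    # -- tabular I/O -------------------------------------------------------

    def to_frame(self, include_split: bool = True) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            hba = rec.mixture.component_by_role("hba")
            hbd = rec.mixture.component_by_role("hbd")
            cos = rec.mixture.component_by_role("cosolvent")
            ratio = hbd.mole_fraction / hba.mole_fraction
            row = {
                "system_id": rec.system_id,
                "hba": hba.compound_id,
                "hbd": hbd.compound_id,
                "cosolvent": cos.compound_id if cos else "",
                "ratio_hba": 1.0,
                "ratio_hbd": ratio,
                "x_hba": hba.mole_fraction,
                "x_hbd": hbd.mole_fraction,
                "x_cosolv": cos.mole_fraction if cos else 0.0,
                "T_K": rec.temperature,
                "eta_mPas": rec.viscosity,
                "source": rec.source,
            }
            if include_split:
                row["split"] = rec.split if rec.split is not None else ""
            rows.append(row)
        return pd.DataFrame(rows)


def write_dataset(
    dataset: Dataset, target: Union[str, IO[str]], include_split: bool = True
) -> None:
    dataset.to_frame(include_split=include_split).to_csv(
        target, index=False, float_format="%.17g"
    )


def read_dataset(source: Union[str, IO[str]]) -> Dataset:
    """Read the dataset CSV schema into a validated :class:`Dataset`.

    Mole fractions that sum to 1 within 1e-6 are renormalized; larger
    discrepancies are rejected.  Non-positive viscosities are rejected
    with the offending row numbers listed.
    """
    df = pd.read_csv(source, keep_default_na=False, float_precision="round_trip")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"dataset CSV missing columns: {', '.join(missing)}")
    eta = pd.to_numeric(df["eta_mPas"], errors="coerce")
    bad = df.index[~(eta > 0)].tolist()
    if bad:
        raise ValidationError(
            f"non-positive or non-numeric viscosity in rows {bad}"
        )
    records: list[ViscosityRecord] = []
    for idx, row in df.iterrows():
        x = np.array(
            [float(row["x_hba"]), float(row["x_hbd"]), float(row["x_cosolv"])]
        )
        total = x.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"row {idx}: mole fractions sum to {total}, expected 1 "
                "within 1e-6"
            )
        x = x / total
        comps = [
            Component(str(row["hba"]), x[0], "hba"),
            Component(str(row["hbd"]), x[1], "hbd"),
        ]
        if x[2] > 0:
            cos_id = str(row["cosolvent"]) or "cosolvent"
            comps.append(Component(cos_id, x[2], "cosolvent"))
        split = None
        if "split" in df.columns:
            label = str(row["split"])
            split = label if label in SPLIT_LABELS else None
        records.append(
            ViscosityRecord(
                system_id=str(row["system_id"]),
                mixture=MixtureSpec(components=tuple(comps)),
                temperature=float(row["T_K"]),
                viscosity=float(row["eta_mPas"]),
                source=str(row["source"]),
                split=split,
            )
        )
    return Dataset(records=records)


# ---------------------------------------------------------------------------
# splitting


def ordered_response_split(
    dataset: Dataset, every_kth: int = 9
) -> tuple[Dataset, Dataset]:
    """Systematic external-test selection over the response-sorted data.

    Records are sorted ascending by log viscosity (ties broken by original
    order) and the k-th, 2k-th, ... records of the sorted sequence are
    labelled ``external``; the rest are returned unlabelled for the
    subsequent random train/test division.
    """
    if every_kth < 2:
        raise ValidationError("every_kth must be >= 2")
    order = np.argsort(dataset.log_viscosity, kind="stable")
    external_pos = order[every_kth - 1 :: every_kth]
    is_external = np.zeros(len(dataset), dtype=bool)
    is_external[external_pos] = True
    external = dataset.subset(is_external)
    for rec in external.records:
        rec.split = "external"
    remainder = dataset.subset(~is_external)
    return external, remainder


def random_split(
    remainder: Dataset,
    train_fraction_of_total: float = 0.8,
    seed: int = 0,
    total_size: int | None = None,
) -> Dataset:
    """Seeded random train/test labelling of the non-external records.

    ``train_fraction_of_total`` refers to the size of the dataset *before*
    the external records were removed (pass ``total_size``; defaults to
    ``len(remainder)`` when the split is used standalone), so the overall
    scheme is ~80% train / ~9% test / ~11% external.
    """
    if not 0.0 < train_fraction_of_total < 1.0:
        raise ValidationError("train fraction must lie in (0, 1)")
    n_total = total_size if total_size is not None else len(remainder)
    n_train = int(round(train_fraction_of_total * n_total))
    n_test = len(remainder) - n_train
    if n_train < 1 or n_test < 1:
        raise ValidationError(
            f"train fraction {train_fraction_of_total} incompatible with "
            f"{len(remainder)} non-external records out of {n_total}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(remainder))
    for i, rec in enumerate(remainder.records):
        rec.split = None
    for pos in perm[:n_train]:
        remainder.records[pos].split = "train"
    for pos in perm[n_train:]:
        remainder.records[pos].split = "test"
    return remainder


def split_dataset(
    dataset: Dataset,
    every_kth: int = 9,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> Dataset:
    """Apply the full ordered-response + random scheme to one dataset.

    Labels every record ``train`` / ``test`` / ``external`` in place and
    returns the dataset.
    """
    n_total = len(dataset)
    external, remainder = ordered_response_split(dataset, every_kth=every_kth)
    random_split(
        remainder, train_fraction_of_total=train_fraction, seed=seed,
        total_size=n_total,
    )
    return dataset
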