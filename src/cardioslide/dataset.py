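"""Patient-exclusive dataset construction.

Builds manifests joining image items to patient labels, splits patients
(never items) into train/test, and augments the training split by the
four lossless right-angle rotations.  Patient exclusivity — no patient
contributing images to both splits — is validated on every manifest,
because identity leakage silently inflates test accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["item_path", "patient_id", "label", "split", "augmentation_tag"]
ROTATION_TAGS = ("rot0", "rot90", "rot180", "rot270")


class IntegrityError(ValueError):
    """Manifest violates a structural invariant (duplicate paths,
    orphan patients, split leakage)."""


class ConfigurationError(ValueError):
    """Split request cannot be satisfied by the available patients."""


class PolicyError(ValueError):
    """Operation requested on a split it must not touch."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: identifier, cohort, binary outcome label, items.

    ``label_provenance`` stores how the clinical label was defined
    (free text, e.g. the echocardiographic response rule); it is carried
    as metadata only and never recomputed here.
    """

    patient_id: str
    cohort: str
    label: int
    item_paths: tuple[str, ...]
    label_provenance: str = ""

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if len(self.item_paths) < 1:
            raise ValueError("a patient needs at least one item")


@dataclass(frozen=True)
class SplitSpec:
    """Per-class patient counts for the train and test splits."""

    train_per_class: tuple[int, int]   # (negatives, positives)
    test_per_class: tuple[int, int]
    random_seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.train_per_class + self.test_per_class):
            raise ValueError("patient counts must be non-negative")


@dataclass
class Manifest:
    """Item table every training/evaluation stage consumes.

    Wraps a DataFrame with columns ``item_path, patient_id, label,
    split, augmentation_tag`` plus provenance metadata (the split seed).
    """

    frame: pd.DataFrame
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise IntegrityError(f"manifest missing columns {missing}")
        self.frame = self.frame[MANIFEST_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.frame
        key = df["item_path"] + "::" + df["augmentation_tag"].fillna("")
        if key.duplicated().any():
            dup = df.loc[key.duplicated(), "item_path"].iloc[0]
            raise IntegrityError(f"duplicate item: {dup}")
        by_patient = df.groupby("patient_id")["split"].nunique()
        leaky = by_patient[by_patient > 1]
        if len(leaky):
            raise IntegrityError(
                f"patients in both splits: {list(leaky.index[:5])}"
            )

    def subset(self, split: str) -> "Manifest":
        return Manifest(self.frame[self.frame["split"] == split].copy(), seed=self.seed)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def patients(self) -> list[str]:
        return sorted(self.frame["patient_id"].unique())

    def to_csv(self, path: str | Path) -> None:
        """CSV plus a JSON sidecar carrying config/seed provenance."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump({"seed": self.seed, "n_items": len(self.frame)}, fh)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Manifest":
        path = Path(path)
        frame = pd.read_csv(path, keep_default_na=False)
        frame["label"] = frame["label"].astype(int)
        seed = None
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            with open(sidecar) as fh:
                seed = json.load(fh).get("seed")
        return cls(frame, seed=seed)


def build_manifest(
    items: pd.DataFrame, records: Sequence[PatientRecord], split: str = "train"
) -> Manifest:
    """Join an item table (``item_path``, ``patient_id``) with patient labels.

    Every item's patient must exist in ``records``; duplicate paths are
    rejected.
    """
    labels = {r.patient_id: r.label for r in records}
    orphans = set(items["patient_id"]) - set(labels)
    if orphans:
        raise IntegrityError(f"items reference unknown patients: {sorted(orphans)[:5]}")
    df = items[["item_path", "patient_id"]].copy()
    df["label"] = df["patient_id"].map(labels).astype(int)
    df["split"] = split
    df["augmentation_tag"] = "rot0"
    return Manifest(df)


def patient_split(
    records: Sequence[PatientRecord],
    spec: SplitSpec,
    items: pd.DataFrame | None = None,
) -> Manifest:
    """Assign whole patients to train/test by seeded stratified sampling.

    All of a patient's items inherit that patient's split.  ``items``
    may supply an explicit item table (``item_path, patient_id``);
    otherwise each record's ``item_paths`` are used.
    """
    rng = np.random.default_rng(spec.random_seed)
    by_class: dict[int, list[PatientRecord]] = {0: [], 1: []}
    for r in records:
        by_class[r.label].append(r)

    assignment: dict[str, str] = {}
    for label in (0, 1):
        pool = sorted(by_class[label], key=lambda r: r.patient_id)
        need = spec.train_per_class[label] + spec.test_per_class[label]
        if need > len(pool):
            raise ConfigurationError(
                f"class {label}: requested {need} patients, only {len(pool)} available"
            )
        order = rng.permutation(len(pool))
        chosen = [pool[i] for i in order[:need]]
        for i, rec in enumerate(chosen):
            split = "train" if i < spec.train_per_class[label] else "test"
            assignment[rec.patient_id] = split

    rows = []
    if items is not None:
        for _, row in items.iterrows():
            pid = row["patient_id"]
            if pid not in assignment:
                continue
            label = next(r.label for r in records if r.patient_id == pid)
            rows.append((row["item_path"], pid, label, assignment[pid], "rot0"))
    else:
        for rec in records:
            if rec.patient_id not in assignment:
                continue
            for p in rec.item_paths:
                rows.append((p, rec.patient_id, rec.label, assignment[rec.patient_id], "rot0"))
    frame = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return Manifest(frame, seed=spec.random_seed)


def rotate_augment(manifest: Manifest, split: str = "train") -> Manifest:
    """Quadruple the training split by the four right-angle rotations.

    Each training item is replaced by four tagged rows (rot0/90/180/270);
    pixel rotation itself happens losslessly at load time (``np.rot90``),
    so no extra image files are materialised.  The test split passes
    through untouched; asking to augment it is a policy error.
    """
    if split != "train":
        raise PolicyError("augmentation is restricted to the training split")
    df = manifest.frame
    train = df[df["split"] == split]
    rest = df[df["split"] != split]
    out = []
    for tag in ROTATION_TAGS:
        block = train.copy()
        block["augmentation_tag"] = tag
        out.append(block)
    out.append(rest)
    frame = pd.concat(out, ignore_index=True)
    return Manifest(frame, seed=manifest.seed)


def apply_rotation(image: np.ndarray, tag: str) -> np.ndarray:
    """Materialise an augmentation tag as an exact k*90-degree rotation."""
    k = ROTATION_TAGS.index(tag)
    return np.ascontiguousarray(np.rot90(image, k))
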