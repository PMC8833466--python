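"""Simulated three-reader ordinal (Likert 1-4) scoring of the five datasets.

Each rated item is generated by a cumulative-threshold (ordered-categorical)
model: a patient/dataset latent value, plus independent per-reader Gaussian
jitter, is cut at three thresholds into the four ordinal levels.

Latents are stated monotone functions of the quantitative metrics:

* ``image_quality``   — log apparent SNR minus a per-dataset artifact
  penalty (computed images carry a misregistration-artifact penalty, the
  full-FOV geometry a distortion/motion penalty).
* ``lesion_detection`` — the apparent CNR of the lesion.
* ``dwi_type``        — the lesion-to-parenchyma contrast ratio, cut in
  *descending* order (type 1 = clearly hyperintense ... type 4 = hypointense).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import ConfigurationError
from .roi import MetricRecord

DATASET_IDS = ("f-aDWI600", "f-cDWI1000", "r-aDWI600", "r-cDWI1000", "r-aDWI1000")

ITEMS = ("image_quality", "lesion_detection", "dwi_type")


@dataclass(frozen=True)
class ItemModel:
    """One rated item: latent source, 3 ascending cutpoints, reader jitter.

    ``descending=True`` reverses the coding so that *larger* latent values map
    to *smaller* scores (used for the DWI signal-intensity type).
    """

    name: str
    thresholds: tuple[float, float, float]
    jitter_sd: float
    descending: bool = False

    def __post_init__(self) -> None:
        t = self.thresholds
        if not (t[0] < t[1] < t[2]):
            raise ConfigurationError(f"{self.name}: thresholds must be strictly increasing, got {t}")
        if self.jitter_sd < 0:
            raise ConfigurationError(f"{self.name}: jitter_sd must be >= 0")

    def score(self, latent: np.ndarray) -> np.ndarray:
        s = 1 + (latent[..., None] >= np.asarray(self.thresholds)).sum(axis=-1)
        return 5 - s if self.descending else s


@dataclass(frozen=True)
class RatingModel:
    """Reader panel model: item models plus per-dataset artifact penalties."""

    items: tuple[ItemModel, ...]
    artifact_penalty: dict = field(default_factory=dict)
    n_readers: int = 3

    def item(self, name: str) -> ItemModel:
        for it in self.items:
            if it.name == name:
                return it
        raise ConfigurationError(f"no ItemModel named {name!r}")


def default_rating_model(agreement: str = "high") -> RatingModel:
    """The default high-agreement panel (jitter calibrated to kappa ≈ 0.9).

    ``agreement="low"`` triples the reader jitter (for sensitivity checks).
    """
    scale = {"high": 1.0, "low": 3.0}[agreement]
    return RatingModel(
        items=(
            ItemModel("image_quality", thresholds=(0.7, 1.55, 2.4), jitter_sd=0.005 * scale),
            ItemModel("lesion_detection", thresholds=(4.0, 7.0, 10.5), jitter_sd=0.015 * scale),
            ItemModel("dwi_type", thresholds=(0.9, 1.52, 2.02), jitter_sd=0.0025 * scale, descending=True),
        ),
        artifact_penalty={
            "f-aDWI600": 1.20,   # full-FOV distortion / motion
            "f-cDWI1000": 1.65,  # + misregistration artifacts of the computed image
            "r-aDWI600": 0.00,
            "r-cDWI1000": 0.30,
            "r-aDWI1000": 0.08,
        },
    )


def _latent(item: ItemModel, rec: MetricRecord, model: RatingModel) -> float:
    if item.name == "image_quality":
        return float(np.log(max(rec.asnr, 1e-6)) - model.artifact_penalty.get(rec.dataset_id, 0.0))
    if item.name == "lesion_detection":
        return float(rec.acnr)
    if item.name == "dwi_type":
        return float(rec.cr_proximal)
    raise ConfigurationError(f"no latent definition for item {item.name!r}")


def simulate_reader_scores(metrics, rating_model: RatingModel | None = None, seed: int = 0) -> pd.DataFrame:
    """Simulate the reader panel on a cohort's metric records.

    Returns a tidy Likert table (patient_id, dataset_id, reader_id, item,
    score) with the complete patients x datasets x readers crossing per item.
    Deterministic given ``seed``; with ``jitter_sd = 0`` all readers agree
    exactly.
    """
    model = rating_model or default_rating_model()
    records = list(metrics)
    if not records:
        raise ValueError("metrics must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for item in model.items:
        base = np.array([_latent(item, r, model) for r in records])
        jitter = (
            rng.standard_normal((len(records), model.n_readers)) * item.jitter_sd
            if item.jitter_sd > 0
            else np.zeros((len(records), model.n_readers))
        )
        scores = item.score(base[:, None] + jitter)
        for i, rec in enumerate(records):
            for reader in range(model.n_readers):
                rows.append(
                    (rec.patient_id, rec.dataset_id, f"reader{reader + 1}",
                     item.name, int(scores[i, reader]))
                )
    return pd.DataFrame(rows, columns=["patient_id", "dataset_id", "reader_id", "item", "score"])


def likert_counts(likert: pd.DataFrame, item: str, dataset_id: str, n_categories: int = 4) -> np.ndarray:
    """Subjects x categories rater tally for one item/dataset (Fleiss input)."""
    sub = likert[(likert["item"] == item) & (likert["dataset_id"] == dataset_id)]
    if sub.empty:
        raise ValueError(f"no ratings for item={item!r}, dataset={dataset_id!r}")
    patients = sorted(sub["patient_id"].unique())
    counts = np.zeros((len(patients), n_categories), dtype=int)
    for i, pid in enumerate(patients):
        for s in sub.loc[sub["patient_id"] == pid, "score"]:
            counts[i, int(s) - 1] += 1
    return counts


def scores_matrix(likert: pd.DataFrame, item: str, reader_id: str = "reader1") -> pd.DataFrame:
    """Patients x datasets score matrix of one reader (rank-test input)."""
    sub = likert[(likert["item"] == item) & (likert["reader_id"] == reader_id)]
    return sub.pivot(index="patient_id", columns="dataset_id", values="score")[list(DATASET_IDS)]
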