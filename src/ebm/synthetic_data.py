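"""Synthetic cohorts with known ground truth.

The generator mirrors the generative reading of the event-based model: each
subject carries a hidden stage k; biomarkers whose event position is at or
before k are drawn from their abnormal component, the rest from the normal
component, independently given the stage.  Two sporadic-disease
imperfections are built in:

* contamination — a fraction of the cognitively-normal group are
  presymptomatic cases drawn from nonzero (early) stages; about a third of
  apparently healthy elderly carry such biomarker evidence;
* misdiagnosis — a modest fraction of the patient group are drawn from
  stage 0.

Default group sizes (CN 97 / MCI 135 / AD 68, J = 300) follow the diagnostic
proportions of a typical sporadic Alzheimer's cohort; the default separation
between components is 2 pooled SDs, a realistic overlap for CSF and volumetric
markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .data_io import BASELINE_VISIT, BiomarkerDataset
from .sequence_inference import EventSequence


def _triangular_weights(n_stages: int) -> np.ndarray:
    """Symmetric triangular bump over stages 0..N, peaked at the middle."""
    k = np.arange(n_stages + 1)
    peak = n_stages / 2.0
    w = 1.0 + (peak - np.abs(k - peak))
    return w / w.sum()


@dataclass
class SimulationScenario:
    """Ground-truth configuration for a synthetic cohort.

    ``separation`` is the distance between the normal and abnormal component
    means in units of the (common) component SD.  Stage distributions default
    to: CN at stage 0 except for the contaminated fraction, spread uniformly
    over the early stages 1..min(6, N); AD concentrated on the last four
    stages (most at stage N) except for the misdiagnosed fraction at stage 0;
    MCI a triangular bump over the middle stages.  All are user-overridable.
    """

    n_events: int = 14
    sequence_truth: tuple | None = None       # default: identity ordering
    separation: float = 2.0
    sd_normal: float = 1.0
    sd_abnormal: float = 1.0
    directions: tuple | None = None           # default: all "increase"
    n_cn: int = 97
    n_mci: int = 135
    n_ad: int = 68
    contamination: float = 1.0 / 3.0
    misdiagnosis: float = 0.1
    stage_distributions: dict = field(default=None)  # label -> length N+1 probs
    seed: int = 0

    def __post_init__(self):
        n = self.n_events
        if self.sequence_truth is None:
            self.sequence_truth = tuple(range(n))
        self.sequence_truth = tuple(int(i) for i in self.sequence_truth)
        if sorted(self.sequence_truth) != list(range(n)):
            raise ValueError("sequence_truth must be a permutation of 0..N-1")
        if self.directions is None:
            self.directions = ("increase",) * n
        if len(self.directions) != n:
            raise ValueError("directions must have one entry per event")
        for frac in (self.contamination, self.misdiagnosis):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("contamination/misdiagnosis fractions must lie in [0, 1]")
        if min(self.n_cn, self.n_mci, self.n_ad) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.stage_distributions is None:
            self.stage_distributions = {}
        for lab, probs in self.stage_distributions.items():
            p = np.asarray(probs, dtype=float)
            if len(p) != n + 1 or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"stage distribution for {lab!r} must be length N+1 and sum to 1")

    @property
    def biomarker_names(self) -> list:
        return [f"marker_{i + 1:02d}" for i in range(self.n_events)]

    def component_means(self):
        """(mu_normal, mu_abnormal) arrays; abnormal mean offset by the
        separation in the declared direction."""
        n = self.n_events
        mu_n = np.zeros(n)
        sign = np.where(np.asarray(self.directions) == "increase", 1.0, -1.0)
        mu_a = mu_n + sign * self.separation * self.sd_normal
        return mu_n, mu_a

    def label_stage_distribution(self, label: str) -> np.ndarray:
        if label in self.stage_distributions:
            return np.asarray(self.stage_distributions[label], dtype=float)
        n = self.n_events
        p = np.zeros(n + 1)
        if label == "CN":
            early = np.arange(1, min(6, n) + 1)
            p[0] = 1.0 - self.contamination
            p[early] = self.contamination / len(early)
        elif label == "AD":
            late = np.arange(max(0, n - 3), n + 1)[-4:]
            weights = np.array([0.1, 0.15, 0.25, 0.5])[-len(late):]
            p[late] = (1.0 - self.misdiagnosis) * weights / weights.sum()
            p[0] += self.misdiagnosis
        elif label == "MCI":
            p = _triangular_weights(n)
        else:
            raise ValueError(f"unknown label {label!r}")
        return p

    def to_yaml(self, path) -> None:
        d = {
            "n_events": self.n_events,
            "sequence_truth": list(self.sequence_truth),
            "separation": self.separation,
            "sd_normal": self.sd_normal,
            "sd_abnormal": self.sd_abnormal,
            "directions": list(self.directions),
            "n_cn": self.n_cn,
            "n_mci": self.n_mci,
            "n_ad": self.n_ad,
            "contamination": self.contamination,
            "misdiagnosis": self.misdiagnosis,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("sequence_truth") is not None:
            d["sequence_truth"] = tuple(d["sequence_truth"])
        if d.get("directions") is not None:
            d["directions"] = tuple(d["directions"])
        return cls(**d)


@dataclass
class CohortTruth:
    """Hidden ground truth emitted alongside a synthetic cohort."""

    stages: np.ndarray               # per-subject true stage
    sequence: EventSequence          # true event ordering
    labels: np.ndarray               # per-subject diagnostic label

    def to_frame(self, subject_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject": subject_ids, "true_stage": self.stages, "label": self.labels}
        )


def _draw_values(sc: SimulationScenario, stages: np.ndarray, rng) -> np.ndarray:
    mu_n, mu_a = sc.component_means()
    pos_of_event = np.empty(sc.n_events, dtype=int)
    for p, e in enumerate(sc.sequence_truth):
        pos_of_event[e] = p
    j = len(stages)
    # Event e has occurred for subject at stage k iff position(e) < k.
    occurred = pos_of_event[None, :] < stages[:, None]
    mu = np.where(occurred, mu_a[None, :], mu_n[None, :])
    sd = np.where(occurred, sc.sd_abnormal, sc.sd_normal)
    return rng.normal(mu, sd, size=(j, sc.n_events))


def generate_cohort(sc: SimulationScenario):
    """Draw a full synthetic cohort.

    Returns ``(BiomarkerDataset, CohortTruth)``: labels are assigned by group
    size, each subject's true stage is drawn from the label's stage
    distribution, and biomarker values are drawn from the per-event normal or
    abnormal component according to the true sequence and stage.
    Reproducible given ``sc.seed``.
    """
    rng = np.random.default_rng(sc.seed)
    labels = np.array(["CN"] * sc.n_cn + ["MCI"] * sc.n_mci + ["AD"] * sc.n_ad, dtype=object)
    j = len(labels)
    stages = np.empty(j, dtype=int)
    for lab in ("CN", "MCI", "AD"):
        mask = labels == lab
        if mask.any():
            p = sc.label_stage_distribution(lab)
            stages[mask] = rng.choice(sc.n_events + 1, size=mask.sum(), p=p)
    values = _draw_values(sc, stages, rng)
    ds = BiomarkerDataset(
        subject_ids=[f"S{r + 1:04d}" for r in range(j)],
        biomarker_names=sc.biomarker_names,
        values=values,
        diagnosis=labels,
        direction=dict(zip(sc.biomarker_names, sc.directions)),
        visit=np.array([BASELINE_VISIT] * j, dtype=object),
    )
    truth = CohortTruth(stages=stages, sequence=EventSequence(sc.sequence_truth), labels=labels)
    return ds, truth


def generate_staged_subjects(sc: SimulationScenario, stages, seed: int = 0,
                             label: str = "MCI") -> BiomarkerDataset:
    """Draw one subject per entry of ``stages`` at exactly that true stage.

    Useful for staging checks where every stage must be represented.
    """
    stages = np.asarray(stages, dtype=int)
    if np.any(stages < 0) or np.any(stages > sc.n_events):
        raise ValueError("stages must lie in 0..N")
    rng = np.random.default_rng(seed)
    values = _draw_values(sc, stages, rng)
    j = len(stages)
    return BiomarkerDataset(
        subject_ids=[f"S{r + 1:04d}" for r in range(j)],
        biomarker_names=sc.biomarker_names,
        values=values,
        diagnosis=np.array([label] * j, dtype=object),
        direction=dict(zip(sc.biomarker_names, sc.directions)),
        visit=np.array([BASELINE_VISIT] * j, dtype=object),
    )


def generate_followup(ds: BiomarkerDataset, truth: CohortTruth, sc: SimulationScenario,
                      progression=1, seed: int = 0, visit: str = "m12"):
    """Resample the cohort at advanced stages for a follow-up visit.

    ``progression`` gives each subject's stage increment: a scalar, a
    per-subject array, or a dict mapping increment -> probability.  Stages
    are capped at N.  Returns ``(followup BiomarkerDataset, followup stages)``.
    """
    rng = np.random.default_rng(seed)
    j = ds.n_subjects
    if isinstance(progression, dict):
        incs = np.asarray(list(progression.keys()), dtype=int)
        probs = np.asarray(list(progression.values()), dtype=float)
        if np.any(incs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("increment distribution must be non-negative and sum to 1")
        increments = rng.choice(incs, size=j, p=probs)
    else:
        increments = np.broadcast_to(np.asarray(progression, dtype=int), (j,)).copy()
    if np.any(increments < 0):
        raise ValueError("stage increments must be >= 0")
    new_stages = np.minimum(truth.stages + increments, sc.n_events)
    values = _draw_values(sc, new_stages, rng)
    fu = BiomarkerDataset(
        subject_ids=list(ds.subject_ids),
        biomarker_names=list(ds.biomarker_names),
        values=values,
        diagnosis=ds.diagnosis.copy(),
        direction=dict(ds.direction),
        covariates=None if ds.covariates is None else ds.covariates.copy(),
        visit=np.array([visit] * j, dtype=object),
    )
    return fu, new_stages
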