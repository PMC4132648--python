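"""Bootstrap cross-validation of the maximum-likelihood event ordering.

Each replicate resamples subjects with replacement, re-fits every event
distribution on the resample, rebuilds the likelihood tables and reruns the
greedy sequence search.  The positional variance matrix over the B replicate
ML sequences captures the uncertainty contributed by both the distribution
fits and the ordering — typically more diffuse than the MCMC diagram, which
holds the distribution fits fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import BiomarkerDataset
from .event_distributions import event_likelihoods, fit_all_biomarkers
from .exceptions import DataValidationError, FitError
from .sequence_inference import (
    EventSequence,
    most_likely_sequence,
    positional_variance_from_samples,
)

logger = logging.getLogger(__name__)


def _resample(ds: BiomarkerDataset, idx) -> BiomarkerDataset:
    """Row resample with replacement; subject ids suffixed to stay unique."""
    idx = np.asarray(idx)
    return BiomarkerDataset(
        subject_ids=[f"{ds.subject_ids[i]}#{r}" for r, i in enumerate(idx)],
        biomarker_names=list(ds.biomarker_names),
        values=ds.values[idx],
        diagnosis=ds.diagnosis[idx],
        direction=dict(ds.direction),
        covariates=None if ds.covariates is None
        else ds.covariates.iloc[idx].reset_index(drop=True),
        visit=None if ds.visit is None else ds.visit[idx],
    )


@dataclass
class BootstrapResult:
    B: int
    ml_sequences: list          # B EventSequence records
    positional_variance: np.ndarray
    seed: int

    def diagonal_mass(self, reference: EventSequence) -> float:
        """Mean frequency with which each event lands at its reference position."""
        pos = {e: p for p, e in enumerate(reference.order)}
        n = self.positional_variance.shape[0]
        return float(np.mean([self.positional_variance[e, pos[e]] for e in range(n)]))

    def save(self, outdir, biomarker_names=None) -> None:
        import json

        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        n = self.positional_variance.shape[0]
        names = list(biomarker_names) if biomarker_names else [f"event_{i}" for i in range(n)]
        pd.DataFrame(
            self.positional_variance,
            index=names,
            columns=[f"position_{p + 1}" for p in range(n)],
        ).to_csv(outdir / "bootstrap_positional_variance.csv")
        rows = [
            {"replicate": b, "position": p + 1, "biomarker": names[e]}
            for b, seq in enumerate(self.ml_sequences)
            for p, e in enumerate(seq.order)
        ]
        pd.DataFrame(rows).to_csv(outdir / "bootstrap_sequences.csv", index=False)
        (outdir / "bootstrap_run.json").write_text(
            json.dumps({"B": self.B, "seed": int(self.seed)}, indent=2)
        )


def bootstrap_sequences(
    ds: BiomarkerDataset,
    B: int = 100,
    seed: int = 0,
    n_starts: int = 10,
    stratify: bool = False,
    max_redraws: int | None = None,
) -> BootstrapResult:
    """Re-estimate distributions and ML ordering on B bootstrap resamples.

    Subjects are resampled with replacement (unstratified by default; set
    ``stratify`` to resample within diagnostic groups).  A replicate whose
    resample has fewer than 2 CN or 2 AD subjects is redrawn and logged;
    exceeding ``max_redraws`` (default ``B // 2``) raises.  Each replicate
    consumes an independent substream of the master seed, so increasing B
    extends rather than reshuffles the replicate list.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if max_redraws is None:
        max_redraws = max(B // 2, 1)
    master = np.random.SeedSequence(seed)
    children = master.spawn(B)
    j = ds.n_subjects
    groups = None
    if stratify:
        groups = {lab: np.flatnonzero(ds.diagnosis == lab) for lab in set(ds.diagnosis)}

    ml_sequences = []
    n_redraws = 0
    for child in children:
        rng = np.random.default_rng(child)
        while True:
            if groups is None:
                idx = rng.integers(0, j, size=j)
            else:
                idx = np.concatenate(
                    [rng.choice(g, size=len(g), replace=True) for g in groups.values()]
                )
            sub = _resample(ds, idx)
            if (sub.diagnosis == "CN").sum() >= 2 and (sub.diagnosis == "AD").sum() >= 2:
                break
            n_redraws += 1
            logger.warning("bootstrap resample lacked >=2 CN or >=2 AD subjects; redrawn")
            if n_redraws > max_redraws:
                raise DataValidationError(
                    f"more than {max_redraws} bootstrap redraws: cohort too small per group"
                )
        try:
            dists = fit_all_biomarkers(sub)
        except FitError:
            # Degenerate resample (e.g. duplicated single value); treat as redraw.
            n_redraws += 1
            if n_redraws > max_redraws:
                raise
            continue
        lt = event_likelihoods(sub, dists)
        greedy_seed = int(child.generate_state(1)[0] % (2**31))
        ml_sequences.append(most_likely_sequence(lt, n_starts=n_starts, seed=greedy_seed))

    samples = np.asarray([s.order for s in ml_sequences], dtype=int)
    pv = positional_variance_from_samples(samples, ds.n_biomarkers)
    return BootstrapResult(B=len(ml_sequences), ml_sequences=ml_sequences,
                           positional_variance=pv, seed=int(seed))
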