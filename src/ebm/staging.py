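"""Patient staging under a fixed event ordering, and longitudinal checks.

A subject's stage is the number of events that have occurred: the k in 0..N
maximising the probability of their measurements given the maximum-likelihood
sequence, under a uniform stage prior.  The stage is an idealised summary —
a subject assigned stage k need not match the stage-k profile exactly; it is
simply the most compatible stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data_io import BASELINE_VISIT
from .event_distributions import LikelihoodTables
from .exceptions import PairingError
from .sequence_inference import EventSequence, stage_log_joint


@dataclass
class StageAssignment:
    """Maximum-likelihood stage for one subject, with the full stage posterior."""

    subject_id: object
    stage: int
    stage_posterior: np.ndarray  # length N+1, sums to 1
    visit: str = BASELINE_VISIT


def stage_subjects(lt: LikelihoodTables, seq: EventSequence,
                   subject_ids=None, visit=None) -> list:
    """Assign every subject its maximum-likelihood stage under ``seq``.

    For each subject the joint log-likelihood of all N+1 stages is computed
    in the log domain (shared kernel with the sequence likelihood); the
    posterior is its normalisation and the stage is the argmax, taking the
    lowest stage on ties.
    """
    joint = stage_log_joint(lt, seq)                      # J x (N+1)
    log_post = joint - logsumexp(joint, axis=1, keepdims=True)
    post = np.exp(log_post)
    stages = np.argmax(joint, axis=1)                     # argmax -> lowest index on ties
    j = lt.n_subjects
    if subject_ids is None:
        subject_ids = list(range(j))
    if visit is None:
        visit = [BASELINE_VISIT] * j
    elif isinstance(visit, str):
        visit = [visit] * j
    return [
        StageAssignment(subject_ids[r], int(stages[r]), post[r], visit[r])
        for r in range(j)
    ]


def stage_table(assignments) -> pd.DataFrame:
    """Flatten stage assignments to a table (posterior as a semicolon list)."""
    return pd.DataFrame(
        {
            "subject": [a.subject_id for a in assignments],
            "visit": [a.visit for a in assignments],
            "stage": [a.stage for a in assignments],
            "max_posterior": [float(a.stage_posterior[a.stage]) for a in assignments],
            "posterior": [";".join(f"{p:.6g}" for p in a.stage_posterior) for a in assignments],
        }
    )


def uncertainty_band(pv: np.ndarray, seq: EventSequence, stage: int,
                     band_mass: float = 0.95) -> int:
    """Sequence-uncertainty band half-width at a given stage.

    For the event at sequence position ``stage`` (stage 0 carries no event and
    has band 0), the half-width is the smallest w such that the positional
    variance mass of that event within w positions of its ML position reaches
    ``band_mass``.  A near-certain sequence gives band 0; weakly ordered
    regions widen it.
    """
    if stage <= 0:
        return 0
    n = pv.shape[0]
    event = seq.order[stage - 1]
    pos = stage - 1
    row = pv[event]
    for w in range(n):
        lo, hi = max(0, pos - w), min(n, pos + w + 1)
        if row[lo:hi].sum() >= band_mass:
            return w
    return n - 1


def longitudinal_consistency(baseline, followup, pv: np.ndarray, seq: EventSequence,
                             band_mass: float = 0.95) -> pd.DataFrame:
    """Flag subjects whose stage decreases beyond the sequence uncertainty.

    Stages should increase or remain stable over follow-up.  A subject is
    flagged inconsistent iff the follow-up stage is below baseline AND the
    drop exceeds the uncertainty band at the baseline stage.  The band is
    this package's operationalisation of positional-variance uncertainty
    (``band_mass`` default 0.95), not a formal model quantity.

    ``baseline`` and ``followup`` are lists of :class:`StageAssignment`;
    subjects are matched by id.
    """
    fu = {a.subject_id: a for a in followup}
    rows = []
    for a in baseline:
        if a.subject_id not in fu:
            raise PairingError(f"subject {a.subject_id!r} missing from follow-up")
        b = fu[a.subject_id]
        band = uncertainty_band(pv, seq, a.stage, band_mass)
        drop = a.stage - b.stage
        rows.append(
            {
                "subject": a.subject_id,
                "baseline_stage": a.stage,
                "followup_stage": b.stage,
                "band": band,
                "consistent": not (drop > 0 and drop > band),
            }
        )
    return pd.DataFrame(rows)
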