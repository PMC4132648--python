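"""Constrained two-component normal mixtures defining p(x|E) and p(x|not E).

Each biomarker's "event" is its transition from a normal to an abnormal
distribution.  Because a sporadic-disease control group is contaminated by
presymptomatic cases (and the patient group by misdiagnoses), the two
component densities are fitted to *all* subjects jointly by EM, with a weak
constraint anchoring the fit: the normal component's standard deviation may
not exceed the sample SD of the CN-labelled values, and the abnormal
component's may not exceed the sample SD of the AD-labelled values.  The
constraint is enforced by projection at each M-step (for a fixed mean the
weighted-likelihood objective is unimodal in the SD, so clipping at the bound
is the exact constrained maximiser and the EM ascent property is preserved).

The mixing weight serves fitting and descriptive cut points only; the
sequence likelihood conditions on event status, so only the component
densities enter it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import optimize, stats

from .data_io import BiomarkerDataset
from .exceptions import FitError, NumericalError, SchemaError

#: Densities are floored at this value before taking logs, so extreme
#: outliers yield a very negative but finite log-likelihood.  At realistic
#: biomarker values the floor is never active.
DENSITY_FLOOR = 1e-300


@dataclass
class EventDistribution:
    """Two-component normal model of one biomarker: not-yet-abnormal vs abnormal."""

    biomarker_name: str
    mu_normal: float
    sd_normal: float
    mu_abnormal: float
    sd_abnormal: float
    weight_normal: float
    direction: str
    loglik_trace: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.sd_normal <= 0 or self.sd_abnormal <= 0:
            raise FitError("component standard deviations must be positive")
        if not 0.0 <= self.weight_normal <= 1.0:
            raise FitError("mixing weight must lie in [0, 1]")
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"bad direction {self.direction!r}")

    def pdf_normal(self, x):
        return stats.norm.pdf(x, self.mu_normal, self.sd_normal)

    def pdf_abnormal(self, x):
        return stats.norm.pdf(x, self.mu_abnormal, self.sd_abnormal)

    def logpdf_normal(self, x):
        return stats.norm.logpdf(x, self.mu_normal, self.sd_normal)

    def logpdf_abnormal(self, x):
        return stats.norm.logpdf(x, self.mu_abnormal, self.sd_abnormal)

    def posterior_abnormal(self, x):
        """P(abnormal | x) under the fitted mixture."""
        a = (1.0 - self.weight_normal) * self.pdf_abnormal(x)
        b = self.weight_normal * self.pdf_normal(x)
        return a / (a + b)

    def to_dict(self) -> dict:
        return {
            "biomarker_name": self.biomarker_name,
            "mu_normal": float(self.mu_normal),
            "sd_normal": float(self.sd_normal),
            "mu_abnormal": float(self.mu_abnormal),
            "sd_abnormal": float(self.sd_abnormal),
            "weight_normal": float(self.weight_normal),
            "direction": self.direction,
        }


class DistributionSet:
    """Ordered collection of per-biomarker :class:`EventDistribution` records."""

    def __init__(self, distributions):
        self.distributions = list(distributions)
        names = [d.biomarker_name for d in self.distributions]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate biomarker name in DistributionSet")
        self._by_name = {d.biomarker_name: d for d in self.distributions}

    def __len__(self):
        return len(self.distributions)

    def __iter__(self):
        return iter(self.distributions)

    def __getitem__(self, name: str) -> EventDistribution:
        return self._by_name[name]

    @property
    def names(self):
        return [d.biomarker_name for d in self.distributions]

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump([d.to_dict() for d in self.distributions], sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path) -> "DistributionSet":
        records = yaml.safe_load(Path(path).read_text())
        return cls(EventDistribution(**r) for r in records)


@dataclass
class LikelihoodTables:
    """Per-subject, per-biomarker event/no-event densities (and their logs).

    ``like_event[j, i]`` is the density of subject j's measurement of
    biomarker i under the abnormal component; ``like_noevent`` under the
    normal component.  These two J x N tables are the only input the sequence
    likelihood needs.
    """

    like_event: np.ndarray
    like_noevent: np.ndarray
    log_like_event: np.ndarray
    log_like_noevent: np.ndarray
    biomarker_names: list

    def __post_init__(self):
        for m in (self.like_event, self.like_noevent):
            if not np.all(np.isfinite(m)) or np.any(m <= 0):
                raise NumericalError("likelihood tables must be strictly positive and finite")
        if self.like_event.shape != self.like_noevent.shape:
            raise NumericalError("likelihood table shapes differ")

    @property
    def n_subjects(self) -> int:
        return self.like_event.shape[0]

    @property
    def n_events(self) -> int:
        return self.like_event.shape[1]


def _mixture_loglik(x, w, mu_n, sd_n, mu_a, sd_a):
    dens = w * stats.norm.pdf(x, mu_n, sd_n) + (1 - w) * stats.norm.pdf(x, mu_a, sd_a)
    return float(np.sum(np.log(np.maximum(dens, DENSITY_FLOOR))))


def _run_projected_em(x, init, sd_cn_bound, sd_ad_bound, tied, max_iter, tol):
    """Projected EM from one starting point; returns (params, trace).

    The SD projection (clip at its bound) is the exact constrained M-step
    maximiser — for a fixed mean the weighted objective is unimodal in the
    SD — so the observed-data log-likelihood trace is non-decreasing.  With
    ``tied`` the two components share one SD, bounded by the smaller of the
    two diagnostic-group bounds (which satisfies both component bounds).
    """
    mu_n, sd_n, mu_a, sd_a, w = init
    sd_min = 1e-6 * max(np.ptp(x), 1e-12)
    tied_bound = min(sd_cn_bound, sd_ad_bound)
    if tied:
        sd_n = sd_a = min(max(sd_n, sd_min), tied_bound)
    else:
        sd_n = min(max(sd_n, sd_min), sd_cn_bound)
        sd_a = min(max(sd_a, sd_min), sd_ad_bound)
    trace = [_mixture_loglik(x, w, mu_n, sd_n, mu_a, sd_a)]
    for _ in range(max_iter):
        # E-step
        dn = w * stats.norm.pdf(x, mu_n, sd_n)
        da = (1 - w) * stats.norm.pdf(x, mu_a, sd_a)
        tot = np.maximum(dn + da, DENSITY_FLOOR)
        r = dn / tot
        # M-step with SD projection at the diagnostic-group bounds
        wn = r.sum()
        wa = (1 - r).sum()
        if wn <= 0 or wa <= 0:
            raise FitError("a mixture component collapsed to zero weight")
        w = float(wn / len(x))
        mu_n = float(np.sum(r * x) / wn)
        mu_a = float(np.sum((1 - r) * x) / wa)
        if tied:
            pooled = float(
                np.sqrt((np.sum(r * (x - mu_n) ** 2) + np.sum((1 - r) * (x - mu_a) ** 2)) / len(x))
            )
            sd_n = sd_a = min(max(pooled, sd_min), tied_bound)
        else:
            sd_n = float(np.sqrt(np.sum(r * (x - mu_n) ** 2) / wn))
            sd_a = float(np.sqrt(np.sum((1 - r) * (x - mu_a) ** 2) / wa))
            sd_n = min(max(sd_n, sd_min), sd_cn_bound)
            sd_a = min(max(sd_a, sd_min), sd_ad_bound)
        trace.append(_mixture_loglik(x, w, mu_n, sd_n, mu_a, sd_a))
        if trace[-1] - trace[-2] < tol * max(1.0, abs(trace[-2])):
            break
    return (mu_n, sd_n, mu_a, sd_a, w), np.asarray(trace)


def fit_constrained_gmm(
    values,
    cn_mask,
    ad_mask,
    direction: str,
    biomarker_name: str = "",
    sd_structure: str = "tied",
    max_iter: int = 500,
    tol: float = 1e-9,
) -> EventDistribution:
    """Fit the SD-constrained two-component normal mixture to one biomarker.

    All subjects' values participate.  The normal component is initialised
    from the mean of the CN-labelled values and the abnormal component from
    the AD-labelled values, with the mixing weight starting at the CN
    fraction; projected EM then clips each SD at its diagnostic-group bound
    (``sd_normal <= SD(CN values)``, ``sd_abnormal <= SD(AD values)``) at
    every M-step.  The procedure is deterministic.

    ``sd_structure`` selects the variance model.  The default ``"tied"``
    shares one SD between the components, bounded by the smaller group SD —
    when the components overlap substantially, the unequal-variance mixture
    is only weakly identified and its likelihood is maximised by solutions
    that carve the data bulk with one narrow component, which satisfy the SD
    bounds yet misplace both means; tying the variances removes that
    degeneracy.  ``"free"`` fits separate SDs (appropriate for well-separated
    biomarkers), starting from both the group-anchored init and the tied
    solution and keeping the better constrained likelihood.

    Returns an :class:`EventDistribution` whose ``loglik_trace`` records the
    observed-data log-likelihood after each EM iteration of the winning run
    (non-decreasing).
    """
    x = np.asarray(values, dtype=float)
    cn_mask = np.asarray(cn_mask, dtype=bool)
    ad_mask = np.asarray(ad_mask, dtype=bool)
    if sd_structure not in ("tied", "free"):
        raise ValueError(f"sd_structure must be 'tied' or 'free', got {sd_structure!r}")
    if cn_mask.sum() < 2 or ad_mask.sum() < 2:
        raise FitError("need at least 2 CN-labelled and 2 AD-labelled values")
    if np.ptp(x) == 0:
        raise FitError("degenerate input: all biomarker values identical")
    sd_cn_bound = float(np.std(x[cn_mask], ddof=1))
    sd_ad_bound = float(np.std(x[ad_mask], ddof=1))
    if sd_cn_bound <= 0 or sd_ad_bound <= 0:
        raise FitError("constraint infeasible: a diagnostic group has zero spread")

    anchor = (
        float(np.mean(x[cn_mask])), sd_cn_bound,
        float(np.mean(x[ad_mask])), sd_ad_bound,
        float(cn_mask.mean()),
    )
    # Tail-anchored starts guard against the coincident-components optimum
    # when one component carries only a small fraction of the cohort (e.g.
    # the last event, abnormal only in late-stage patients).
    xs = np.sort(x)
    if direction == "decrease":
        xs = xs[::-1]  # most-normal values first
    third = max(len(xs) // 3, 2)
    tail = max(len(xs) // 7, 2)
    sd0 = min(sd_cn_bound, sd_ad_bound)
    tied_inits = [anchor]
    for lo, hi, w0 in (
        (xs[:third], xs[-third:], 0.5),
        (xs[:-tail], xs[-tail:], 1.0 - tail / len(xs)),
        (xs[:tail], xs[tail:], tail / len(xs)),
    ):
        tied_inits.append((float(np.mean(lo)), sd0, float(np.mean(hi)), sd0, w0))
    tied_params, tied_trace = None, None
    for init in tied_inits:
        params, trace = _run_projected_em(
            x, init, sd_cn_bound, sd_ad_bound, True, max_iter, tol
        )
        if tied_trace is None or trace[-1] > tied_trace[-1]:
            tied_params, tied_trace = params, trace
    if sd_structure == "tied":
        best_params, trace = tied_params, tied_trace
    else:
        best_params, trace = _run_projected_em(
            x, anchor, sd_cn_bound, sd_ad_bound, False, max_iter, tol
        )
        from_tied = _run_projected_em(
            x, tied_params, sd_cn_bound, sd_ad_bound, False, max_iter, tol
        )
        if from_tied[1][-1] > trace[-1]:
            best_params, trace = from_tied
    mu_n, sd_n, mu_a, sd_a, w = best_params

    # Resolve component identity by the declared abnormality direction.
    wrong_side = (direction == "increase" and mu_a < mu_n) or (
        direction == "decrease" and mu_a > mu_n
    )
    if wrong_side:
        mu_n, mu_a = mu_a, mu_n
        sd_n, sd_a = sd_a, sd_n
        w = 1.0 - w
        sd_n = min(sd_n, sd_cn_bound)
        sd_a = min(sd_a, sd_ad_bound)

    return EventDistribution(
        biomarker_name=biomarker_name,
        mu_normal=mu_n,
        sd_normal=sd_n,
        mu_abnormal=mu_a,
        sd_abnormal=sd_a,
        weight_normal=w,
        direction=direction,
        loglik_trace=np.asarray(trace),
    )


def fit_all_biomarkers(ds: BiomarkerDataset, **kwargs) -> DistributionSet:
    """Fit the constrained mixture for every biomarker in the dataset."""
    cn = ds.diagnosis_mask("CN")
    ad = ds.diagnosis_mask("AD")
    dists = [
        fit_constrained_gmm(
            ds.values[:, i], cn, ad, ds.direction[name], biomarker_name=name, **kwargs
        )
        for i, name in enumerate(ds.biomarker_names)
    ]
    return DistributionSet(dists)


def event_likelihoods(ds: BiomarkerDataset, dists: DistributionSet) -> LikelihoodTables:
    """Build the J x N density tables p(x|E) and p(x|not E).

    Mixing weights are deliberately not applied: the sequence likelihood
    conditions on whether each event has occurred, and the uniform stage
    prior takes the weight's place.
    """
    if set(dists.names) != set(ds.biomarker_names):
        raise SchemaError("DistributionSet does not cover the dataset's biomarkers")
    j, n = ds.values.shape
    le = np.empty((j, n))
    ln = np.empty((j, n))
    for i, name in enumerate(ds.biomarker_names):
        d = dists[name]
        le[:, i] = d.pdf_abnormal(ds.values[:, i])
        ln[:, i] = d.pdf_normal(ds.values[:, i])
    le = np.maximum(le, DENSITY_FLOOR)
    ln = np.maximum(ln, DENSITY_FLOOR)
    return LikelihoodTables(
        like_event=le,
        like_noevent=ln,
        log_like_event=np.log(le),
        log_like_noevent=np.log(ln),
        biomarker_names=list(ds.biomarker_names),
    )


@dataclass
class CutPoint:
    """Descriptive biomarker cut point with optional operating characteristics."""

    biomarker_name: str
    value: float
    sensitivity: float | None = None  # % of AD-labelled beyond the cut, abnormal side
    specificity: float | None = None  # % of CN-labelled on the normal side


def compute_cutpoint(dist: EventDistribution, cn_values=None, ad_values=None) -> CutPoint:
    """Value at which a measurement is equally likely normal or abnormal.

    Solves ``weight_normal * phi(x; mu_n, sd_n) =
    (1 - weight_normal) * phi(x; mu_a, sd_a)`` for x between the component
    means, i.e. the posterior probability of abnormality equals 0.5.  When
    labelled values are supplied, sensitivity is the percentage of AD-labelled
    values beyond the cut in the abnormal direction and specificity the
    percentage of CN-labelled values on the normal side.
    """
    if dist.mu_normal == dist.mu_abnormal and dist.sd_normal == dist.sd_abnormal:
        raise NumericalError("components identical: cut point undefined")

    def g(x):
        return (
            np.log(max(dist.weight_normal, 1e-300)) + dist.logpdf_normal(x)
            - np.log(max(1 - dist.weight_normal, 1e-300)) - dist.logpdf_abnormal(x)
        )

    lo, hi = sorted((dist.mu_normal, dist.mu_abnormal))
    if lo == hi or g(lo) * g(hi) > 0:
        raise NumericalError(
            "no posterior-0.5 crossing between the component means: "
            f"normal=({dist.mu_normal}, {dist.sd_normal}), "
            f"abnormal=({dist.mu_abnormal}, {dist.sd_abnormal}), "
            f"weight_normal={dist.weight_normal}"
        )
    xstar = float(optimize.brentq(g, lo, hi, xtol=1e-12))

    sens = spec = None
    sign = 1.0 if dist.direction == "increase" else -1.0
    if ad_values is not None:
        ad_values = np.asarray(ad_values, dtype=float)
        sens = float(100.0 * np.mean(sign * (ad_values - xstar) >= 0))
    if cn_values is not None:
        cn_values = np.asarray(cn_values, dtype=float)
        spec = float(100.0 * np.mean(sign * (cn_values - xstar) < 0))
    return CutPoint(dist.biomarker_name, xstar, sens, spec)
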