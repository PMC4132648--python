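"""Sequence likelihood, maximum-likelihood ordering, and MCMC posterior.

The model: disease progression is a single ordering S of N biomarker events.
A subject at stage k has experienced exactly the first k events of S.  With a
uniform prior over stages, the data likelihood of a sequence is

    L(S) = prod_j  (1/(N+1)) * sum_{k=0}^{N}
           prod_{i<=k} p(x_{s(i),j} | E) * prod_{i>k} p(x_{s(i),j} | not E)

Everything here works in the log domain: cumulative log-sums over positions
and a log-sum-exp over stages make one sequence evaluation O(J*N).

The posterior over orderings is summarised by the positional variance
matrix: entry (event, position) is the fraction of MCMC samples placing that
event at that position.  It is doubly stochastic by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .event_distributions import LikelihoodTables
from .exceptions import DataValidationError


@dataclass(frozen=True)
class EventSequence:
    """A permutation of the N event indices; ``order[i]`` occupies position i."""

    order: tuple

    def __post_init__(self):
        order = tuple(int(i) for i in self.order)
        object.__setattr__(self, "order", order)
        if sorted(order) != list(range(len(order))):
            raise DataValidationError(f"not a permutation of 0..{len(order) - 1}: {order}")

    def __len__(self):
        return len(self.order)

    def position_of(self, event: int) -> int:
        return self.order.index(event)

    def names(self, biomarker_names) -> list:
        return [biomarker_names[i] for i in self.order]


@dataclass
class SequencePosterior:
    """MCMC sample set over orderings with its positional variance summary."""

    samples: np.ndarray              # M x N int matrix of sampled orders
    log_likelihoods: np.ndarray      # M
    ml_sequence: EventSequence       # best sequence seen (incl. init)
    ml_log_likelihood: float
    positional_variance: np.ndarray  # N x N, row = event, column = position
    acceptance_rate: float
    seed: int

    def save(self, outdir, biomarker_names=None) -> None:
        """Serialize the posterior summary to a directory of text files."""
        import json

        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        n = len(self.ml_sequence)
        names = list(biomarker_names) if biomarker_names else [f"event_{i}" for i in range(n)]
        (outdir / "ml_sequence.json").write_text(
            json.dumps([names[i] for i in self.ml_sequence.order], indent=2)
        )
        pd.DataFrame(
            self.positional_variance,
            index=names,
            columns=[f"position_{p + 1}" for p in range(n)],
        ).to_csv(outdir / "positional_variance.csv")
        meta = {
            "seed": int(self.seed),
            "n_samples": int(self.samples.shape[0]),
            "acceptance_rate": float(self.acceptance_rate),
            "ml_log_likelihood": float(self.ml_log_likelihood),
        }
        (outdir / "run.json").write_text(json.dumps(meta, indent=2))


def _as_order(seq) -> np.ndarray:
    order = np.asarray(seq.order if isinstance(seq, EventSequence) else seq, dtype=int)
    if sorted(order.tolist()) != list(range(len(order))):
        raise DataValidationError("sequence is not a permutation")
    return order


def stage_log_joint(lt: LikelihoodTables, seq) -> np.ndarray:
    """J x (N+1) matrix of log p(x_j | stage k, S), excluding the stage prior.

    Column k holds ``sum_{i<=k} log p(x|E) + sum_{i>k} log p(x|not E)`` with
    biomarkers taken in sequence order.  This is the shared kernel of the
    sequence likelihood and of patient staging.
    """
    order = _as_order(seq)
    a = lt.log_like_event[:, order]
    b = lt.log_like_noevent[:, order]
    j = a.shape[0]
    zeros = np.zeros((j, 1))
    ca = np.concatenate([zeros, np.cumsum(a, axis=1)], axis=1)
    cb = np.concatenate([zeros, np.cumsum(b, axis=1)], axis=1)
    return ca + (cb[:, -1:] - cb)


def log_likelihood_sequence(lt: LikelihoodTables, seq) -> float:
    """Log data likelihood of an event ordering under the uniform stage prior."""
    joint = stage_log_joint(lt, seq)
    n = lt.n_events
    return float(np.sum(logsumexp(joint, axis=1)) - lt.n_subjects * np.log(n + 1))


def _batch_log_likelihood(lt: LikelihoodTables, orders: np.ndarray) -> np.ndarray:
    """Sequence log-likelihood for S orders at once (S x N int array)."""
    a = lt.log_like_event[:, orders]       # J x S x N
    b = lt.log_like_noevent[:, orders]
    j, s, n = a.shape
    zeros = np.zeros((j, s, 1))
    ca = np.concatenate([zeros, np.cumsum(a, axis=2)], axis=2)
    cb = np.concatenate([zeros, np.cumsum(b, axis=2)], axis=2)
    joint = ca + (cb[:, :, -1:] - cb)
    return logsumexp(joint, axis=2).sum(axis=0) - j * np.log(n + 1)


def _swap_pairs(n: int):
    return [(i, k) for i in range(n) for k in range(i + 1, n)]


def most_likely_sequence(lt: LikelihoodTables, n_starts: int = 10, seed: int = 0) -> EventSequence:
    """Multi-start greedy ascent over pairwise swaps.

    From each random initial permutation, all N(N-1)/2 transpositions are
    evaluated; the best strictly-improving one is applied (lexicographically
    first pair on ties) until a local optimum is reached.  The best local
    optimum across starts is returned.  Deterministic given ``seed``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    n = lt.n_events
    rng = np.random.default_rng(seed)
    pairs = _swap_pairs(n)
    best_order, best_ll = None, -np.inf
    any_improved = False
    for _ in range(n_starts):
        order = rng.permutation(n)
        cur_ll = float(_batch_log_likelihood(lt, order[None, :])[0])
        while True:
            cand = np.tile(order, (len(pairs), 1))
            for r, (i, k) in enumerate(pairs):
                cand[r, i], cand[r, k] = cand[r, k], cand[r, i]
            lls = _batch_log_likelihood(lt, cand)
            r = int(np.argmax(lls))
            if lls[r] > cur_ll:
                order, cur_ll = cand[r], float(lls[r])
                any_improved = True
            else:
                break
        if cur_ll > best_ll:
            best_order, best_ll = order, cur_ll
    if not any_improved:
        warnings.warn(
            "fully degenerate likelihood tables: no pairwise swap changed the "
            "likelihood from any start; the returned ordering is arbitrary",
            stacklevel=2,
        )
    return EventSequence(tuple(int(i) for i in best_order))


def positional_variance_from_samples(samples: np.ndarray, n_events: int) -> np.ndarray:
    """Event x position frequency matrix from an M x N array of sampled orders."""
    pv = np.zeros((n_events, n_events))
    for pos in range(n_events):
        counts = np.bincount(samples[:, pos], minlength=n_events)
        pv[:, pos] = counts / samples.shape[0]
    return pv


def mcmc_sample(
    lt: LikelihoodTables,
    init,
    n_samples: int,
    burn_in: int = 0,
    seed: int = 0,
) -> SequencePosterior:
    """Metropolis sampling over orderings with a random-transposition proposal.

    The proposal (swap two uniformly chosen positions) is symmetric, so a move
    is accepted with probability ``min(1, exp(delta log-likelihood))``.
    Post-burn-in samples are retained; the positional variance matrix is the
    per-position event frequency over those samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    order = _as_order(init).copy()
    n = lt.n_events
    rng = np.random.default_rng(seed)
    cur_ll = log_likelihood_sequence(lt, order)
    ml_order, ml_ll = order.copy(), cur_ll

    total = burn_in + n_samples
    samples = np.empty((n_samples, n), dtype=int)
    lls = np.empty(n_samples)
    n_accept = 0
    # Pre-draw proposal indices and uniforms for speed.
    ii = rng.integers(0, n, size=total)
    kk = rng.integers(0, n - 1, size=total)
    kk = np.where(kk >= ii, kk + 1, kk)
    log_u = np.log(rng.random(size=total))
    for t in range(total):
        i, k = ii[t], kk[t]
        prop = order.copy()
        prop[i], prop[k] = prop[k], prop[i]
        prop_ll = log_likelihood_sequence(lt, prop)
        if log_u[t] < prop_ll - cur_ll:
            order, cur_ll = prop, prop_ll
            n_accept += 1
            if cur_ll > ml_ll:
                ml_order, ml_ll = order.copy(), cur_ll
        if t >= burn_in:
            samples[t - burn_in] = order
            lls[t - burn_in] = cur_ll

    if n_accept == 0:
        warnings.warn("MCMC accepted no proposals over the entire run", stacklevel=2)
    return SequencePosterior(
        samples=samples,
        log_likelihoods=lls,
        ml_sequence=EventSequence(tuple(int(i) for i in ml_order)),
        ml_log_likelihood=float(ml_ll),
        positional_variance=positional_variance_from_samples(samples, n),
        acceptance_rate=n_accept / total,
        seed=int(seed),
    )


def exhaustive_ml_sequence(lt: LikelihoodTables):
    """Exact argmax over all N! orderings (oracle-scale N only)."""
    best, best_ll = None, -np.inf
    for perm in permutations(range(lt.n_events)):
        ll = log_likelihood_sequence(lt, np.asarray(perm))
        if ll > best_ll:
            best, best_ll = perm, ll
    return EventSequence(best), best_ll


def plot_positional_variance(pv, biomarker_names, ml_sequence: EventSequence, path=None):
    """Greyscale positional variance diagram (0 -> white, 1 -> black).

    Rows are displayed in maximum-likelihood order, top to bottom.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = list(ml_sequence.order)
    mat = np.asarray(pv)[order, :]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(mat, cmap="Greys", vmin=0, vmax=1, aspect="auto")
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([biomarker_names[i] for i in order])
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels([str(p + 1) for p in range(len(order))])
    ax.set_xlabel("sequence position")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
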