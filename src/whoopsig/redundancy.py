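"""Serial-redundancy analysis: evidence accumulation over whoop bouts.

A receiver hearing a bout can pool evidence across successive calls. Here
the per-call evidence is the random forest's tree-vote fraction vector; the
aggregated "probability" that the bout belongs to each caller after k calls
is the mean of the first k vote vectors (equivalently, pooled tree votes).
The empirical accumulation curve is compared against two baselines:

* chance — a flat line at the weighted expectation (WE);
* equal informativeness — each call is an independent categorical observation
  that is correct with probability p and uniformly wrong otherwise; after k
  calls the receiver takes the plurality class (the Bayesian MAP class under
  this symmetric likelihood), with fractional credit on ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial
from typing import Optional

import numpy as np
import pandas as pd

from .classify import CVSummary, SplitSpec, run_repeats, drop_failed

__all__ = [
    "PrefixCurve",
    "bout_prefix_probabilities",
    "prefix_accuracy_curve",
    "equal_informative_baseline",
    "chance_baseline",
    "RedundancyGateError",
]


class RedundancyGateError(RuntimeError):
    """Raised when single-whoop accuracy does not beat chance: accumulating
    uninformative evidence is not meaningful, so the analysis refuses to run."""


@dataclass
class PrefixCurve:
    """Mean probability on the true caller after k whoops (k = 1..k_max)."""

    k: np.ndarray            # prefix lengths
    mean_prob: np.ndarray    # mean vote mass on the true caller
    n_bouts: np.ndarray      # contributing (repeat, bout) instances per k
    mean_accuracy: float     # single-whoop argmax accuracy of the models
    mean_we: float
    #: optional argmax-accuracy variant of the curve
    mean_argmax: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        d = {"k": self.k, "mean_prob": self.mean_prob, "n_bouts": self.n_bouts}
        if self.mean_argmax is not None:
            d["mean_argmax"] = self.mean_argmax
        return pd.DataFrame(d)


def bout_prefix_probabilities(votes: np.ndarray) -> np.ndarray:
    """Prefix-aggregated class probabilities for one bout.

    ``votes``: [n_whoops, n_classes] per-whoop tree-vote fractions in natural
    bout order. Row k-1 of the result is the mean of the first k rows; each
    row sums to 1.
    """
    v = np.asarray(votes, dtype=float)
    if v.ndim != 2 or v.shape[0] == 0:
        raise ValueError("empty bout")
    return np.cumsum(v, axis=0) / np.arange(1, v.shape[0] + 1)[:, None]


def prefix_accuracy_curve(
    table: pd.DataFrame,
    spec: SplitSpec,
    target: str = "caller_id",
    k_max: Optional[int] = None,
    summary: Optional[CVSummary] = None,
) -> PrefixCurve:
    """Average evidence-accumulation curve over repeats and test bouts.

    Runs (or reuses) individual-scheme repeats with per-bout vote collection;
    curve(k) is the mean, over all model repeats and test bouts of length
    >= k, of the aggregated vote mass on the true caller after the first k
    whoops in natural order. Only computed when mean single-whoop accuracy
    exceeds mean WE (otherwise :class:`RedundancyGateError`).
    """
    if spec.scheme != "individual":
        raise ValueError("redundancy analysis uses the individual scheme")
    if summary is None:
        summary = run_repeats(drop_failed(table), spec, target, collect_votes=True)
    if summary.repeats is None or not any(r.bout_votes for r in summary.repeats):
        raise ValueError("summary must carry collected bout votes")
    if summary.mean_accuracy <= summary.mean_we:
        raise RedundancyGateError(
            f"mean single-whoop accuracy {summary.mean_accuracy:.3f} does not "
            f"exceed chance (WE {summary.mean_we:.3f}); redundancy analysis "
            "is not meaningful"
        )
    longest = max(
        v.shape[0] for r in summary.repeats for (_, v) in r.bout_votes.values()
    )
    k_max = longest if k_max is None else min(k_max, longest)
    sums = np.zeros(k_max)
    arg_sums = np.zeros(k_max)
    counts = np.zeros(k_max, dtype=int)
    for rep in summary.repeats:
        classes = rep.classes
        for bout, (true_caller, votes) in rep.bout_votes.items():
            prefix = bout_prefix_probabilities(votes)
            ci = int(np.flatnonzero(classes == true_caller)[0])
            n = min(prefix.shape[0], k_max)
            sums[:n] += prefix[:n, ci]
            arg_sums[:n] += (np.argmax(prefix[:n], axis=1) == ci)
            counts[:n] += 1
    if counts[0] == 0:
        raise ValueError("no qualifying bouts")
    valid = counts > 0
    return PrefixCurve(
        k=np.arange(1, k_max + 1)[valid],
        mean_prob=sums[valid] / counts[valid],
        n_bouts=counts[valid],
        mean_accuracy=summary.mean_accuracy,
        mean_we=summary.mean_we,
        mean_argmax=arg_sums[valid] / counts[valid],
    )


# ------------------------------------------------------------ baselines

def _partitions(m: int, max_parts: int):
    """Yield integer partitions of m into at most max_parts positive parts,
    as non-increasing tuples (the empty tuple for m == 0)."""

    def rec(remaining, largest, parts_left, prefix):
        if remaining == 0:
            yield tuple(prefix)
            return
        if parts_left == 0:
            return
        for part in range(min(remaining, largest), 0, -1):
            prefix.append(part)
            yield from rec(remaining - part, part, parts_left - 1, prefix)
            prefix.pop()

    yield from rec(m, m if m else 1, max_parts, [])


def _exact_plurality_correct(k: int, p: float, K: int) -> float:
    """P(plurality decision is correct) after k symmetric categorical votes.

    The true class receives c ~ Binomial(k, p) votes; the remaining m = k - c
    votes fall uniformly on the K-1 wrong classes. The decision takes the
    class with most votes, awarding 1/|tied set| credit on ties. Exact by
    enumeration over integer partitions of the wrong-vote counts.
    """
    q = 1.0 - p
    total = 0.0
    for c in range(k + 1):
        m = k - c
        pc = comb(k, c) * (p**c) * (q**m) if q > 0 else (1.0 if c == k else 0.0)
        if pc == 0.0:
            continue
        if m == 0:
            total += pc  # all votes correct: c = k > 0
            continue
        credit = 0.0
        for parts in _partitions(m, K - 1):
            # multinomial ways to order the m wrong votes into these counts
            ways_votes = factorial(m)
            for part in parts:
                ways_votes //= factorial(part)
            # ways to choose which wrong classes carry the parts
            mult: dict[int, int] = {}
            for part in parts:
                mult[part] = mult.get(part, 0) + 1
            ways_classes = 1
            remaining = K - 1
            for v in mult.values():
                ways_classes *= comb(remaining, v)
                remaining -= v
            prob = ways_votes * ways_classes * (1.0 / (K - 1)) ** m
            mx = parts[0]
            if c > mx:
                credit += prob
            elif c == mx:
                ties = mult[mx] + 1  # wrong classes at the max, plus the true class
                credit += prob / ties
        total += pc * credit
    return total


def equal_informative_baseline(
    p: float,
    K: int,
    k_max: int,
    method: str = "exact",
    seed: int = 0,
    n_sim: int = 100_000,
) -> np.ndarray:
    """Expected plurality accuracy after k = 1..k_max equally informative,
    independent calls (correct w.p. p, each wrong class w.p. (1-p)/(K-1)).

    ``exact`` enumerates vote-count compositions; ``monte_carlo`` simulates
    ``n_sim`` bouts per k (seeded). Ties award fractional credit.
    """
    if K < 2:
        raise ValueError("need K >= 2 classes")
    if not (1.0 / K <= p <= 1.0):
        raise ValueError(f"p={p} outside [1/K, 1]")
    if method == "exact":
        return np.array([_exact_plurality_correct(k, p, K) for k in range(1, k_max + 1)])
    if method != "monte_carlo":
        raise ValueError("method must be 'exact' or 'monte_carlo'")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBA7E5]))
    pvec = np.full(K, (1.0 - p) / (K - 1))
    pvec[0] = p
    out = np.empty(k_max)
    for i, k in enumerate(range(1, k_max + 1)):
        counts = rng.multinomial(k, pvec, size=n_sim)
        c = counts[:, 0]
        wrong = counts[:, 1:]
        mx = wrong.max(axis=1)
        ties = (wrong == mx[:, None]).sum(axis=1)
        credit = np.where(c > mx, 1.0, np.where(c == mx, 1.0 / (ties + 1.0), 0.0))
        out[i] = credit.mean()
    return out


def chance_baseline(we: float, k_max: int) -> np.ndarray:
    """Flat chance line: uninformative whoops never improve with k."""
    if not (0.0 <= we <= 1.0):
        raise ValueError("we must lie in [0, 1]")
    return np.full(k_max, float(we))
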