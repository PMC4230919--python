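"""Cumulative detection probability for rare non-target taxa in clone libraries.

A clone library of ``n`` Sanger-sequenced clones drawn from an egg capsule
detects a non-target (contaminant) taxon of per-capsule incidence ``q`` with
cumulative probability

    P = 1 - (1 - q)^n

assuming clones are independent draws with equal incidence across capsules
and no amplification bias.  Solving for ``q`` gives the largest incidence a
survey of ``n`` clones could have failed to detect at confidence ``P``:

    q_max = 1 - (1 - P)^(1/n)

The module provides the forward model, both inversions, the geometric
expected waiting time to a first detection, the per-host/pooled incidence
table, and a Monte Carlo simulator used as an independent oracle.

All forms are computed through ``log1p``/``expm1`` so small incidences and
large clone counts do not underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .util import round_half_away

__all__ = [
    "DetectionModel",
    "IncidenceTable",
    "detection_probability",
    "max_incidence",
    "required_clones",
    "expected_clones_to_detection",
    "incidence_table",
    "mc_detection_probability",
    "estimate_incidence",
]

#: Statement of the sampling assumptions under which pooling clone counts
#: across hosts and capsules into a single n is valid.
IID_ASSUMPTION = (
    "Clones are treated as independent draws with equal non-target incidence "
    "across all capsules and hosts, and amplification is assumed unbiased; "
    "pooled rows use n = sum of per-host clone counts."
)


def _check_q(q: float) -> None:
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"incidence q must be in [0, 1], got {q}")


def _check_n(n: int) -> None:
    if int(n) != n or n < 1:
        raise ValueError(f"clone count n must be a positive integer, got {n}")


def _check_P(P: float) -> None:
    if not 0.0 < P < 1.0:
        raise ValueError(f"detection probability P must be in (0, 1), got {P}")


def detection_probability(q: float, n: int) -> float:
    """P = 1 - (1-q)^n: probability of >=1 non-target clone among n."""
    _check_q(q)
    _check_n(n)
    if q == 0.0:
        return 0.0
    if q == 1.0:
        return 1.0
    return -math.expm1(n * math.log1p(-q))


def max_incidence(P: float, n: int) -> float:
    """q = 1 - (1-P)^(1/n): largest incidence compatible with zero detections at confidence P."""
    _check_P(P)
    _check_n(n)
    return -math.expm1(math.log1p(-P) / n)


def required_clones(P: float, q: float) -> int:
    """Smallest n with detection_probability(q, n) >= P."""
    _check_P(P)
    _check_q(q)
    if q == 0.0:
        raise ValueError("q = 0: the target probability is unreachable")
    if q == 1.0:
        return 1
    n = max(1, math.ceil(math.log1p(-P) / math.log1p(-q)))
    # guard against floating-point boundary slips in the ceil
    while detection_probability(q, n) < P:
        n += 1
    while n > 1 and detection_probability(q, n - 1) >= P:
        n -= 1
    return n


def expected_clones_to_detection(q: float) -> float:
    """Mean number of clones sequenced until the first non-target clone (geometric: 1/q)."""
    _check_q(q)
    if q == 0.0:
        raise ValueError("q = 0: detection never occurs")
    return 1.0 / q


@dataclass
class DetectionModel:
    """The (P, q, n) triple bound by P = 1 - (1-q)^n; solve() fills the missing field."""

    P: float | None = None
    q: float | None = None
    n: int | None = None

    def solve(self) -> "DetectionModel":
        given = sum(v is not None for v in (self.P, self.q, self.n))
        if given != 2:
            raise ValueError("exactly two of (P, q, n) must be set")
        if self.P is None:
            return DetectionModel(P=detection_probability(self.q, self.n), q=self.q, n=self.n)
        if self.q is None:
            return DetectionModel(P=self.P, q=max_incidence(self.P, self.n), n=self.n)
        return DetectionModel(P=self.P, q=self.q, n=required_clones(self.P, self.q))


@dataclass
class IncidenceTable:
    """Per-host and pooled maximum undetected incidence at threshold P."""

    threshold: float
    hosts: list[tuple[str, int, float]]  # (host, n, q_max raw)
    pooled_n: int
    pooled_q_max: float
    assumption: str = IID_ASSUMPTION
    ndigits: int = 3

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "host": host,
                "n": n,
                "q_max": round_half_away(q, self.ndigits),
                "q_max_raw": q,
            }
            for host, n, q in self.hosts
        ]
        rows.append(
            {
                "host": "combined",
                "n": self.pooled_n,
                "q_max": round_half_away(self.pooled_q_max, self.ndigits),
                "q_max_raw": self.pooled_q_max,
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "threshold_P": self.threshold,
            "assumption": self.assumption,
            "hosts": [
                {"host": h, "n": n, "q_max_raw": q, "q_max": round_half_away(q, self.ndigits)}
                for h, n, q in self.hosts
            ],
            "combined": {
                "n": self.pooled_n,
                "q_max_raw": self.pooled_q_max,
                "q_max": round_half_away(self.pooled_q_max, self.ndigits),
            },
        }

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def incidence_table(per_host_n: Mapping[str, int], P: float) -> IncidenceTable:
    """Maximum undetected incidence per host plus the pooled (summed-n) row."""
    _check_P(P)
    if not per_host_n:
        raise ValueError("per_host_n is empty")
    hosts = []
    for host, n in per_host_n.items():
        _check_n(n)
        hosts.append((host, int(n), max_incidence(P, int(n))))
    pooled_n = sum(n for _, n, _ in hosts)
    return IncidenceTable(
        threshold=P,
        hosts=hosts,
        pooled_n=pooled_n,
        pooled_q_max=max_incidence(P, pooled_n),
    )


class MCDetectionResult(NamedTuple):
    estimate: float
    std_error: float
    reps: int


def mc_detection_probability(
    q: float, n: int, reps: int = 100_000, seed: int | None = None
) -> MCDetectionResult:
    """Monte Carlo estimate of the detection probability (independent oracle).

    Simulates ``reps`` libraries of ``n`` Bernoulli(q) clones and reports the
    fraction containing at least one non-target clone, with its binomial
    standard error.  ``reps`` below 1000 is refused: the estimate would be
    too noisy to serve as a check on the closed form.
    """
    _check_q(q)
    _check_n(n)
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a usable oracle")
    rng = np.random.default_rng(seed)
    detected = 0
    chunk = max(1, int(4_000_000 // n))
    done = 0
    while done < reps:
        r = min(chunk, reps - done)
        draws = rng.random((r, n)) < q
        detected += int(draws.any(axis=1).sum())
        done += r
    est = detected / reps
    se = math.sqrt(est * (1.0 - est) / reps)
    return MCDetectionResult(estimate=est, std_error=se, reps=reps)


def estimate_incidence(
    non_target: int, total: int, conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Point estimate and Clopper–Pearson interval for the non-target incidence.

    ``non_target`` is the observed non-target clone count among ``total``
    pooled clones.
    """
    if total < 1 or not 0 <= non_target <= total:
        raise ValueError("need 0 <= non_target <= total, total >= 1")
    alpha = 1.0 - conf
    lo = 0.0 if non_target == 0 else float(
        stats.beta.ppf(alpha / 2, non_target, total - non_target + 1)
    )
    hi = 1.0 if non_target == total else float(
        stats.beta.ppf(1 - alpha / 2, non_target + 1, total - non_target)
    )
    return non_target / total, (lo, hi)
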