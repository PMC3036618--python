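"""Expected screen-level error counts for libraries with multiple RNAi reagents per gene.

A screening library carries ``k`` independently tested reagents per gene.  Each
reagent behaves as an independent Bernoulli trial: on a true-hit gene it fails
to score with probability ``r_fn`` (an ineffective or weak reagent), on a
non-hit gene it scores with probability ``r_fp`` (an off-target-driven false
positive).  A gene is called a hit when at least ``m`` of its ``k`` reagents
score; the classical disambiguation rules are special cases of this m-of-k
vote:

* lenient   — any reagent scoring calls the gene (m = 1),
* stringent — every reagent must score (m = k),
* majority  — more than half must score (m = floor(k/2) + 1).

Under reagent independence the expected numbers of missed true hits and of
spuriously called non-hits are binomial tail probabilities scaled by the
number of true-hit genes ``H`` and non-hit genes ``N``:

    E[FN] = P(Binomial(k, 1 - r_fn) < m) * H
    E[FP] = P(Binomial(k, r_fp) >= m) * N

For k <= 3 these tails expand into short polynomials in r_fn / r_fp;
:func:`mofk_polynomial` evaluates those expansions literally and serves as an
independent cross-check of the binomial form.  :func:`simulate_disambiguation`
verifies both by Monte-Carlo at the reagent level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ErrorRates",
    "LibraryScenario",
    "DisambiguationRule",
    "ExpectedOutcome",
    "SimulationSummary",
    "expected_error_counts",
    "mofk_polynomial",
    "simulate_disambiguation",
    "rule_frontier",
]


@dataclass(frozen=True)
class ErrorRates:
    """Per-reagent error probabilities.

    r_fn : probability that a reagent targeting a true-hit gene fails to score.
    r_fp : probability that a reagent targeting a non-hit gene scores.
    """

    r_fn: float
    r_fp: float

    def __post_init__(self) -> None:
        for name in ("r_fn", "r_fp"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class LibraryScenario:
    """Library composition: H true-hit genes, N non-hit genes, k reagents per gene."""

    h_true_hits: int
    n_non_hits: int
    k_reagents: int

    def __post_init__(self) -> None:
        if self.h_true_hits < 0 or self.n_non_hits < 0:
            raise ValueError("gene counts must be non-negative")
        if self.k_reagents < 1:
            raise ValueError("k_reagents must be >= 1")


@dataclass(frozen=True)
class DisambiguationRule:
    """An m-of-k gene-call rule: a gene is a hit when >= m of its k reagents score."""

    name: str
    m: int

    _NAMED = ("lenient", "stringent", "majority", "m_of_k")

    def __post_init__(self) -> None:
        if self.name not in self._NAMED:
            raise ValueError(f"unknown rule name {self.name!r}")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @classmethod
    def lenient(cls) -> "DisambiguationRule":
        return cls("lenient", 1)

    @classmethod
    def stringent(cls, k: int) -> "DisambiguationRule":
        return cls("stringent", k)

    @classmethod
    def majority(cls, k: int) -> "DisambiguationRule":
        return cls("majority", k // 2 + 1)

    @classmethod
    def m_of_k(cls, m: int) -> "DisambiguationRule":
        return cls("m_of_k", m)

    @classmethod
    def from_name(cls, name: str, k: int) -> "DisambiguationRule":
        if name == "lenient":
            return cls.lenient()
        if name == "stringent":
            return cls.stringent(k)
        if name == "majority":
            return cls.majority(k)
        raise ValueError(f"unknown rule name {name!r}")

    def validate_for(self, k: int) -> None:
        if not 1 <= self.m <= k:
            raise ValueError(f"rule requires 1 <= m <= k; got m={self.m}, k={k}")
        if self.name == "stringent" and self.m != k:
            raise ValueError("stringent rule requires m == k")
        if self.name == "majority" and self.m != k // 2 + 1:
            raise ValueError("majority rule requires m == floor(k/2) + 1")
        if self.name == "lenient" and self.m != 1:
            raise ValueError("lenient rule requires m == 1")


@dataclass(frozen=True)
class ExpectedOutcome:
    """Expected counts of missed true hits and spurious non-hit calls."""

    expected_fn: float
    expected_fp: float


@dataclass(frozen=True)
class SimulationSummary:
    mean_fn: float
    mean_fp: float
    se_fn: float
    se_fp: float
    n_reps: int


def expected_error_counts(
    rates: ErrorRates, scenario: LibraryScenario, rule: DisambiguationRule
) -> ExpectedOutcome:
    """Closed-form expected FN/FP gene counts under an m-of-k call rule.

    A true-hit gene is missed when fewer than m of its k reagents score, each
    scoring independently with probability 1 - r_fn; a non-hit gene is called
    when at least m reagents score, each with probability r_fp.
    """
    k, m = scenario.k_reagents, rule.m
    rule.validate_for(k)
    p_miss = stats.binom.cdf(m - 1, k, 1.0 - rates.r_fn)
    p_spurious = stats.binom.sf(m - 1, k, rates.r_fp)
    return ExpectedOutcome(
        expected_fn=float(p_miss) * scenario.h_true_hits,
        expected_fp=float(p_spurious) * scenario.n_non_hits,
    )


# Literal polynomial expansions of the m-of-k binomial tails for k <= 3,
# keyed by (rule name, k, which).  R is r_fn for "fn" and r_fp for "fp".
_POLYNOMIALS = {
    ("lenient", 1, "fn"): lambda r: r,
    ("lenient", 2, "fn"): lambda r: r**2,
    ("lenient", 3, "fn"): lambda r: r**3,
    ("lenient", 1, "fp"): lambda r: r,
    ("lenient", 2, "fp"): lambda r: r * 2 - r**2,
    ("lenient", 3, "fp"): lambda r: r * 3 - r**2 * 3 + r**3,
    ("stringent", 1, "fn"): lambda r: r,
    ("stringent", 2, "fn"): lambda r: r * 2 - r**2,
    ("stringent", 3, "fn"): lambda r: r * 3 - r**2 * 3 + r**3,
    ("stringent", 1, "fp"): lambda r: r,
    ("stringent", 2, "fp"): lambda r: r**2,
    ("stringent", 3, "fp"): lambda r: r**3,
    ("majority", 1, "fn"): lambda r: r,
    ("majority", 2, "fn"): lambda r: r * 2 - r**2,
    ("majority", 3, "fn"): lambda r: r**2 * 3 - r**3 * 2,
    ("majority", 1, "fp"): lambda r: r,
    ("majority", 2, "fp"): lambda r: r**2,
    ("majority", 3, "fp"): lambda r: r**2 * 3 - r**3 * 2,
}


def mofk_polynomial(
    rates: ErrorRates, k: int, rule: DisambiguationRule, which: str
) -> float:
    """Evaluate the printed k<=3 polynomial for a rule, as a probability factor.

    Serves as an oracle for :func:`expected_error_counts`: multiplying by H
    (for ``which="fn"``) or N (for ``which="fp"``) gives the expected count.
    """
    if k > 3:
        raise ValueError("polynomial expansions are tabulated for k <= 3 only")
    if which not in ("fn", "fp"):
        raise ValueError("which must be 'fn' or 'fp'")
    rule.validate_for(k)
    name = rule.name
    if name == "m_of_k":
        # map an explicit m back onto the named rule it coincides with
        if rule.m == 1:
            name = "lenient"
        elif rule.m == k:
            name = "stringent"
        elif rule.m == k // 2 + 1:
            name = "majority"
        else:
            raise ValueError(f"no tabulated polynomial for m={rule.m} of k={k}")
    r = rates.r_fn if which == "fn" else rates.r_fp
    return float(_POLYNOMIALS[(name, k, which)](r))


def simulate_disambiguation(
    rates: ErrorRates,
    scenario: LibraryScenario,
    rule: DisambiguationRule,
    n_reps: int,
    seed: int | np.random.Generator = 0,
    _chunk: int = 256,
) -> SimulationSummary:
    """Monte-Carlo verification of the closed form at the reagent level.

    Per replicate, every reagent's score is an independent Bernoulli draw
    (success probability 1 - r_fn on hit genes, r_fp on non-hit genes); genes
    are called by the m-of-k rule and the FN/FP gene counts recorded.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    k, m = scenario.k_reagents, rule.m
    rule.validate_for(k)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    fn_counts = np.empty(n_reps, dtype=np.int64)
    fp_counts = np.empty(n_reps, dtype=np.int64)
    h, n = scenario.h_true_hits, scenario.n_non_hits
    for start in range(0, n_reps, _chunk):
        reps = min(_chunk, n_reps - start)
        scoring_h = (
            rng.random((reps, h, k)) < (1.0 - rates.r_fn)
            if h
            else np.zeros((reps, 0, k), bool)
        )
        scoring_n = (
            rng.random((reps, n, k)) < rates.r_fp if n else np.zeros((reps, 0, k), bool)
        )
        fn_counts[start : start + reps] = (scoring_h.sum(axis=2) < m).sum(axis=1)
        fp_counts[start : start + reps] = (scoring_n.sum(axis=2) >= m).sum(axis=1)

    return SimulationSummary(
        mean_fn=float(fn_counts.mean()),
        mean_fp=float(fp_counts.mean()),
        se_fn=float(fn_counts.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else 0.0,
        se_fp=float(fp_counts.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else 0.0,
        n_reps=n_reps,
    )


def rule_frontier(
    rates: ErrorRates, scenario: LibraryScenario, k_max: int
) -> list[dict]:
    """Enumerate every m-of-k rule for k <= k_max with its expected error counts.

    Returns one record per (k, m) with keys ``k``, ``m``, ``rule_names``,
    ``expected_fn``, ``expected_fp`` and ``best`` flagging the rule that
    minimises expected_fn + expected_fp.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    rows: list[dict] = []
    for k in range(1, k_max + 1):
        sub = LibraryScenario(scenario.h_true_hits, scenario.n_non_hits, k)
        for m in range(1, k + 1):
            rule = DisambiguationRule.m_of_k(m)
            out = expected_error_counts(rates, sub, rule)
            names = [
                nm
                for nm in ("lenient", "stringent", "majority")
                if DisambiguationRule.from_name(nm, k).m == m
            ]
            rows.append(
                {
                    "k": k,
                    "m": m,
                    "rule_names": names,
                    "expected_fn": out.expected_fn,
                    "expected_fp": out.expected_fp,
                    "total": out.expected_fn + out.expected_fp,
                    "best": False,
                }
            )
    best = min(range(len(rows)), key=lambda i: rows[i]["total"])
    rows[best]["best"] = True
    return rows
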