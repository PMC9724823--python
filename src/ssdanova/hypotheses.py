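"""Informative hypotheses on group means as linear constraint sets.

A hypothesis on the means ``mu1 .. muK`` of K independent groups is written
as a chain such as ``"mu1=mu2=mu3"`` (null), ``"mu3>mu2>mu1"`` (full
ordering), or a mixed chain like ``"mu1>mu2=mu3"``.  Two sentinels are
recognised: ``"Ha"``, the unconstrained alternative, and ``"Hc"``, the
complement of the hypothesis it is compared against.

Each relation in a chain becomes one pairwise contrast row over the K means:
``mu_a = mu_b`` becomes an equality row with ``R @ mu == 0`` and
``mu_a > mu_b`` an inequality row with ``R @ mu > 0``.  The number of
independent constraints J of a comparison — which sets the fraction of the
data's information spent on the prior — is the rank of all constraint rows
of both hypotheses stacked.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = ["Hypothesis", "ComparisonPair", "parse_hypothesis", "build_pair", "render"]

_TOKEN_RE = re.compile(r"mu(\d+)|([=<>])|(\S)")


class HypothesisParseError(ValueError):
    """Raised when a hypothesis string cannot be interpreted."""


@dataclass(frozen=True)
class Hypothesis:
    """A parsed hypothesis over K group means.

    ``kind`` is ``"constrained"`` for explicit chains, ``"unconstrained_Ha"``
    for the alternative, ``"complement_Hc"`` for the complement sentinel.
    ``levels`` records the chain structure for constrained hypotheses: group
    indices (0-based) from largest to smallest, groups tied by ``=`` sharing
    a level.  It is what population construction needs to place means.
    """

    label: str
    kind: str
    K: int
    equality_rows: tuple[tuple[int, ...], ...] = ()
    inequality_rows: tuple[tuple[int, ...], ...] = ()
    levels: tuple[tuple[int, ...], ...] | None = None

    @property
    def is_constrained(self) -> bool:
        return self.kind == "constrained"

    @property
    def has_equalities(self) -> bool:
        return len(self.equality_rows) > 0

    @property
    def has_inequalities(self) -> bool:
        return len(self.inequality_rows) > 0

    def equality_matrix(self) -> np.ndarray:
        return np.array(self.equality_rows, dtype=float).reshape(len(self.equality_rows), self.K)

    def inequality_matrix(self) -> np.ndarray:
        return np.array(self.inequality_rows, dtype=float).reshape(len(self.inequality_rows), self.K)

    def satisfied_by(self, means) -> bool:
        """Whether a mean vector lies in the hypothesis' region (Ha: always)."""
        m = np.asarray(means, dtype=float)
        if self.kind == "unconstrained_Ha":
            return True
        if self.kind == "complement_Hc":
            raise ValueError("Hc has no region of its own; test against the paired hypothesis")
        ok = True
        if self.has_equalities:
            ok &= bool(np.allclose(self.equality_matrix() @ m, 0.0))
        if self.has_inequalities:
            ok &= bool(np.all(self.inequality_matrix() @ m > 0.0))
        return ok


@dataclass(frozen=True)
class ComparisonPair:
    """Two hypotheses under comparison, with the derived situation and J.

    Situations: 1 = constrained vs unconstrained Ha; 2 = equality-only vs a
    hypothesis with inequality constraints; 3 = inequality-constrained vs its
    complement Hc; 4 = two constrained hypotheses.
    """

    hyp1: Hypothesis
    hyp2: Hypothesis
    situation: int
    J: int

    @property
    def K(self) -> int:
        return self.hyp1.K

    @property
    def has_equalities(self) -> bool:
        return self.hyp1.has_equalities or self.hyp2.has_equalities


def _contrast_row(K: int, plus: int, minus: int) -> tuple[int, ...]:
    row = [0] * K
    row[plus] = 1
    row[minus] = -1
    return tuple(row)


def parse_hypothesis(text: str, K: int) -> Hypothesis:
    """Parse a hypothesis string over ``mu1 .. muK``.

    Accepts ``"Ha"``, ``"Hc"``, or a chain of ``mu<i>`` tokens joined by
    ``=``, ``>`` or ``<`` (``a<b`` is normalised to ``b>a``).  Whitespace is
    ignored.  Raises :class:`HypothesisParseError` naming the offending token
    for unknown tokens, out-of-range or duplicated group indices, or an empty
    string.
    """
    if K < 2:
        raise HypothesisParseError(f"need at least 2 groups, got K={K}")
    stripped = "".join(text.split())
    if stripped in ("Ha", "ha", "HA"):
        return Hypothesis(label="Ha", kind="unconstrained_Ha", K=K)
    if stripped in ("Hc", "hc", "HC"):
        return Hypothesis(label="Hc", kind="complement_Hc", K=K)
    if not stripped:
        raise HypothesisParseError("empty hypothesis string")

    tokens: list[object] = []
    for m in _TOKEN_RE.finditer(stripped):
        if m.group(1) is not None:
            idx = int(m.group(1))
            if not 1 <= idx <= K:
                raise HypothesisParseError(f"group index out of range for K={K}: 'mu{idx}'")
            tokens.append(idx - 1)
        elif m.group(2) is not None:
            tokens.append(m.group(2))
        else:
            raise HypothesisParseError(f"unknown token {m.group(3)!r} in {text!r}")
    if len(tokens) < 3 or len(tokens) % 2 == 0:
        raise HypothesisParseError(f"malformed chain: {text!r}")
    if any(not isinstance(t, int) for t in tokens[0::2]) or any(
        not isinstance(t, str) for t in tokens[1::2]
    ):
        raise HypothesisParseError(f"malformed chain: {text!r}")

    groups = [t for t in tokens if isinstance(t, int)]
    seen: set[int] = set()
    for g in groups:
        if g in seen:
            raise HypothesisParseError(f"duplicate mean 'mu{g + 1}' in one chain")
        seen.add(g)

    # normalise "<" by reversing the whole chain ("a<b<c" == "c>b>a"); a chain
    # mixing "<" and ">" is reversed relation-by-relation below instead.
    pairs: list[tuple[int, str, int]] = []
    for i in range(1, len(tokens), 2):
        left, op, right = tokens[i - 1], tokens[i], tokens[i + 1]
        if op == "<":
            left, op, right = right, ">", left
        pairs.append((left, op, right))  # type: ignore[arg-type]

    # chain levels, largest first; well-defined whenever the normalised
    # relations form a single descending chain
    levels = _chain_levels(pairs)

    eq_rows: list[tuple[int, ...]] = []
    ineq_rows: list[tuple[int, ...]] = []
    if levels is not None:
        # canonical rows from the level structure, so equivalent chains
        # ("mu2=mu3=mu1", "mu1=mu2=mu3") yield identical constraint sets
        for lv in levels:
            for a, c in zip(lv[:-1], lv[1:]):
                eq_rows.append(_contrast_row(K, a, c))
        for upper, lower in zip(levels[:-1], levels[1:]):
            ineq_rows.append(_contrast_row(K, upper[0], lower[0]))
    else:
        for left, op, right in pairs:
            if op == "=":
                # equality rows are sign-symmetric; canonicalise to +1 first
                eq_rows.append(_contrast_row(K, min(left, right), max(left, right)))
            else:
                ineq_rows.append(_contrast_row(K, left, right))
    return Hypothesis(
        label=stripped,
        kind="constrained",
        K=K,
        equality_rows=tuple(eq_rows),
        inequality_rows=tuple(ineq_rows),
        levels=levels,
    )


def _chain_levels(pairs: list[tuple[int, str, int]]) -> tuple[tuple[int, ...], ...] | None:
    # rebuild the descending order left-to-right; give up (None) if the
    # normalised pairs no longer form one linear chain
    adj = {left: (op, right) for left, op, right in pairs}
    starts = set(adj) - {r for _, _, r in pairs}
    if len(starts) != 1:
        return None
    cur = starts.pop()
    levels: list[list[int]] = [[cur]]
    while cur in adj:
        op, nxt = adj[cur]
        if op == "=":
            levels[-1].append(nxt)
        else:
            levels.append([nxt])
        cur = nxt
    return tuple(tuple(sorted(lv)) for lv in levels)


def render(h: Hypothesis) -> str:
    """Inverse of :func:`parse_hypothesis` (canonical form, ``>`` only)."""
    if h.kind == "unconstrained_Ha":
        return "Ha"
    if h.kind == "complement_Hc":
        return "Hc"
    if h.levels is None:
        raise ValueError("hypothesis has no chain representation")
    parts = ["=".join(f"mu{g + 1}" for g in lv) for lv in h.levels]
    return ">".join(parts)


def _exact_rank(rows: list[tuple[int, ...]]) -> int:
    """Rank over the rationals by fraction-exact Gaussian elimination."""
    mat = [[Fraction(x) for x in row] for row in rows]
    rank = 0
    ncols = len(mat[0]) if mat else 0
    col = 0
    for col in range(ncols):
        pivot = next((r for r in range(rank, len(mat)) if mat[r][col] != 0), None)
        if pivot is None:
            continue
        mat[rank], mat[pivot] = mat[pivot], mat[rank]
        pv = mat[rank][col]
        for r in range(len(mat)):
            if r != rank and mat[r][col] != 0:
                factor = mat[r][col] / pv
                mat[r] = [a - factor * b for a, b in zip(mat[r], mat[rank])]
        rank += 1
    return rank


def build_pair(hyp1: Hypothesis, hyp2: Hypothesis) -> ComparisonPair:
    """Classify the comparison and derive the number of independent constraints J.

    J is the rank (over the rationals) of all equality and inequality rows of
    both hypotheses stacked.  A pair in which neither hypothesis carries any
    constraint (e.g. Ha vs Hc) is invalid: J would be 0 and the fractional
    prior undefined.
    """
    if hyp1.K != hyp2.K:
        raise ValueError(f"hypotheses disagree on K: {hyp1.K} vs {hyp2.K}")
    rows = list(hyp1.equality_rows + hyp1.inequality_rows + hyp2.equality_rows + hyp2.inequality_rows)
    if not rows:
        raise ValueError("invalid pair: neither hypothesis has constraints (J would be 0)")
    J = _exact_rank(rows)

    kinds = (hyp1.kind, hyp2.kind)
    if "complement_Hc" in kinds:
        other = hyp2 if hyp1.kind == "complement_Hc" else hyp1
        if not other.is_constrained:
            raise ValueError("Hc must be paired with a constrained hypothesis")
        if other.has_equalities:
            raise ValueError(
                "the complement Hc is only defined for inequality-constrained hypotheses"
            )
        situation = 3
    elif "unconstrained_Ha" in kinds:
        situation = 1
    else:
        eq_only_1 = hyp1.has_equalities and not hyp1.has_inequalities
        eq_only_2 = hyp2.has_equalities and not hyp2.has_inequalities
        if (eq_only_1 and hyp2.has_inequalities) or (eq_only_2 and hyp1.has_inequalities):
            situation = 2
        else:
            situation = 4
    return ComparisonPair(hyp1=hyp1, hyp2=hyp2, situation=situation, J=J)
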