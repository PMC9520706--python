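"""Two-stage detection of the disease node's parent set (STS-BN).

Phase I filters and orders candidate markers with G-tests of marginal and
conditional independence: under faithfulness, a marker is adjacent to the
disease node D if and only if no conditioning set renders it independent
of D, so markers that some small conditioning set screens off cannot be
parents or children of D.  Phase II runs a greedy hill-climb over the
surviving candidates, maximising the penalised local likelihood of D
given its parent set; the Phase I ranking supplies a stable input order,
which is what makes the overall procedure robust to permutations of the
marker columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .data import MISSING, GenotypeMatrix
from .gtest import g_test
from .scoring import DEFAULT_KAPPA, local_score

__all__ = ["STSBNConfig", "DetectionResult", "phase1_candidates", "phase2_select", "run_sts_bn"]


@dataclass(frozen=True)
class STSBNConfig:
    """Tuning parameters of the two-stage search.

    alpha1
        Significance level of the Phase I (conditional) independence
        G-tests.
    max_cond
        Largest conditioning-set size tried in Phase I; bounding it keeps
        the stratified tables populated and the subset enumeration cheap.
    kappa
        Penalty coefficient of the local score (0.5 = standard BIC).
    max_parents
        Optional cap on the Phase II parent-set size.
    bonferroni
        Apply a Bonferroni correction (alpha1 / n_markers) to the marginal
        screen, controlling the familywise error of the whole-panel sweep.
        This is what keeps the selected set nearly always empty on
        signal-free panels regardless of panel size; the conditional
        shrink tests use alpha1 per test either way.
    """

    alpha1: float = 0.01
    max_cond: int = 3
    kappa: float = DEFAULT_KAPPA
    max_parents: int | None = None
    bonferroni: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha1 < 1.0):
            raise ValueError("alpha1 must be in (0, 1)")
        if self.max_cond < 0:
            raise ValueError("max_cond must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass
class DetectionResult:
    """Outcome of a detection run.

    ``candidates`` is the Phase I survivor list in association-strength
    order (strongest first); ``selected`` is the chosen parent set of the
    disease node; ``score_trace`` records each accepted greedy move as
    ``(action, marker_index, score_after)``.
    """

    candidates: list[int]
    selected: set[int]
    score_trace: list[tuple[str, int, float]] = field(default_factory=list)
    final_score: float = float("nan")

    def selected_ids(self, g: GenotypeMatrix) -> set[str]:
        return {g.marker_ids[j] for j in self.selected}


def _complete_cases(columns: list[np.ndarray]) -> list[np.ndarray]:
    """Drop rows with a missing value in any of the given columns."""
    keep = np.ones(columns[0].shape[0], dtype=bool)
    for c in columns:
        keep &= c != MISSING
    if keep.all():
        return columns
    return [c[keep] for c in columns]


def _cond_independent(x, d, cond_cols, alpha: float) -> bool:
    cols = _complete_cases([x, d, *cond_cols])
    _, dependent = g_test(cols[0], cols[1], cols[2:], alpha=alpha)
    return not dependent


def phase1_candidates(g: GenotypeMatrix, cfg: STSBNConfig = STSBNConfig()) -> list[int]:
    """Constraint-based screen: keep markers no small set renders independent of D.

    The procedure is (i) a marginal G-test screen at ``cfg.alpha1``,
    (ii) ranking of the survivors by ascending marginal p-value (ties by
    descending G, then column index), and (iii) an interleaved shrink pass:
    walking the ranked list, an incoming marker X joins the candidate set C
    unless some subset Z of C with ``|Z| <= max_cond`` makes X independent
    of D given Z; after each admission the existing members are re-tested
    against subsets involving the newcomer and evicted if screened off.
    """
    d = g.phenotype
    if len(np.unique(d)) < 2:
        raise ValueError("phenotype must contain both cases and controls")

    # (i) marginal screen + (ii) ranking
    alpha_screen = cfg.alpha1 / max(g.n_markers, 1) if cfg.bonferroni else cfg.alpha1
    stats = []
    for j in range(g.n_markers):
        x, dd = _complete_cases([g.column(j), d])
        res, dependent = g_test(x, dd, (), alpha=alpha_screen)
        if dependent:
            stats.append((res.p_value, -res.g, j))
    stats.sort()
    ranked = [j for _, _, j in stats]

    # (iii) interleaved conditional shrink
    cand: list[int] = []
    for x in ranked:
        xcol = g.column(x)
        rejected = False
        for size in range(1, min(cfg.max_cond, len(cand)) + 1):
            for zs in itertools.combinations(cand, size):
                if _cond_independent(xcol, d, [g.column(z) for z in zs], cfg.alpha1):
                    rejected = True
                    break
            if rejected:
                break
        if rejected:
            continue
        cand.append(x)
        # re-test existing members against subsets that include the newcomer
        for y in [c for c in cand if c != x]:
            others = [c for c in cand if c != y and c != x]
            evict = False
            for size in range(0, min(cfg.max_cond - 1, len(others)) + 1):
                for zs in itertools.combinations(others, size):
                    cond = [g.column(z) for z in (*zs, x)]
                    if _cond_independent(g.column(y), d, cond, cfg.alpha1):
                        evict = True
                        break
                if evict:
                    break
            if evict:
                cand.remove(y)
    return cand


def phase2_select(
    candidates: list[int], g: GenotypeMatrix, cfg: STSBNConfig = STSBNConfig()
) -> DetectionResult:
    """Greedy hill-climb on the penalised local score of D over ``candidates``.

    Starts from the empty parent set and repeatedly applies the single
    addition or removal with the largest strict score improvement; ties are
    broken in candidate order with additions preferred.  The candidate
    ordering from Phase I therefore fully determines the search path.
    """
    d = g.phenotype

    def score_of(parents: list[int]) -> float:
        cols = _complete_cases([d, *(g.column(j) for j in parents)])
        return local_score(cols[0], cols[1:], kappa=cfg.kappa).score

    selected: list[int] = []
    current = score_of(selected)
    trace: list[tuple[str, int, float]] = []

    while True:
        best: tuple[float, str, int] | None = None
        can_add = cfg.max_parents is None or len(selected) < cfg.max_parents
        if can_add:
            for j in candidates:
                if j in selected:
                    continue
                s = score_of(selected + [j])
                if s > current and (best is None or s > best[0]):
                    best = (s, "add", j)
        for j in selected:
            s = score_of([k for k in selected if k != j])
            if s > current and (best is None or s > best[0]):
                best = (s, "remove", j)
        if best is None:
            break
        current, action, j = best
        if action == "add":
            selected.append(j)
            # keep candidate (rank) order inside the set
            selected.sort(key=candidates.index)
        else:
            selected.remove(j)
        trace.append((action, j, current))

    return DetectionResult(
        candidates=list(candidates),
        selected=set(selected),
        score_trace=trace,
        final_score=current,
    )


def run_sts_bn(g: GenotypeMatrix, cfg: STSBNConfig = STSBNConfig()) -> DetectionResult:
    """Full two-stage run: Phase I filtering/ordering, then Phase II search."""
    return phase2_select(phase1_candidates(g, cfg), g, cfg)
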