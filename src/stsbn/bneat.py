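"""Score-only greedy baseline over the unfiltered marker set.

A bNEAT-style search: no pre-filtering and no ranking — the markers are
scanned in their given column order, the first marker whose addition
improves the penalised local score is added (first-improvement moves), and
removals are attempted after every addition.  Because the scan order is
whatever column order the input happens to have, the selected set can
change when the columns are permuted; this order sensitivity is exactly
the behaviour the two-stage method's Phase I ordering is designed to
remove, and the contrast between the two searches is what this module is
for.
"""

from __future__ import annotations

from .data import GenotypeMatrix
from .detect import DetectionResult, _complete_cases
from .scoring import DEFAULT_KAPPA, local_score

__all__ = ["run_bneat"]


def run_bneat(g: GenotypeMatrix, kappa: float = DEFAULT_KAPPA) -> DetectionResult:
    """First-improvement greedy grow/shrink over all markers in column order."""
    d = g.phenotype

    def score_of(parents: list[int]) -> float:
        cols = _complete_cases([d, *(g.column(j) for j in parents)])
        return local_score(cols[0], cols[1:], kappa=kappa).score

    selected: list[int] = []
    current = score_of(selected)
    trace: list[tuple[str, int, float]] = []

    changed = True
    while changed:
        changed = False
        for j in range(g.n_markers):
            if j in selected:
                continue
            s = score_of(selected + [j])
            if s > current:
                selected.append(j)
                current = s
                trace.append(("add", j, current))
                changed = True
                # shrink: drop any member whose removal now helps
                improved = True
                while improved:
                    improved = False
                    for y in list(selected):
                        s2 = score_of([k for k in selected if k != y])
                        if s2 > current:
                            selected.remove(y)
                            current = s2
                            trace.append(("remove", y, current))
                            improved = True
                            break

    return DetectionResult(
        candidates=list(range(g.n_markers)),
        selected=set(selected),
        score_trace=trace,
        final_score=current,
    )
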