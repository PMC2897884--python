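"""Cumulative-binomial annotation enrichment.

For an annotation carried by a fraction ``p`` of the background model
set, observing ``x`` carriers among ``n`` selected models is scored with
the cumulative binomial distribution B(x; n, p) = sum_{i<=x} C(n,i) p^i
(1-p)^(n-i), and the reported p-value is 1 - B, i.e. P(X > x).  Note
this excludes the observed count itself, one notch more conservative
than the conventional upper tail; ``inclusive=True`` gives P(X >= x).
No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binom


@dataclass(frozen=True)
class AnnotationTally:
    annotation: str
    x: int      # carriers in the selected set
    n: int      # selected-set size
    p: float    # background carrier fraction

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n:
            raise ValueError(f"{self.annotation!r}: need 0 <= x <= n")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"{self.annotation!r}: p outside [0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    annotation: str
    x: int
    n: int
    p: float
    p_value: float


def cumulative_binomial(x: int, n: int, p: float) -> float:
    """B(x; n, p): probability of at most x successes in n trials."""
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p outside [0, 1]")
    return float(binom.cdf(x, n, p))


def enrichment_p_value(x: int, n: int, p: float, inclusive: bool = False) -> float:
    """1 - B(x; n, p) = P(X > x); or P(X >= x) with ``inclusive``."""
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p outside [0, 1]")
    return float(binom.sf(x - 1 if inclusive else x, n, p))


def annotation_enrichment(
    tallies: list[AnnotationTally],
    p_cut: float = 0.001,
    min_models: int = 10,
    inclusive: bool = False,
) -> list[EnrichmentResult]:
    """Annotations with p-value below *p_cut* and at least *min_models*
    carriers in the selected set, sorted by ascending p-value."""
    out = []
    for t in tallies:
        pv = enrichment_p_value(t.x, t.n, t.p, inclusive=inclusive)
        if pv < p_cut and t.x >= min_models:
            out.append(EnrichmentResult(t.annotation, t.x, t.n, t.p, pv))
    out.sort(key=lambda r: (r.p_value, r.annotation))
    return out


def tallies_from_tables(
    selected: dict[str, set[str]], background: dict[str, set[str]]
) -> list[AnnotationTally]:
    """Build tallies from gene -> annotations maps for the selected set and
    the full background model set."""
    n = len(selected)
    n_bg = len(background)
    if n_bg == 0:
        raise ValueError("empty background set")
    ann_sel: dict[str, int] = {}
    for anns in selected.values():
        for a in anns:
            ann_sel[a] = ann_sel.get(a, 0) + 1
    ann_bg: dict[str, int] = {}
    for anns in background.values():
        for a in anns:
            ann_bg[a] = ann_bg.get(a, 0) + 1
    return [
        AnnotationTally(a, ann_sel.get(a, 0), n, ann_bg.get(a, 0) / n_bg)
        for a in sorted(ann_bg)
    ]


def read_annotation_table(path) -> dict[str, set[str]]:
    """Two-column tab-separated gene -> annotation table (repeated rows)."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns")
            table.setdefault(parts[0], set()).add(parts[1])
    return table
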