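"""Summary reporting: relative-rate matrices and event-fraction arithmetic.

Observed frequencies of the three structural modification modes (gene
reordering, ≥30 nt gap widening, promoter modification) serve as proxies
for their relative evolutionary rates: the rate of mode *i* relative to
mode *j* is the ratio of their observed counts.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

MODES = ("gene_reordering", "gap_widening", "promoter_modification")
MODE_LABELS = {
    "gene_reordering": "Gene Reordering",
    "gap_widening": "30nt Gap Widening",
    "promoter_modification": "Promoter Modification",
}


def round_half_up(x: float, decimals: int) -> float:
    """Decimal rounding with ties away from zero (printed-table convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_ratio(x: float) -> float:
    """Round a rate ratio for display: two decimals at or above 1, two
    significant figures below 1."""
    if x >= 1:
        return round_half_up(x, 2)
    d = Decimal(repr(x))
    shift = -d.adjusted() + 1  # digits to reach 2 significant figures
    return float(d.quantize(Decimal(1).scaleb(-shift), rounding=ROUND_HALF_UP))


def rate_ratio_matrix(counts: Mapping[str, int]) -> dict[str, dict[str, float]]:
    """Element-wise count-ratio matrix over the three modification modes.

    ``matrix[i][j]`` is the rate of mode ``i`` relative to mode ``j``
    (count_i / count_j), rounded for display; the diagonal is 1.
    """
    missing = [m for m in MODES if m not in counts]
    if missing:
        raise KeyError(f"missing mode counts: {missing}")
    out: dict[str, dict[str, float]] = {}
    for a in MODES:
        out[a] = {}
        for b in MODES:
            if a == b:
                out[a][b] = 1.0
            else:
                if counts[b] == 0:
                    raise ZeroDivisionError(f"zero count for mode {b}")
                out[a][b] = round_ratio(counts[a] / counts[b])
    return out


def rate_matrix_tsv(matrix: Mapping[str, Mapping[str, float]]) -> str:
    lines = ["\t" + "\t".join(MODE_LABELS[m] for m in MODES)]
    for a in MODES:
        lines.append(
            MODE_LABELS[a] + "\t" + "\t".join(f"{matrix[a][b]:g}" for b in MODES)
        )
    return "\n".join(lines) + "\n"


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """A printed percentage: 100·n/d rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty set")
    return round_half_up(100.0 * numerator / denominator, decimals)


def event_fractions(counts: Mapping[str, int], decimals: int = 1) -> dict[str, float]:
    """Share of each modification-event kind among all events, in percent."""
    total = sum(counts.values())
    return {k: percentage(v, total, decimals) for k, v in counts.items()}


def count_events_by_kind(events: Sequence) -> dict[str, int]:
    out = {"prepend": 0, "append": 0, "insertion": 0}
    for e in events:
        out[e.kind] += 1
    return out
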