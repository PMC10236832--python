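"""Greedy collapsing of similar sequences and UMI deduplication.

In reference-free (barcode) mode, low-frequency sequences that are within a
small Hamming distance of a much more abundant sequence are usually PCR or
sequencing error derivatives of it.  They are absorbed greedily: sequences
are visited in decreasing count order, each unabsorbed sequence seeds a
cluster, and every later sequence joins the first (most abundant) seed that
is close enough and sufficiently dominant.  Absorption is single-pass and
non-transitive: an absorbed sequence never absorbs others.

UMI deduplication within one variant uses the same greedy sweep without the
abundance/ratio thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CollapseParams:
    """Thresholds for greedy sequence collapsing.

    max_distance
        Maximum Hamming distance for a sequence to be absorbed.
    min_abundance
        Minimum read count of the absorbing seed.
    min_ratio
        Minimum ratio seed count / absorbed count (both original,
        pre-absorption counts).
    """

    max_distance: int = 0
    min_abundance: int = 0
    min_ratio: float = 0.0

    def __post_init__(self) -> None:
        if self.max_distance < 0 or self.min_abundance < 0 or self.min_ratio < 0:
            raise ValueError("collapse thresholds must be nonnegative")


def hamming(a: str, b: str) -> int | None:
    """Hamming distance between equal-length strings; ``None`` (treated as
    infinite upstream) when lengths differ."""
    if len(a) != len(b):
        return None
    return sum(x != y for x, y in zip(a, b))


def _greedy_order(counts: dict[str, int]) -> list[str]:
    # decreasing count, ties broken lexicographically for determinism
    return sorted(counts, key=lambda s: (-counts[s], s))


def collapse_sequences(
    counts: dict[str, int], params: CollapseParams
) -> dict[str, tuple[int, list[str]]]:
    """Greedily collapse a sequence→count table.

    Returns a map seed sequence → (summed count, constituent sequences in
    absorption order, seed first).  Total read counts are conserved.
    Sequences of unequal length are never merged.
    """
    order = _greedy_order(counts)
    seeds: list[str] = []
    members: dict[str, list[str]] = {}
    totals: dict[str, int] = {}
    for seq in order:
        c = counts[seq]
        absorbed = False
        for seed in seeds:
            d = hamming(seq, seed)
            if d is None or d > params.max_distance:
                continue
            if counts[seed] < params.min_abundance:
                continue
            if c > 0 and counts[seed] / c < params.min_ratio:
                continue
            totals[seed] += c
            members[seed].append(seq)
            absorbed = True
            break
        if not absorbed:
            seeds.append(seq)
            totals[seq] = c
            members[seq] = [seq]
    return {s: (totals[s], members[s]) for s in seeds}


def collapse_umis(umis: dict[str, int], max_distance: int) -> int:
    """Number of distinct UMIs after greedy error-collapsing within one
    variant.  A UMI is absorbed by the most abundant earlier seed within
    `max_distance`; no abundance or ratio conditions apply."""
    if max_distance < 0:
        raise ValueError("max_distance must be nonnegative")
    if max_distance == 0:
        return len(umis)
    collapsed = collapse_sequences(umis, CollapseParams(max_distance=max_distance))
    return len(collapsed)
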