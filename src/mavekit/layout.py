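"""Read-layout grammar for amplicon reads.

Each sequencing read in a MAVE/DMS library is a concatenation of up to five
kinds of segments:

``V``
    variable region — carries the variant of interest.
``C``
    constant region — fixed sequence, used for error-rate estimation and
    filtering on unexpected mismatches.
``S``
    skipped region — ignored.
``P``
    primer — an anchor located by exact search rather than by position.
``U``
    unique molecular identifier (UMI) — random tag used to collapse PCR
    duplicates.

A layout is written as an element string plus a parallel vector of segment
lengths, e.g. ``"SUCV"`` with lengths ``[1, 10, 18, 96]`` for a read of the
form  [1 nt skip][10 nt UMI][18 nt constant][96 nt variable].  A length of
``-1`` is the *remainder* sentinel: the segment absorbs whatever part of the
read is not claimed by fixed-length segments.  With a primer anchor the read
is split into a pre-primer and a post-primer part, each of which may carry
one sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_CODES = frozenset("VCSPU")

#: length value meaning "the remainder of the read (part)"
REMAINDER = -1

# filter reasons produced by segmentation (unprefixed; the digestion cascade
# maps them onto its tally fields)
NO_PRIMER = "noPrimer"
READ_LENGTH_MISMATCH = "readLengthMismatch"


class LayoutError(ValueError):
    """Raised for an invalid element specification."""


@dataclass(frozen=True)
class ElementSpec:
    """Validated read-composition specification.

    Parameters
    ----------
    codes
        Segment codes in read order, each one of ``V C S P U``.
    lengths
        Segment lengths, parallel to `codes`; ``-1`` marks a remainder
        sentinel.
    primer_seq
        Anchor sequence; required iff a ``P`` code is present, and its
        length must equal the length entry at the ``P`` position.
    """

    codes: tuple[str, ...]
    lengths: tuple[int, ...]
    primer_seq: str | None = None

    def __post_init__(self) -> None:
        codes, lengths = self.codes, self.lengths
        if not codes:
            raise LayoutError("element string must be non-empty")
        if len(codes) != len(lengths):
            raise LayoutError(
                f"{len(codes)} element codes but {len(lengths)} lengths"
            )
        bad = [c for c in codes if c not in VALID_CODES]
        if bad:
            raise LayoutError(f"unknown element code(s): {bad!r}")
        n_primer = codes.count("P")
        if n_primer > 1:
            raise LayoutError("at most one primer (P) element is allowed")
        if n_primer == 1:
            if not self.primer_seq:
                raise LayoutError("P element requires a primer sequence")
            p = codes.index("P")
            if lengths[p] != len(self.primer_seq):
                raise LayoutError(
                    f"length entry at P ({lengths[p]}) must equal the primer "
                    f"sequence length ({len(self.primer_seq)})"
                )
            pre = lengths[:p]
            post = lengths[p + 1 :]
            if sum(1 for v in pre if v == REMAINDER) > 1:
                raise LayoutError("at most one remainder sentinel before the primer")
            if sum(1 for v in post if v == REMAINDER) > 1:
                raise LayoutError("at most one remainder sentinel after the primer")
        else:
            if self.primer_seq:
                raise LayoutError("primer sequence given without a P element")
            if sum(1 for v in lengths if v == REMAINDER) > 1:
                raise LayoutError("at most one remainder sentinel without a primer")
        for c, v in zip(codes, lengths):
            if v != REMAINDER and v < 1:
                raise LayoutError(f"segment {c} has illegal length {v}")

    @property
    def primer_index(self) -> int | None:
        return self.codes.index("P") if "P" in self.codes else None

    @property
    def fixed_length(self) -> int:
        """Total length of all fixed (non-sentinel, non-primer-slack) parts."""
        return sum(v for v in self.lengths if v != REMAINDER)


@dataclass
class ComponentSet:
    """Segments extracted from one read under an :class:`ElementSpec`.

    Multiple regions of one code are concatenated in read order, so there is
    one logical variable/constant/UMI string per read.  Qualities are Phred
    scores (integers in [0, 93]) parallel to their sequence.
    """

    variable: str = ""
    variable_qual: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    constant: str = ""
    constant_qual: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    umi: str = ""
    skipped_length: int = 0
    primer_length: int = 0

    @property
    def total_length(self) -> int:
        return (
            len(self.variable)
            + len(self.constant)
            + len(self.umi)
            + self.skipped_length
            + self.primer_length
        )


def parse_element_spec(
    code_string: str,
    lengths: list[int] | tuple[int, ...],
    primer_seq: str | None = None,
) -> ElementSpec:
    """Parse and validate an element string + length vector into an
    :class:`ElementSpec`.

    >>> parse_element_spec("SUCV", [1, 10, 18, 96]).fixed_length
    125
    """
    return ElementSpec(tuple(code_string), tuple(int(v) for v in lengths), primer_seq)


def locate_primer(read_seq: str, primer_seq: str) -> int | None:
    """0-based start of the first exact occurrence of `primer_seq` in
    `read_seq`, or ``None`` if it does not occur."""
    if not primer_seq:
        raise ValueError("primer sequence must be non-empty")
    pos = read_seq.find(primer_seq)
    return None if pos < 0 else pos


def _resolve_lengths(
    codes: tuple[str, ...], lengths: tuple[int, ...], available: int
) -> list[int] | str:
    """Resolve a run of segments (no primer) against `available` bases.

    Returns concrete lengths, or the ``readLengthMismatch`` reason when the
    fixed lengths cannot tile the available span.
    """
    fixed = sum(v for v in lengths if v != REMAINDER)
    residual = available - fixed
    has_sentinel = REMAINDER in lengths
    if residual < 0 or (residual != 0 and not has_sentinel):
        return READ_LENGTH_MISMATCH
    return [residual if v == REMAINDER else v for v in lengths]


def segment_read(
    seq: str, quals: np.ndarray, spec: ElementSpec
) -> ComponentSet | str:
    """Split one read into its components under `spec`.

    Returns a :class:`ComponentSet`, or a filter reason string:
    ``"noPrimer"`` when the anchor is absent, ``"readLengthMismatch"`` when
    the fixed segment lengths are incompatible with the read length.

    With a primer anchor, the anchor is the first exact occurrence whose
    start is at least the summed fixed length of the pre-primer segments
    (exactly that offset when the pre-primer part has no remainder
    sentinel).
    """
    n = len(seq)
    p = spec.primer_index
    if p is None:
        resolved = _resolve_lengths(spec.codes, spec.lengths, n)
        if isinstance(resolved, str):
            return resolved
        return _extract(seq, quals, spec.codes, resolved)

    primer = spec.primer_seq
    assert primer is not None
    plen = len(primer)
    pre_codes, pre_lengths = spec.codes[:p], spec.lengths[:p]
    post_codes, post_lengths = spec.codes[p + 1 :], spec.lengths[p + 1 :]
    fixed_pre = sum(v for v in pre_lengths if v != REMAINDER)
    if REMAINDER in pre_lengths:
        pos = seq.find(primer, fixed_pre)
        if pos < 0:
            return NO_PRIMER
    else:
        pos = fixed_pre
        if seq[pos : pos + plen] != primer:
            return NO_PRIMER
    pre = _resolve_lengths(pre_codes, pre_lengths, pos)
    post = _resolve_lengths(post_codes, post_lengths, n - pos - plen)
    if isinstance(pre, str):
        return pre
    if isinstance(post, str):
        return post
    codes = pre_codes + ("P",) + post_codes
    lengths = pre + [plen] + post
    return _extract(seq, quals, codes, lengths)


def _extract(
    seq: str, quals: np.ndarray, codes: tuple[str, ...], lengths: list[int]
) -> ComponentSet:
    comp = ComponentSet()
    var_parts: list[str] = []
    var_quals: list[np.ndarray] = []
    const_parts: list[str] = []
    const_quals: list[np.ndarray] = []
    umi_parts: list[str] = []
    start = 0
    for code, length in zip(codes, lengths):
        stop = start + length
        if code == "V":
            var_parts.append(seq[start:stop])
            var_quals.append(quals[start:stop])
        elif code == "C":
            const_parts.append(seq[start:stop])
            const_quals.append(quals[start:stop])
        elif code == "U":
            umi_parts.append(seq[start:stop])
        elif code == "S":
            comp.skipped_length += length
        elif code == "P":
            comp.primer_length += length
        start = stop
    comp.variable = "".join(var_parts)
    comp.variable_qual = (
        np.concatenate(var_quals) if var_quals else np.empty(0, dtype=np.int64)
    )
    comp.constant = "".join(const_parts)
    comp.constant_qual = (
        np.concatenate(const_quals) if const_quals else np.empty(0, dtype=np.int64)
    )
    comp.umi = "".join(umi_parts)
    return comp
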